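# facetshift

How will climate change redistribute not just species, but the *traits* and
*evolutionary lineages* they carry?  `facetshift` is a reusable, tested
pipeline for answering that question for a species assemblage (its design
case is a continental odonate fauna): per-species presence–background
distribution models projected to future climates, stacked into community
predictions, decomposed into taxonomic (TD), functional (FD) and
phylogenetic (PD) α- and β-diversity maps, and per-species range shifts
analysed with phylogenetic comparative methods.

It is aimed at macroecologists and climate-change biogeographers who want
the full chain — occurrence cleaning through PGLS — as one scripted,
seed-reproducible artefact, plus a synthetic-data module that generates
complete study systems with *known* ground truth, so that every stage has a
recovery target.

## The methods in brief

**Suitability models.** For each species, presences are contrasted with
background points (2× the presences) drawn inside a buffered accessible area
— the minimum convex polygon of its records, trimmed of 1% centroid-distance
outliers and buffered by 10 km per month of flight period,
`buffer = 100 000 m × (flight months / 10)`.  Three learner families are fit
(additive logistic model with spline terms; a MaxEnt-style regularized
log-linear classifier with linear + quadratic + product features; stochastic
gradient-boosted trees) plus their unweighted-mean ensemble.  A stratified
75/25 holdout scores each candidate by AUC and the continuous Boyce index;
species whose best model has AUC < 0.7 or Boyce < 0.4 are flagged and
excluded downstream.  The best learner is refit on all data and binarised at
the threshold `t* = argmax_t [sensitivity(t) + specificity(t)]`.

**Predictors.** From monthly tmin/tmax/precipitation the pipeline derives
the bioclim variables it needs (bio1–bio15 subset), Emberger's pluviometric
quotient `Q = 2000 P / ((T_max + T_min)(T_max − T_min))` (kelvin), and
filters collinearity by clustering on `1 − |r|` (cut at 0.5) followed by
iterative VIF pruning to VIF ≤ 3.

**Diversity.** Binary maps are stacked into a cell × species matrix.  Tree
facets use Faith-style α: the summed branch length of the root-inclusive
subtree spanning the present species (on a unit star tree this is the
species count, i.e. TD).  Temporal β per cell compares present vs future
communities via shared (a) and unique (b, c) branch lengths:

    β_total = (b + c)/(a + b + c) = β_repl + β_rich
    β_repl  = 2·min(b, c)/(a + b + c)        β_rich = |b − c|/(a + b + c)

The functional tree is a UPGMA dendrogram on a group-balanced Gower
dissimilarity (size traits, habitat flags, flight season and colour each
contribute equally as groups).

**Comparative analysis.** Per species the pipeline computes relative area
change, altitude difference and centroid difference (great-circle,
R = 6 371 008.8 m), then tests for phylogenetic signal (Pagel's λ by ML with
a likelihood-ratio test; Blomberg's K with a seeded permutation test), runs
ML ancestral state reconstruction, and fits PGLS with λ/κ/δ branch-length
transformations profiled by maximum likelihood.

## Worked example

```bash
facetshift run-all --out runs/demo --seed 1
facetshift report --out runs/demo
```

generates a 15-species synthetic world (60 × 60 grid, 0.1° cells), runs every
stage under the +2 °C mid-century scenario preset, and prints (excerpt):

```
counts: {"n_clean_records": 3000, ..., "n_modelled": 15, "n_low_quality": 3,
         "n_community_species": 12, ...}

Range-shift summary (mean +/- SE, counts shifting north/up)
  scenario  period  centroid_latitude_shift_mean ...  n_species  n_northward  n_upward
BCC-CSM1-1    2050                         0.447 ...         12           12        12

Alpha/beta diversity summary per facet
  scenario  period facet  alpha_present_mean  alpha_future_mean  delta_alpha_mean ...
BCC-CSM1-1    2050    TD               3.801              4.286             0.485 ...
```

Reading this: of 15 simulated species, 12 passed the model-quality gates;
all 12 shifted their range centroid poleward (mean +0.447° latitude) and
upslope under warming — exactly the behaviour built into the generator,
since every species' thermal niche follows the warmest-quarter temperature.
Mean per-cell species richness rises from 3.80 to 4.29 because the northern
(cold-edge) half of the grid gains more species than the southern half
loses.  Every intermediate artefact (cleaned occurrences, accessible-area
polygons as WKT, per-species binary maps, diversity rasters, PGLS tables)
lands under `runs/demo/` with a hash-complete `manifest.json`; rerunning
with the same seed reproduces every CSV byte-for-byte.

The same stages are available as library calls (`facetshift.run_all`,
`facetshift.fit_learners`, `facetshift.beta_temporal`, `facetshift.PGLS`,
…); the SDM learners and PGLS are scikit-learn-style estimators that
compose with sklearn model selection.

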