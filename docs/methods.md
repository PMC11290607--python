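# Methods

This note documents the models, defaults and numerical choices behind
`facetshift`, and what the synthetic study system does and does not emulate.

## The synthetic study system

The generator (`facetshift.synthetic`) produces every input the pipeline
consumes, with known ground truth.

**Landscape.** A regular lon/lat grid (default 60 × 60 cells of 0.1°,
upper-left corner at 5°E 48°N).  Monthly mean temperature is a sum of a
latitudinal gradient (default 2 °C per degree latitude), an elevational
lapse (6.5 °C km⁻¹), a sinusoidal seasonal cycle (amplitude 9 °C, peak in
July) and spatially autocorrelated anomalies (Gaussian-filtered white
noise, kernel σ = 4 cells).  tmin/tmax are the monthly mean ∓ half an 8 °C
diurnal range, so `tmax ≥ tmin` holds by construction.  Precipitation is a
seasonal cycle around 60 mm month⁻¹ plus smoothed anomalies, clipped at 0.
Elevation is |smoothed noise| × 700 m; a smoothed field thresholded at its
85th percentile defines water cells, and its logistic transform is the
continuous "water density" predictor.

The default latitudinal gradient is steeper than the real mid-latitude
~0.7 °C per degree: the domain is a scaled-down stand-in for a continent, and
compressing the gradient keeps the biologically relevant regime — isotherm
displacement under warming small relative to the domain, and of the same
order as species' dispersal buffers — inside a 6° window.

**Future scenarios** are additive temperature offsets and multiplicative
precipitation factors.  The three presets carry familiar GCM labels
(BCC-CSM1-1: +2.0/+2.6 °C for 2050/2070; MIROC-ESM-CHEM: +2.4/+3.2;
NorESM1-M: +1.6/+2.1; precipitation factors 0.90–0.97) and are plausible
moderate-pathway magnitudes — parameter presets, not climate-model output.
Elevation and water are held constant in the future.

**Species.** Each species' true suitability is a logistic function of named
predictor layers: a Gaussian-shaped thermal niche on bio10 (mean temperature
of the warmest quarter), expressed as linear + quadratic logit terms with
optimum spread over the 30th–90th bio10 quantiles, niche breadth 1–2 °C, peak
logit 2.5–4.5; plus a positive water-density affinity (weight 1–2.5) that
gives the suitability surface structure *within* an accessible area.
Because every niche tracks bio10, warming moves each species' suitable band
poleward/upslope by construction — that is the recovery target of the
end-to-end directional test.  Presences are drawn without replacement among
land cells with probability ∝ true suitability and jittered uniformly within
the cell; a configurable dirty fraction appends records violating each
cleaning rule (pre-1970 year, exact duplicate, inflated coordinate
uncertainty, out-of-area), round-robin, with provenance bookkeeping.

**Phylogeny and traits.** A hand-rolled pure-birth (Yule) simulator gives
exactly ultrametric trees (lineages split at exponential waiting times; all
tips extend to the stopping time).  Traits evolve as Brownian motion on the
λ-transformed tree: covariance `rate × C_λ` where `C_λ` keeps the BM
diagonal and scales off-diagonals by λ, so λ = 0 gives independent tips and
λ = 1 plain BM.  The trait table scales three BM realisations into
body/abdomen/wing lengths (mm), uses one for abdomen colour, and takes
habitat flags and flight period from the species objects.

**What the generator does not emulate:** sampling bias and spatial clumping
of real occurrence data, coastlines and true dispersal barriers, climate
physics (no circulation, no interannual variability), niche axes beyond
temperature and water, and trait–niche correlations beyond what BM supplies.
Passing tests therefore demonstrate that the *machinery* is correct and that
known signals are recovered — not that any real fauna will behave this way.

## Occurrence preparation

Cleaning removes records before 1970, outside the study polygon, with
coordinate uncertainty above one grid cell (~11 km), and duplicate
coordinates after rounding to 6 decimals (sub-metre noise must not defeat
deduplication); the surviving duplicate is chosen by sorting, making the
result order-independent.  Species with no survivors are flagged
unmodellable.  Thinning enforces a minimum pairwise great-circle distance
(default 1 cell, converted at the meridian scale of 111.195 km/°) by greedily
removing the record with the most neighbours inside the radius, ties broken
by a seeded draw.  Thinning runs before accessible-area construction;
the alternative order is a one-line change in the pipeline stage.

The accessible area is the convex hull after discarding the
⌈1% · n⌉ records farthest from the coordinate centroid, buffered by
`100 000 m × flight_months / 10` (10 km per month of flight season; the
multiplier is a config constant).  Buffering happens in a local
equirectangular projection centred on the hull — at the few-hundred-km scale
involved this tracks a geodesic buffer to well under 1%.  Background points
are cell centres drawn uniformly without replacement inside the buffered
polygon, presence cells excluded, exactly 2× the presences; if fewer
eligible cells exist, sampling falls back to with-replacement and logs it.

## Predictors

Quarters in the bioclim derivations are the 12 wrap-around 3-month windows
indexed by their **centre** month; ties between equally wet/warm quarters go
to the lowest centre month.  (Indexing by start month would pick a different
member of a tied triple; the centred convention makes "the quarter of the
wet month" the window centred on it.)  bio15 uses the `1 + bio12/12`
denominator so arid cells stay defined; bio4 and bio15 use the sample
standard deviation (ddof = 1).  Emberger's quotient takes its temperatures
in kelvin; cells with `T_max = T_min` are masked and counted.

Collinearity filtering clusters variables by average linkage on `1 − |r|`
cut at `1 − r_max`, keeps one representative per cluster (lowest mean |r|
against all variables; named variables in the keep-list are always kept),
then iteratively drops the highest-VIF variable until all VIF ≤ 3.  Average
linkage does not mathematically guarantee that representatives of different
clusters satisfy |r| < r_max, so a post-hoc pass enforces it.  VIF is the
diagonal of the inverse correlation matrix.  The pipeline's default
keep-list is the classical seven-predictor set (water, elevation, Emberger's
Q, bio7, bio8, bio10, bio15); the filter still verifies it and prunes the
remaining candidates.

## Suitability modelling

The three learners are deliberately simple, well-tested compositions:

* **Additive logistic (GAM family):** standardise → cubic splines (5 knots)
  per predictor → ridge-penalised logistic regression.
* **MaxEnt-style:** min-max scale → all linear, quadratic and pairwise
  product features → L1-regularised logistic regression.  This is the
  presence–background log-linear equivalent of a MaxEnt model with
  linear/quadratic/product feature classes, not a port of the original
  software.
* **Boosted trees:** stochastic gradient boosting (300 trees, learning rate
  0.05, depth 3, subsample 0.75).

The ensemble is the unweighted pointwise mean of the three calibrated
suitabilities and competes as a fourth candidate on the same split.  The
75/25 split is class-stratified and seeded.  Quality gates: best holdout
AUC < 0.7 or Boyce < 0.4 flags the species; flagged species keep their model
but are excluded from stacked metrics.  The threshold search uses the exact
candidate set (all observed scores) with integer-exact objective comparison,
so the smallest-threshold tie-break is well defined.

**Boyce windowing.** The continuous Boyce index is the Spearman correlation
between the presence-to-background ratio P/E and the window centre.  Two
windowings are used, both config keys.  The *library default* is 101 centres
of width range/50: measured on 200 null replicates (presences permuted from
background, n = 500 each), |index| ≤ 0.35 in 98.5% of replicates, while a
monotone model still scores ≥ 0.9.  The *classic* smoothing (width =
range/10) produces heavily overlapping windows whose P/E values are strongly
autocorrelated; its null |index| 95th percentile is ≈ 0.6, which makes it
unusable as a calibrated metric — but its lower variance is what a fixed
quality gate needs with 25–50 test presences, so the per-species holdout
evaluation uses it (`boyce_window_fraction = 0.1`).

## Diversity

α for tree facets is root-inclusive Faith: every branch whose descendant set
intersects the community counts, so a single-species cell scores its
root-to-tip distance; the taxonomic facet is exactly the same computation on
a unit-branch star tree.  Temporal β uses the replacement/richness
decomposition on shared (a) vs unique (b, c) branch lengths; a branch is
shared iff it lies on the root path of at least one tip of each community.
β_total = β_repl + β_rich holds to machine precision by construction.  Cells
empty in both periods score 0 on all three components (a companion mask
records them); a cell suitable in only one period is an ordinary comparison
with one empty side (β_total = 1, β_repl = 0).

The functional dendrogram is UPGMA (configurable linkage) on the
group-balanced Gower matrix: continuous traits use range-normalised absolute
differences, the two habitat flags average their 0/1 mismatches, RGB is one
trait (Euclidean distance in the unit colour cube ÷ √3); member traits
average within groups and the four groups average with equal weight.  This
is the analytic equal-contribution form; iterative optimisation of trait
weights is out of scope.  Merge at distance d places the new node at height
d/2, so cophenetic distances reproduce ultrametric inputs exactly.

## Range shifts

Area = count of suitable cells (ratio future/current); altitude = mean
elevation over suitable cells; centroid = unweighted mean of suitable-cell
centres (a cos(latitude) weighting is a switch); centroid distance by
haversine on a sphere of radius 6 371 008.8 m (an ellipsoid differs by
< 0.5% at these scales).  An empty future range reports area ratio 0 and
missing altitude/centroid differences.  Summaries report mean ± SE (sd/√n,
NaN for a single species) and counts shifting north/upslope.

## Comparative methods

The BM covariance `C` has `C[i,j]` = shared root-path length.  Pagel's λ is
profiled analytically (GLS root mean and ML rate in closed form per λ) and
maximised over `[0, λ_max]`, where λ_max is computed as the largest value
keeping every off-diagonal below both involved diagonals (≥ 1 for
ultrametric trees); significance is a likelihood-ratio test against λ = 0
(χ², 1 df).  Star trees are reported with a flat-likelihood flag.
Blomberg's K standardises MSE₀/MSE by its BM expectation
`(tr C − n/(1'C⁻¹1))/(n−1)`; its p-value is a seeded tip-shuffling
permutation test (add-one rule), vectorised over permutations.  Ancestral
states are GLS predictions `μ̂ + Cov(node, tips) V⁻¹ (x − μ̂)` with
prediction variances that include the uncertainty of μ̂; the root estimate
equals the GLS mean exactly.

PGLS profiles one transformation parameter per family — λ (off-diagonal
scaling), κ (branch lengths raised to a power, with 0⁰ := 0 so κ = 0 gives
unit branches), δ (element-wise power of C, i.e. node depths raised to δ) —
on a 51-point grid with bounded scalar refinement; `transform="best"` keeps
the ML winner.  **The λ search in PGLS is capped at min(computed bound, 1):**
just past the ultrametric cap the covariance approaches singularity and the
regression can absorb the near-null direction, sending the profile
likelihood to +∞ and the coefficient SEs to 0 (measured: slope CI coverage
collapsed to ~34% uncapped, 92–98% capped).  Coefficient SEs use the
unbiased σ² (n − p denominator); t-tests have n − p df.  Singular designs
raise an error naming the collinear columns; the suite-level runner prunes
constant/collinear predictor columns first (as one would when excluding
collinear traits) and skips strata with fewer than 4 species or saturated
designs, logging each.

The suite runs λ, K, ancestral reconstruction and PGLS per response
(relative area change, altitude difference, centroid difference) × scenario
× period, for the full tree and for the two clades at the root split
(mirroring a suborder-level reanalysis).  Responses stay on their raw scale;
a log-transform is the caller's choice.  Signal significance is read at
α = 0.01 and PGLS coefficients at α = 0.05 by convention; both are the
caller's to change.

## Pipeline and reproducibility

Stage seeds derive from CRC32 of `"{master_seed}:{stage}"` (< 2³¹), so
stages rerun independently yet reproducibly.  All tabular outputs are tidy
CSV, rasters are ESRI ASCII grids, trees Newick; `manifest.json` lists every
artefact with a SHA-256 hash, the config, its hash and the per-stage seeds.
Identical config + seed reproduces every CSV byte-for-byte (tested).

Default problem sizes — 15 species, 60 × 60 grid, 200 presences per species,
one scenario × period — run end-to-end in roughly ten seconds on one core;
the acceptance script's calibration batteries (λ recovery, K calibration,
PGLS coverage) use 20–100 replicates at 50–100 tips, chosen to give stable
means while keeping a full run near ten seconds.

## Known limitations

* Binary stacked maps only: no abundance weighting, no rarefaction, no
  cell-vs-neighbour spatial β.
* Dispersal enters only through the accessible-area buffer; no
  dispersal-explicit or mechanistic modelling.
* The equirectangular metric buffering and meridian-scale cell conversion
  are small-extent approximations; they are not suitable for polar or
  hemispheric domains.
* The MaxEnt-style learner is the log-linear equivalent, not the original
  software; hinge/threshold features are not implemented.
* PGLS profiles a single transformation parameter; no OU or multi-parameter
  models, and no Bayesian comparative methods.
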