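"""End-to-end orchestration: synthetic world -> occurrence prep -> predictors
-> SDMs -> diversity maps -> range shifts -> comparative analysis.

Every stage derives its own seed deterministically from the master seed and
the stage name, writes tidy CSV / ASCII-grid / Newick artefacts into the run
directory, and registers them (with content hashes) in ``manifest.json``, so
a run is fully reproducible from its config + seed and stages can be rerun
independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparative as comp
from . import diversity as div
from . import occurrences as occ_mod
from . import predictors as pred_mod
from . import rangeshift as rs
from . import sdm as sdm_mod
from . import synthetic as syn
from .grids import PredictorStack, RasterGrid
from .trees import build_dendrogram, load_tree
from .traits import TraitTable, gower_grouped

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "stage_seed", "run_all", "report", "STAGES"]

STAGES = ["synth", "prep", "predictors", "sdm", "diversity", "shift", "comparative"]

BIOCLIM_CANDIDATES = ["bio1", "bio4", "bio5", "bio6", "bio7", "bio8", "bio10", "bio12", "bio15"]


@dataclass
class RunConfig:
    """Full parameterisation of a pipeline run."""

    # synthetic world
    grid_shape: tuple[int, int] = (60, 60)
    cell_size_deg: float = 0.1
    origin: tuple[float, float] = (5.0, 48.0)
    n_species: int = 15
    n_presences: int = 200
    dirty_fraction: float = 0.1
    birth_rate: float = 1.0
    lat_gradient: float = 2.0
    optima_quantiles: tuple[float, float] = (0.30, 0.90)
    # scope
    scenarios: list[str] = field(default_factory=lambda: ["BCC-CSM1-1"])
    periods: list[str] = field(default_factory=lambda: ["2050"])
    # occurrence prep
    min_distance_cells: float = 1.0
    outlier_pct: float = 0.01
    max_uncertainty_cells: float = 1.0
    # predictors
    r_max: float = 0.5
    vif_max: float = 3.0
    n_predictor_samples: int = 2000
    # the classical seven-predictor set is forced by default; the filter still
    # verifies it and prunes everything else
    keep_predictors: list[str] = field(default_factory=lambda: [
        "water", "elevation", "embergerQ", "bio7", "bio8", "bio10", "bio15"])
    # sdm
    min_presences: int = 15
    boyce_windows: int = 101
    boyce_window_fraction: float = 0.1
    brt_estimators: int = 300
    # comparative
    n_permutations: int = 200
    pgls_transform: str = "best"
    # master seed
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        d["origin"] = list(d["origin"])
        d["optima_quantiles"] = list(d["optima_quantiles"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "origin" in d:
            d["origin"] = tuple(d["origin"])
        if "optima_quantiles" in d:
            d["optima_quantiles"] = tuple(d["optima_quantiles"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of 'master:stage' (below 2^31)."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


# --------------------------------------------------------------------- manifest

class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.data = {
            "config": config.to_dict(),
            "config_hash": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
            "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
            "stages_completed": [],
            "counts": {},
            "files": {},
        }

    def register(self, path: Path) -> None:
        rel = str(path.relative_to(self.outdir))
        self.data["files"][rel] = hashlib.sha256(path.read_bytes()).hexdigest()

    def complete(self, stage: str, **counts) -> None:
        if stage not in self.data["stages_completed"]:
            self.data["stages_completed"].append(stage)
        self.data["counts"].update(counts)
        self.save()

    def save(self) -> None:
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def _write_csv(df: pd.DataFrame, path: Path, manifest: _Manifest, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.10g")
    manifest.register(path)


def _write_grid(grid: RasterGrid, path: Path, manifest: _Manifest) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    grid.to_ascii(path)
    manifest.register(path)


# ---------------------------------------------------------------------- stages

def _stage_synth(config: RunConfig, outdir: Path, manifest: _Manifest, state: dict) -> None:
    seed = stage_seed(config.seed, "synth")
    world = syn.generate_world(syn.WorldConfig(
        grid_shape=config.grid_shape, cell_size_deg=config.cell_size_deg,
        origin=config.origin, lat_gradient=config.lat_gradient, seed=seed))
    layers = pred_mod.bioclim(world.monthly_tmin, world.monthly_tmax, world.monthly_prec)
    layers = {**layers, "elevation": world.elevation, "water": world.water}
    pool = syn.make_species_pool(
        config.n_species,
        (float(np.quantile(layers["bio10"], config.optima_quantiles[0])),
         float(np.quantile(layers["bio10"], config.optima_quantiles[1]))),
        seed=seed + 1, n_presences=config.n_presences)
    tree = syn.simulate_pure_birth(config.n_species, config.birth_rate, seed + 2,
                                   labels=[sp.species_id for sp in pool])
    traits = syn.synthetic_trait_table(pool, tree, seed + 3)

    occs = []
    for i, sp in enumerate(pool):
        occs.append(syn.sample_occurrences(world, sp, seed=seed + 10 + i,
                                           dirty_fraction=config.dirty_fraction,
                                           layers=layers))
    raw = pd.concat(occs, ignore_index=True)

    d = outdir / "world"
    d.mkdir(parents=True, exist_ok=True)
    _write_grid(world.layer(world.elevation, "elevation"), d / "elevation.asc", manifest)
    _write_grid(world.layer(world.water, "water"), d / "water.asc", manifest)
    _write_csv(raw, outdir / "occurrences" / "raw.csv", manifest)
    _write_csv(traits, outdir / "traits.csv", manifest, index=True)
    (outdir / "phylogeny.nwk").write_text(tree.to_newick() + "\n")
    manifest.register(outdir / "phylogeny.nwk")
    species_meta = pd.DataFrame([{
        "species": sp.species_id, "flight_months": sp.flight_months,
        "lentic": int(sp.lentic), "lotic": int(sp.lotic),
        "thermal_optimum": sp.thermal_optimum, "n_presences": sp.n_presences,
    } for sp in pool])
    _write_csv(species_meta, outdir / "species.csv", manifest)

    state.update(world=world, pool=pool, tree=tree, traits=traits, raw_occurrences=raw,
                 current_layers=layers)
    manifest.complete("synth", n_species=len(pool), n_raw_records=len(raw))


def _stage_prep(config: RunConfig, outdir: Path, manifest: _Manifest, state: dict) -> None:
    seed = stage_seed(config.seed, "prep")
    world: syn.SyntheticWorld = state["world"]
    raw: pd.DataFrame = state["raw_occurrences"]
    study_area = world.study_area_polygon()
    max_unc = config.max_uncertainty_cells * config.cell_size_deg * occ_mod.METERS_PER_DEGREE

    cleaned, thinned, areas, backgrounds = [], [], {}, []
    unmodellable = []
    meta = {sp.species_id: sp for sp in state["pool"]}
    for i, (species, grp) in enumerate(raw.groupby("species", sort=True)):
        try:
            cl = occ_mod.clean_records(grp, study_area, max_uncertainty_m=max_unc)
        except occ_mod.UnmodellableSpeciesError:
            unmodellable.append(species)
            continue
        th = occ_mod.thin_spatially(cl, config.min_distance_cells,
                                    config.cell_size_deg, seed=seed + i)
        try:
            area = occ_mod.accessible_area(th, meta[species].flight_months,
                                           outlier_pct=config.outlier_pct,
                                           species_id=species)
        except ValueError:
            unmodellable.append(species)
            continue
        grid = world.grid
        pr, pc = grid.indices_of(th["lon"].to_numpy(), th["lat"].to_numpy())
        bg = occ_mod.sample_background(area, len(th), grid, seed=seed + 500 + i,
                                       presence_cells=set(zip(pr[pr >= 0].tolist(),
                                                              pc[pr >= 0].tolist())))
        cleaned.append(cl)
        thinned.append(th)
        areas[species] = area
        backgrounds.append(bg)

    clean_df = pd.concat(cleaned, ignore_index=True)
    thin_df = pd.concat(thinned, ignore_index=True)
    bg_df = pd.concat(backgrounds, ignore_index=True)
    _write_csv(clean_df, outdir / "occurrences" / "clean.csv", manifest)
    _write_csv(thin_df, outdir / "occurrences" / "thinned.csv", manifest)
    _write_csv(bg_df, outdir / "occurrences" / "background.csv", manifest)
    wkt = pd.DataFrame([{"species": s, "buffer_m": a.buffer_m,
                         "mcp_wkt": a.mcp.wkt, "buffered_wkt": a.buffered.wkt}
                        for s, a in areas.items()])
    _write_csv(wkt, outdir / "occurrences" / "accessible_areas.csv", manifest)

    state.update(occ_clean=clean_df, occ_thinned=thin_df, areas=areas,
                 backgrounds=bg_df, unmodellable=unmodellable)
    manifest.complete("prep", n_modellable=len(areas), n_unmodellable=len(unmodellable),
                      n_clean_records=len(clean_df), n_thinned_records=len(thin_df))


def _build_stack(world: syn.SyntheticWorld, scenario: str, period: str) -> PredictorStack:
    w = world if scenario == "current" else world.future_climate(scenario, period)
    layers = pred_mod.bioclim(w.monthly_tmin, w.monthly_tmax, w.monthly_prec)
    grid = world.grid
    stack = PredictorStack({}, scenario=scenario, period=period)
    for name in BIOCLIM_CANDIDATES:
        stack.add(grid.like(layers[name], name=name))
    stack.add(pred_mod.emberger_q(stack["bio5"], stack["bio6"], stack["bio12"]))
    # terrain held constant under every scenario
    stack.add(grid.like(world.elevation, name="elevation"))
    stack.add(grid.like(world.water, name="water"))
    return stack


def _stage_predictors(config: RunConfig, outdir: Path, manifest: _Manifest, state: dict) -> None:
    seed = stage_seed(config.seed, "predictors")
    world: syn.SyntheticWorld = state["world"]
    current = _build_stack(world, "current", "current")
    sample = current.sample_frame(config.n_predictor_samples, seed)
    filtered, rep = pred_mod.filter_collinear(current, sample, r_max=config.r_max,
                                              vif_max=config.vif_max,
                                              keep=config.keep_predictors or None)
    selected = filtered.names
    stacks = {("current", "current"): filtered}
    for scenario in config.scenarios:
        for period in config.periods:
            stacks[(scenario, period)] = _build_stack(world, scenario, period).subset(selected)

    d = outdir / "predictors"
    for (scenario, period), stack in stacks.items():
        for name in stack.names:
            _write_grid(stack[name], d / f"{scenario}_{period}" / f"{name}.asc", manifest)
    with open(d / "collinearity_report.json", "w") as fh:
        json.dump({"kept": rep.kept, "dropped": rep.dropped, "clusters": rep.clusters,
                   "final_vif": rep.final_vif}, fh, indent=1)
    manifest.register(d / "collinearity_report.json")

    state.update(stacks=stacks, selected_predictors=selected, collinearity=rep)
    manifest.complete("predictors", n_predictors=len(selected))


def _stage_sdm(config: RunConfig, outdir: Path, manifest: _Manifest, state: dict) -> None:
    seed = stage_seed(config.seed, "sdm")
    stacks = state["stacks"]
    current = stacks[("current", "current")]
    areas = state["areas"]
    thin_df = state["occ_thinned"]
    bg_df = state["backgrounds"]

    eval_rows = []
    suit_maps: dict[tuple, dict[str, RasterGrid]] = {k: {} for k in stacks}
    bin_maps: dict[tuple, dict[str, RasterGrid]] = {k: {} for k in stacks}
    model_sets = {}
    for i, (species, area) in enumerate(sorted(areas.items())):
        occ = thin_df[thin_df["species"] == species]
        bg = bg_df[bg_df["species"] == species]
        try:
            data = sdm_mod.build_dataset(species, occ, bg, current)
            ms = sdm_mod.fit_learners(data, seed=seed + i,
                                      min_presences=config.min_presences,
                                      boyce_windows=config.boyce_windows,
                                      boyce_window_fraction=config.boyce_window_fraction,
                                      brt_estimators=config.brt_estimators)
            ms = sdm_mod.evaluate_and_finalize(data, ms, seed=seed + i,
                                               brt_estimators=config.brt_estimators)
        except ValueError as exc:
            logger.warning("sdm: skipping %s (%s)", species, exc)
            continue
        model_sets[species] = ms
        for name in ms.learners:
            eval_rows.append({
                "species": species, "learner": name,
                "auc": ms.auc_scores[name], "boyce": ms.boyce_scores[name],
                "best": name == ms.best_learner,
                "threshold": ms.threshold if name == ms.best_learner else np.nan,
                "low_quality": ms.low_quality,
            })
        for key, stack in stacks.items():
            smap, bmap = sdm_mod.project(ms, stack, area)
            suit_maps[key][species] = smap
            bin_maps[key][species] = bmap

    eval_df = pd.DataFrame(eval_rows)
    _write_csv(eval_df, outdir / "sdm" / "evaluation.csv", manifest)
    d = outdir / "sdm" / "maps"
    for (scenario, period), per_sp in bin_maps.items():
        for species, bmap in per_sp.items():
            _write_grid(bmap, d / f"binary_{species}_{scenario}_{period}.asc", manifest)

    state.update(model_sets=model_sets, suitability_maps=suit_maps, binary_maps=bin_maps,
                 evaluation=eval_df)
    n_flagged = sum(ms.low_quality for ms in model_sets.values())
    manifest.complete("sdm", n_modelled=len(model_sets), n_low_quality=n_flagged)


def _usable_species(state: dict) -> list[str]:
    """Species entering the community metrics: non-flagged models with trait
    and tree coverage."""
    model_sets = state["model_sets"]
    tree = state["tree"]
    traits = state["traits"]
    return sorted(s for s, ms in model_sets.items()
                  if not ms.low_quality and s in tree.tip_labels and s in traits.index)


def _stage_diversity(config: RunConfig, outdir: Path, manifest: _Manifest, state: dict) -> None:
    usable = _usable_species(state)
    if not usable:
        raise RuntimeError("diversity: no usable species (all models flagged)")
    traits = TraitTable(state["traits"].loc[usable])
    gower, order = gower_grouped(traits)
    ftree = build_dendrogram(gower, order)
    ptree, tree_report = load_tree(state["tree"].to_newick(), community=usable)

    bin_maps = state["binary_maps"]
    present = div.stack_maps({s: bin_maps[("current", "current")][s] for s in usable})
    d = outdir / "diversity"
    d.mkdir(parents=True, exist_ok=True)
    (d / "functional_dendrogram.nwk").write_text(ftree.to_newick() + "\n")
    manifest.register(d / "functional_dendrogram.nwk")
    pd.DataFrame(gower, index=order, columns=order).to_csv(d / "gower.csv")
    manifest.register(d / "gower.csv")

    summary_rows = []
    facet_results = {}
    for scenario in config.scenarios:
        for period in config.periods:
            future = div.stack_maps(
                {s: bin_maps[(scenario, period)][s] for s in usable},
                scenario=scenario, period=period)
            facets = div.facet_maps(present, future, functional_tree=ftree,
                                    phylogenetic_tree=ptree)
            facet_results[(scenario, period)] = facets
            for facet, fm in facets.items():
                _write_grid(fm.alpha_present, d / f"alpha_{facet}_current.asc", manifest)
                _write_grid(fm.alpha_future, d / f"alpha_{facet}_{scenario}_{period}.asc", manifest)
                _write_grid(fm.delta_alpha, d / f"delta_alpha_{facet}_{scenario}_{period}.asc", manifest)
                for comp_name, g in (("total", fm.beta_total), ("repl", fm.beta_repl),
                                     ("rich", fm.beta_rich)):
                    _write_grid(g, d / f"beta_{comp_name}_{facet}_{scenario}_{period}.asc", manifest)
                summary_rows.append({
                    "scenario": scenario, "period": period, "facet": facet,
                    "alpha_present_mean": float(fm.alpha_present.values.mean()),
                    "alpha_future_mean": float(fm.alpha_future.values.mean()),
                    "delta_alpha_mean": float(fm.delta_alpha.values.mean()),
                    "beta_total_mean": float(fm.beta_total.values.mean()),
                    "beta_repl_mean": float(fm.beta_repl.values.mean()),
                    "beta_rich_mean": float(fm.beta_rich.values.mean()),
                })
    _write_csv(pd.DataFrame(summary_rows), d / "summary.csv", manifest)
    state.update(facet_results=facet_results, usable_species=usable,
                 functional_tree=ftree, pruned_phylogeny=ptree, tree_report=tree_report)
    manifest.complete("diversity", n_community_species=len(usable))


def _stage_shift(config: RunConfig, outdir: Path, manifest: _Manifest, state: dict) -> None:
    usable = state.get("usable_species") or _usable_species(state)
    world: syn.SyntheticWorld = state["world"]
    elevation = world.layer(world.elevation, "elevation")
    bin_maps = state["binary_maps"]
    rows = []
    for scenario in config.scenarios:
        for period in config.periods:
            for species in usable:
                cur = bin_maps[("current", "current")][species]
                if cur.values.sum() == 0:
                    continue
                rows.append(rs.range_metrics(cur, bin_maps[(scenario, period)][species],
                                             elevation, species_id=species,
                                             scenario=scenario, period=period))
    shift_df = pd.DataFrame(rows)
    summary = rs.summarise_shifts(shift_df)
    _write_csv(shift_df, outdir / "rangeshift" / "shifts.csv", manifest)
    _write_csv(summary, outdir / "rangeshift" / "summary.csv", manifest)
    state.update(shift_table=shift_df, shift_summary=summary)
    manifest.complete("shift", n_shift_rows=len(shift_df))


def _stage_comparative(config: RunConfig, outdir: Path, manifest: _Manifest, state: dict) -> None:
    seed = stage_seed(config.seed, "comparative")
    shift_df = state["shift_table"]
    traits = state["traits"]
    tree = state["tree"]
    usable = state.get("usable_species") or _usable_species(state)
    tree_u = tree.prune(usable) if set(usable) != set(tree.tip_labels) else tree
    # two clade strata from the root split, mirroring a suborder-level rerun
    subsets = {"all": list(tree_u.tip_labels)}
    sets_ = tree_u.tip_sets()
    root_children = [u for u in range(tree_u.n_nodes) if tree_u.parent[u] == tree_u.root]
    for j, child in enumerate(sorted(root_children)):
        members = [tree_u.tip_labels[i] for i in np.flatnonzero(sets_[child])]
        subsets[f"clade_{chr(65 + j)}"] = members
    results = comp.run_comparative_suite(
        shift_df, traits, tree_u, subsets=subsets,
        n_permutations=config.n_permutations, seed=seed,
        transform=config.pgls_transform)
    _write_csv(results["signal"], outdir / "comparative" / "signal.csv", manifest)
    _write_csv(results["pgls"], outdir / "comparative" / "pgls.csv", manifest)
    _write_csv(pd.DataFrame({"stratum": results["skipped_strata"]}),
               outdir / "comparative" / "skipped_strata.csv", manifest)
    state.update(comparative=results)
    manifest.complete("comparative",
                      n_signal_rows=len(results["signal"]),
                      n_pgls_rows=len(results["pgls"]))


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "prep": _stage_prep,
    "predictors": _stage_predictors,
    "sdm": _stage_sdm,
    "diversity": _stage_diversity,
    "shift": _stage_shift,
    "comparative": _stage_comparative,
}


def run_all(config: RunConfig, outdir, stages: list[str] | None = None) -> dict:
    """Run the pipeline end-to-end (or a prefix of it).

    Returns the in-memory state dict (world, model sets, tables, maps);
    artefacts and the manifest are written under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest = _Manifest(outdir, config)
    state: dict = {}
    stages = stages or STAGES
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("pipeline: running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, outdir, manifest, state)
        except Exception:
            logger.error("pipeline: stage %s failed", stage)
            raise
    manifest.save()
    return state


def report(outdir) -> str:
    """Plain-text digest of a completed run (shift summary, PGLS table,
    alpha/beta facet summary)."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError("no manifest.json: not a run directory")
    manifest = json.loads(manifest_path.read_text())
    missing = [s for s in STAGES if s not in manifest["stages_completed"]]
    lines = ["facetshift run digest", "=" * 21,
             f"config hash: {manifest['config_hash'][:12]}",
             f"counts: {json.dumps(manifest['counts'], sort_keys=True)}"]
    if missing:
        lines.append(f"incomplete run; missing stages: {', '.join(missing)}")

    def add_table(title: str, path: Path) -> None:
        if path.exists():
            lines.append("")
            lines.append(title)
            lines.append("-" * len(title))
            try:
                df = pd.read_csv(path)
            except pd.errors.EmptyDataError:
                df = pd.DataFrame()
            lines.append("(empty)" if df.empty
                         else df.to_string(index=False, float_format="%.4g"))

    add_table("Range-shift summary (mean +/- SE, counts shifting north/up)",
              outdir / "rangeshift" / "summary.csv")
    add_table("Alpha/beta diversity summary per facet",
              outdir / "diversity" / "summary.csv")
    add_table("PGLS coefficients", outdir / "comparative" / "pgls.csv")
    add_table("Phylogenetic signal", outdir / "comparative" / "signal.csv")
    skipped_path = outdir / "comparative" / "skipped_strata.csv"
    if skipped_path.exists():
        try:
            for name in pd.read_csv(skipped_path)["stratum"]:
                lines.append(f"comparative stratum {name!r}: skipped (<4 species)")
        except pd.errors.EmptyDataError:
            pass
    text = "\n".join(lines) + "\n"
    (outdir / "digest.txt").write_text(text)
    return text
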