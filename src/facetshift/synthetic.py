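"""Synthetic study system with known ground truth.

Generates every input the pipeline consumes — monthly climate fields,
elevation and water layers, species with known logistic suitability
functions, occurrence records (including deliberately dirty ones), a
simulated phylogeny and traits evolved with a chosen level of phylogenetic
signal — so that each downstream stage has a recovery target.

The landscape is deliberately simple: climate = latitudinal gradient
+ elevation lapse + spatially autocorrelated noise (Gaussian-filtered white
noise), with a seasonal cycle over the 12 months.  Future scenarios are
additive temperature offsets and multiplicative precipitation factors; the
three named presets carry the labels of familiar global circulation models
but are parameter presets, not downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grids import RasterGrid
from .trees import FacetTree

__all__ = [
    "ScenarioOffsets", "SCENARIO_PRESETS", "WorldConfig", "SyntheticWorld",
    "generate_world", "TrueSpecies", "make_species_pool", "true_suitability",
    "sample_occurrences", "SimulatedPhylogeny", "simulate_pure_birth",
    "simulate_phylogeny_and_traits", "simulate_traits",
]

LAPSE_RATE = 6.5  # degC per km of elevation


@dataclass(frozen=True)
class ScenarioOffsets:
    """Additive temperature / multiplicative precipitation change per period."""

    temp_offset: dict[str, float]
    prec_factor: dict[str, float]


#: Named future-scenario presets (plausible mid-century / late-century
#: magnitudes under a moderate emission pathway).
SCENARIO_PRESETS: dict[str, ScenarioOffsets] = {
    "BCC-CSM1-1": ScenarioOffsets({"2050": 2.0, "2070": 2.6}, {"2050": 0.95, "2070": 0.92}),
    "MIROC-ESM-CHEM": ScenarioOffsets({"2050": 2.4, "2070": 3.2}, {"2050": 0.93, "2070": 0.90}),
    "NorESM1-M": ScenarioOffsets({"2050": 1.6, "2070": 2.1}, {"2050": 0.97, "2070": 0.95}),
}


@dataclass
class WorldConfig:
    """Parameters of the synthetic landscape."""

    grid_shape: tuple[int, int] = (60, 60)
    cell_size_deg: float = 0.1
    origin: tuple[float, float] = (5.0, 48.0)  # upper-left corner (lon, lat)
    mean_annual_temp: float = 12.0             # degC at the southern edge, sea level
    lat_gradient: float = 2.0                  # degC lost per degree northward
    seasonal_amplitude: float = 9.0            # degC, annual cycle half-range
    diurnal_range: float = 8.0                 # tmax - tmin, degC
    mean_monthly_prec: float = 60.0            # mm
    prec_seasonal_amplitude: float = 25.0      # mm
    noise_sigma_cells: float = 4.0             # Gaussian smoothing kernel width
    temp_noise_sd: float = 1.2                 # degC, spatial anomaly
    prec_noise_sd: float = 18.0                # mm, spatial anomaly
    elevation_scale: float = 700.0             # m
    water_fraction: float = 0.15               # share of cells flagged as water
    scenarios: dict[str, ScenarioOffsets] = field(
        default_factory=lambda: dict(SCENARIO_PRESETS))
    seed: int = 0


@dataclass
class SyntheticWorld:
    """Generated landscape: 12-month climate, terrain and future offsets."""

    config: WorldConfig
    monthly_tmin: np.ndarray   # (12, rows, cols) degC
    monthly_tmax: np.ndarray
    monthly_prec: np.ndarray   # mm
    elevation: np.ndarray      # m
    water: np.ndarray          # continuous water density in [0, 1]
    water_mask: np.ndarray     # bool

    @property
    def grid(self) -> RasterGrid:
        c = self.config
        return RasterGrid(np.zeros(c.grid_shape), origin=c.origin,
                          cell_size=c.cell_size_deg, name="template")

    def layer(self, values: np.ndarray, name: str) -> RasterGrid:
        return self.grid.like(values, name=name)

    def future_climate(self, scenario: str, period: str) -> "SyntheticWorld":
        """World with the scenario offsets applied (terrain held constant)."""
        off = self.config.scenarios[scenario]
        dt = off.temp_offset[period]
        pf = off.prec_factor[period]
        return replace(
            self,
            monthly_tmin=self.monthly_tmin + dt,
            monthly_tmax=self.monthly_tmax + dt,
            monthly_prec=self.monthly_prec * pf,
        )

    def study_area_polygon(self):
        """Rectangular study-area polygon (grid bounding box)."""
        from shapely.geometry import box

        c = self.config
        lon0, lat0 = c.origin
        return box(lon0, lat0 - c.grid_shape[0] * c.cell_size_deg,
                   lon0 + c.grid_shape[1] * c.cell_size_deg, lat0)


def _smooth_noise(rng: np.random.Generator, shape, sigma: float, sd: float) -> np.ndarray:
    """Spatially autocorrelated field: Gaussian-filtered white noise rescaled
    to the requested standard deviation."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    s = raw.std()
    return raw * (sd / s) if s > 0 else raw


def generate_world(config: WorldConfig | None = None, **overrides) -> SyntheticWorld:
    """Deterministically generate a synthetic world from its config + seed."""
    config = replace(config, **overrides) if config is not None else WorldConfig(**overrides)
    rows, cols = config.grid_shape
    if rows < 10 or cols < 10:
        raise ValueError("grid_shape must be at least 10 x 10")
    if config.cell_size_deg <= 0:
        raise ValueError("cell_size_deg must be positive")
    rng = np.random.default_rng(config.seed)

    lat0 = config.origin[1]
    lat = lat0 - (np.arange(rows) + 0.5) * config.cell_size_deg
    south_lat = lat.min()

    elevation = np.abs(_smooth_noise(rng, (rows, cols), config.noise_sigma_cells, 1.0)) \
        * config.elevation_scale
    water_field = _smooth_noise(rng, (rows, cols), config.noise_sigma_cells, 1.0)
    thresh = np.quantile(water_field, 1.0 - config.water_fraction)
    water_mask = water_field > thresh
    water = expit((water_field - thresh) * 3.0)  # continuous density, ~0.5 at mask edge

    base = (config.mean_annual_temp
            - config.lat_gradient * (lat - south_lat)[:, None]
            - LAPSE_RATE * elevation / 1000.0
            + _smooth_noise(rng, (rows, cols), config.noise_sigma_cells, config.temp_noise_sd))

    months = np.arange(12)
    season = config.seasonal_amplitude * np.cos(2 * np.pi * (months - 6) / 12.0)
    tmean = base[None, :, :] + season[:, None, None] \
        + _smooth_noise(rng, (12, rows, cols), (0, config.noise_sigma_cells, config.noise_sigma_cells), 0.4)
    tmin = tmean - config.diurnal_range / 2.0
    tmax = tmean + config.diurnal_range / 2.0

    prec_season = config.prec_seasonal_amplitude * np.cos(2 * np.pi * (months - 0) / 12.0)
    prec = (config.mean_monthly_prec + prec_season[:, None, None]
            + _smooth_noise(rng, (rows, cols), config.noise_sigma_cells, config.prec_noise_sd)[None, :, :]
            + _smooth_noise(rng, (12, rows, cols), (0, config.noise_sigma_cells, config.noise_sigma_cells), 5.0))
    prec = np.clip(prec, 0.0, None)

    return SyntheticWorld(config, tmin, tmax, prec, elevation, water, water_mask)


# ------------------------------------------------------------------- species

@dataclass
class TrueSpecies:
    """A species with a known logistic suitability function.

    ``coefficients`` maps feature names to weights of a logistic model
    ``suitability = expit(intercept + sum w_f * z_f)``; feature names are
    predictor layer names, optionally squared (``"bio10^2"``).  The quadratic
    term lets a species have a thermal optimum (a Gaussian-like niche on a
    logistic scale).
    """

    species_id: str
    intercept: float
    coefficients: dict[str, float]
    n_presences: int = 200
    flight_months: int = 5
    lentic: bool = True
    lotic: bool = False
    thermal_optimum: float | None = None  # degC on bio10, ground truth bookkeeping

    def __post_init__(self) -> None:
        if self.n_presences < 1:
            raise ValueError("n_presences must be >= 1")
        if not (self.lentic or self.lotic):
            raise ValueError("at least one habitat flag must be set")
        if not 1 <= self.flight_months <= 12:
            raise ValueError("flight_months must lie in 1..12")


def true_suitability(sp: TrueSpecies, layers: dict[str, np.ndarray]) -> np.ndarray:
    """Evaluate the species' logistic suitability on named predictor fields."""
    shape = next(iter(layers.values())).shape
    eta = np.full(shape, sp.intercept, dtype=float)
    for feat, w in sp.coefficients.items():
        if feat.endswith("^2"):
            eta += w * layers[feat[:-2]] ** 2
        else:
            eta += w * layers[feat]
    return expit(eta)


def make_species_pool(n_species: int, bio10_range: tuple[float, float], seed: int,
                      n_presences: int = 200) -> list[TrueSpecies]:
    """Species pool with thermal optima spread across the summer-temperature
    range.

    Each species has a Gaussian-like niche on bio10 (mean temperature of the
    warmest quarter) expressed as a logistic with linear + quadratic terms —
    ``eta = h - (bio10 - opt)^2 / (2 w^2)`` — plus a positive affinity for
    water-dense cells (freshwater insects concentrate around water bodies,
    which also gives the suitability surface structure *within* a species'
    accessible area).  Warming pushes every species' suitable band poleward.
    Flight period and habitat flags vary across species (they parameterise
    accessible-area buffers and the trait table).
    """
    rng = np.random.default_rng(seed)
    lo, hi = bio10_range
    optima = np.linspace(lo, hi, n_species)
    rng.shuffle(optima)
    pool = []
    for i in range(n_species):
        opt = float(optima[i])
        width = float(rng.uniform(1.0, 2.0))   # degC niche breadth
        height = float(rng.uniform(2.5, 4.5))  # logit at the optimum
        water_aff = float(rng.uniform(1.0, 2.5))
        a = -1.0 / (2.0 * width**2)
        lentic = bool(rng.random() < 0.7)
        lotic = bool(rng.random() < 0.6)
        if not (lentic or lotic):
            lentic = True
        pool.append(TrueSpecies(
            species_id=f"sp{i:03d}",
            intercept=height + a * opt**2 - 0.5 * water_aff,
            coefficients={"bio10": -2.0 * a * opt, "bio10^2": a, "water": water_aff},
            n_presences=n_presences,
            flight_months=int(rng.integers(3, 11)),
            lentic=lentic,
            lotic=lotic,
            thermal_optimum=opt,
        ))
    return pool


def sample_occurrences(
    world: SyntheticWorld,
    sp: TrueSpecies,
    seed: int,
    dirty_fraction: float = 0.0,
    layers: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Draw presence records with probability proportional to true suitability.

    Presence cells are drawn *without replacement* among non-water cells with
    probability proportional to the species' true suitability; coordinates
    are jittered uniformly within the cell.  A fraction of additional dirty
    records is appended to exercise cleaning: pre-1970 years, exact
    duplicates, huge coordinate uncertainty, and points outside the study
    area, round-robin.  The ``provenance`` column records which records are
    clean; total records = n_presences + n_dirty.

    Returns a DataFrame with columns species, lon, lat, year, uncertainty_m,
    provenance.
    """
    if layers is None:
        from .predictors import bioclim

        layers = bioclim(world.monthly_tmin, world.monthly_tmax, world.monthly_prec)
        layers = {**layers, "elevation": world.elevation, "water": world.water}
    rng = np.random.default_rng(seed)
    suit = true_suitability(sp, layers)
    grid = world.grid
    eligible = ~world.water_mask.ravel()
    n_eligible = int(eligible.sum())
    if sp.n_presences > n_eligible:
        raise ValueError(f"n_presences={sp.n_presences} exceeds {n_eligible} land cells")
    p = suit.ravel() * eligible
    total = p.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere on land")
    cells = rng.choice(p.size, size=sp.n_presences, replace=False, p=p / total)
    r, c = np.unravel_index(cells, grid.shape)
    lon0, lat0 = grid.origin
    cs = grid.cell_size
    lon = lon0 + (c + rng.uniform(0, 1, size=c.size)) * cs
    lat = lat0 - (r + rng.uniform(0, 1, size=r.size)) * cs
    year = rng.integers(1990, 2021, size=r.size)
    unc = rng.uniform(100.0, 0.5 * cs * 111320.0, size=r.size)

    df = pd.DataFrame({
        "species": sp.species_id, "lon": lon, "lat": lat,
        "year": year, "uncertainty_m": unc, "provenance": "clean",
    })

    n_dirty = int(round(dirty_fraction * sp.n_presences))
    kinds = ["pre1970", "duplicate", "high_uncertainty", "outside"]
    dirty_rows = []
    for k in range(n_dirty):
        kind = kinds[k % len(kinds)]
        base = df.iloc[int(rng.integers(0, len(df)))]
        row = {"species": sp.species_id, "lon": float(base.lon), "lat": float(base.lat),
               "year": int(base.year), "uncertainty_m": float(base.uncertainty_m),
               "provenance": f"dirty:{kind}"}
        if kind == "pre1970":
            row["year"] = int(rng.integers(1900, 1970))
            row["lon"] += cs * 0.01 * (k + 1)  # not a duplicate coordinate
        elif kind == "duplicate":
            pass  # exact coordinate copy of an existing clean record
        elif kind == "high_uncertainty":
            row["uncertainty_m"] = float(rng.uniform(5, 50) * cs * 111320.0)
            row["lat"] -= cs * 0.01 * (k + 1)
        elif kind == "outside":
            row["lon"] = lon0 + (grid.n_cols + 2 + k) * cs
        dirty_rows.append(row)
    if dirty_rows:
        df = pd.concat([df, pd.DataFrame(dirty_rows)], ignore_index=True)
    return df


# ----------------------------------------------------------------- phylogeny

@dataclass
class SimulatedPhylogeny:
    """Pure-birth tree plus traits simulated at a known signal level."""

    tree: FacetTree
    trait_values: pd.DataFrame  # tips x traits
    generating_lambda: float
    brownian_rate: float


def simulate_pure_birth(n_tips: int, birth_rate: float, seed: int,
                        labels: list[str] | None = None) -> FacetTree:
    """Exact pure-birth (Yule) tree; ultrametric by construction.

    Lineages split at exponential waiting times with total rate
    ``k * birth_rate``; the process stops when ``n_tips`` lineages exist, and
    all tips extend to the stopping time.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    labels = list(labels) if labels is not None else [f"sp{i:03d}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")

    m = 2 * n_tips - 1
    parent_arr = np.full(m, -1, dtype=int)
    length_arr = np.zeros(m)
    root_id = n_tips
    next_id = n_tips + 1
    # active lineages: (parent node id, time the lineage's edge began)
    active: list[tuple[int, float]] = [(root_id, 0.0), (root_id, 0.0)]
    t = 0.0
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(0, k))
        p, start = active.pop(idx)
        v = next_id
        next_id += 1
        parent_arr[v] = p
        length_arr[v] = t - start
        active.extend([(v, t), (v, t)])
        k += 1
    t_end = t + rng.exponential(1.0 / (birth_rate * k))

    order = rng.permutation(n_tips)  # random assignment of labels to lineages
    for i, (p, start) in enumerate(active):
        tip = int(order[i])
        parent_arr[tip] = p
        length_arr[tip] = t_end - start
    return FacetTree(parent_arr, length_arr, labels, kind="phylogenetic")


def simulate_traits(tree: FacetTree, lambda_signal: float, rate: float,
                    seed: int, n_traits: int = 1, names: list[str] | None = None) -> pd.DataFrame:
    """Continuous traits under BM on the lambda-transformed tree.

    Covariance = rate * C_lambda with off-diagonals of the BM matrix scaled
    by ``lambda_signal`` (0 = independent tips, 1 = plain BM).
    """
    if not 0.0 <= lambda_signal <= 1.0:
        raise ValueError("lambda_signal must lie in [0, 1]")
    from .comparative import lambda_transform

    rng = np.random.default_rng(seed)
    c = lambda_transform(tree.cov_matrix(), lambda_signal) * rate
    chol = np.linalg.cholesky(c + 1e-12 * np.eye(tree.n_tips))
    z = rng.standard_normal((tree.n_tips, n_traits))
    vals = chol @ z
    names = names or [f"trait{j}" for j in range(n_traits)]
    return pd.DataFrame(vals, index=tree.tip_labels, columns=names)


def simulate_phylogeny_and_traits(n_tips: int, birth_rate: float, lambda_signal: float,
                                  seed: int, rate: float = 1.0,
                                  n_traits: int = 1) -> SimulatedPhylogeny:
    """Pure-birth tree plus traits at a known lambda (parameter-recovery
    ground truth for the signal statistics)."""
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    tree = simulate_pure_birth(n_tips, birth_rate, seed)
    traits = simulate_traits(tree, lambda_signal, rate, seed + 1, n_traits=n_traits)
    return SimulatedPhylogeny(tree, traits, lambda_signal, rate)


def synthetic_trait_table(pool: list[TrueSpecies], tree: FacetTree, seed: int) -> pd.DataFrame:
    """Trait table for the species pool, evolving the body measurements and
    colour along the simulated tree (BM, lambda = 1) and taking habitat and
    flight period from the species' own ground truth."""
    base = simulate_traits(tree, 1.0, 1.0, seed, n_traits=4,
                           names=["z_body", "z_abd", "z_wing", "z_col"])

    def scale(z, lo, hi):
        zn = (z - z.min()) / max(z.max() - z.min(), 1e-12)
        return lo + zn * (hi - lo)

    rows = {}
    rng = np.random.default_rng(seed + 7)
    for sp in pool:
        z = base.loc[sp.species_id]
        rows[sp.species_id] = {
            "body_length_mm": scale(base["z_body"], 25, 85).loc[sp.species_id],
            "abdomen_length_mm": scale(base["z_abd"], 18, 60).loc[sp.species_id],
            "wing_length_mm": scale(base["z_wing"], 15, 55).loc[sp.species_id],
            "abdomen_r": float(np.clip(128 + 60 * z["z_col"], 0, 255)),
            "abdomen_g": float(rng.integers(40, 200)),
            "abdomen_b": float(rng.integers(40, 200)),
            "lentic": int(sp.lentic),
            "lotic": int(sp.lotic),
            "flight_months": int(sp.flight_months),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
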