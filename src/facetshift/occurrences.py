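"""Occurrence cleaning, spatial thinning, accessible areas and background
points.

Occurrence sets are tidy DataFrames with columns ``species``, ``lon``,
``lat``, ``year``, ``uncertainty_m`` (and optionally ``provenance``).  The
accessible area of a species — the extent within its long-term dispersal
reach — is a minimum convex polygon of its records (after trimming a small
percentage of centroid-distance outliers) buffered by a distance that scales
with flight-period length: 10 km of buffer per month of flight season.

Metric operations (buffering, distances) use a spherical Earth; buffering is
done in a local equirectangular projection centred on the polygon, which is
accurate to well under a percent at the few-hundred-km scales involved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import transform as shp_transform

from .grids import RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "clean_records", "UnmodellableSpeciesError", "thin_spatially",
    "AccessibleArea", "accessible_area", "sample_background",
    "haversine_m", "EARTH_RADIUS_M", "METERS_PER_DEGREE",
]

EARTH_RADIUS_M = 6371008.8
METERS_PER_DEGREE = EARTH_RADIUS_M * math.pi / 180.0  # meridian metres per degree

#: buffer metres per month of flight period: 100 000 * months / 10
BUFFER_M_PER_MONTH = 100000.0 / 10.0

MIN_YEAR = 1970
COORD_DECIMALS = 6  # dedupe after rounding: sub-metre noise must not defeat it


class UnmodellableSpeciesError(ValueError):
    """Raised when cleaning leaves no usable records for a species."""


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in metres on a sphere of radius 6 371 008.8 m."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def clean_records(raw: pd.DataFrame, study_area: Polygon,
                  max_uncertainty_m: float = 11132.0) -> pd.DataFrame:
    """Drop unusable occurrence records.

    Removes records from before 1970, outside the study-area polygon, with
    coordinate uncertainty above ``max_uncertainty_m`` (default ~ one 0.1-deg
    grid cell), and duplicate coordinates (after rounding to 6 decimals; the
    surviving duplicate is chosen by sorting, so the result is independent of
    input order).  The default uncertainty cap corresponds to the working
    grid resolution.

    Raises
    ------
    UnmodellableSpeciesError
        If no record survives — such species are excluded from modelling.
    """
    if raw.empty:
        raise UnmodellableSpeciesError("empty occurrence set")
    df = raw.copy()
    df = df[df["year"] >= MIN_YEAR]
    if "uncertainty_m" in df.columns:
        df = df[df["uncertainty_m"] <= max_uncertainty_m]
    if not df.empty:
        inside = shapely.contains_xy(study_area, df["lon"].to_numpy(), df["lat"].to_numpy())
        df = df[inside]
    if not df.empty:
        key_lon = df["lon"].round(COORD_DECIMALS)
        key_lat = df["lat"].round(COORD_DECIMALS)
        df = (df.assign(_klon=key_lon, _klat=key_lat)
                .sort_values(list(df.columns))
                .drop_duplicates(subset=["_klon", "_klat"], keep="first")
                .drop(columns=["_klon", "_klat"])
                .sort_index())
    if df.empty:
        species = raw["species"].iloc[0] if "species" in raw.columns else "?"
        raise UnmodellableSpeciesError(f"no usable records for species {species!r}")
    return df.reset_index(drop=True)


def thin_spatially(occ: pd.DataFrame, min_distance_cells: float,
                   cell_size_deg: float, seed: int = 0) -> pd.DataFrame:
    """Greedy spatial thinning to a minimum pairwise great-circle distance.

    The threshold is ``min_distance_cells`` grid cells, converted to metres
    at the meridian scale (one 0.1-deg cell ~ 11.1 km).  While any pair is
    closer than the threshold, the record with the most neighbours inside the
    radius is removed; ties are broken by a seeded random choice.  The output
    is a subset of the input rows.
    """
    if min_distance_cells <= 0:
        raise ValueError("min_distance_cells must be positive")
    n = len(occ)
    if n < 2:
        return occ.copy()
    threshold_m = min_distance_cells * cell_size_deg * METERS_PER_DEGREE
    lon = occ["lon"].to_numpy(dtype=float)
    lat = occ["lat"].to_numpy(dtype=float)
    d = haversine_m(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    close = d < threshold_m
    np.fill_diagonal(close, False)

    rng = np.random.default_rng(seed)
    alive = np.ones(n, dtype=bool)
    counts = close.sum(axis=1)
    while True:
        counts_alive = np.where(alive, counts, -1)
        top = counts_alive.max()
        if top <= 0:
            break
        ties = np.flatnonzero(counts_alive == top)
        victim = int(rng.choice(ties))
        alive[victim] = False
        counts[close[victim]] -= 1
        counts[victim] = 0
    return occ.iloc[np.flatnonzero(alive)].copy()


@dataclass
class AccessibleArea:
    """Minimum convex polygon of a species' records plus a dispersal buffer."""

    species_id: str
    mcp: Polygon
    buffer_m: float
    buffered: Polygon

    def __post_init__(self) -> None:
        if self.buffer_m < 0:
            raise ValueError("buffer_m must be non-negative")
        if not self.buffered.covers(self.mcp.buffer(-1e-9)):
            raise ValueError("buffered polygon does not contain the MCP")


def _local_metric_transforms(poly_or_points):
    """Forward/inverse maps between lon/lat degrees and metres in a local
    equirectangular frame centred on the geometry's centroid."""
    cen = poly_or_points.centroid
    lat0 = math.radians(cen.y)
    kx = METERS_PER_DEGREE * math.cos(lat0)
    ky = METERS_PER_DEGREE

    def fwd(x, y):
        return ((np.asarray(x) - cen.x) * kx, (np.asarray(y) - cen.y) * ky)

    def inv(x, y):
        return (np.asarray(x) / kx + cen.x, np.asarray(y) / ky + cen.y)

    return fwd, inv


def accessible_area(occ: pd.DataFrame, flight_months: int,
                    outlier_pct: float = 0.01,
                    buffer_m_per_month: float = BUFFER_M_PER_MONTH,
                    species_id: str | None = None) -> AccessibleArea:
    """Accessible area: outlier-trimmed MCP with a flight-period buffer.

    The ``ceil(outlier_pct * n)`` records farthest from the coordinate
    centroid are discarded (so 1% trims one point of a hundred); the convex
    hull of the rest is buffered by ``buffer_m_per_month * flight_months``
    metres (default 10 km per month of flight period) in a local metric
    frame.
    """
    if not 0 <= outlier_pct < 1:
        raise ValueError("outlier_pct must lie in [0, 1)")
    lon = occ["lon"].to_numpy(dtype=float)
    lat = occ["lat"].to_numpy(dtype=float)
    n = lon.size
    n_drop = math.ceil(outlier_pct * n) if outlier_pct > 0 else 0
    if n - n_drop < 3:
        raise ValueError("fewer than 3 points left for the MCP")
    if n_drop:
        cen_lon, cen_lat = lon.mean(), lat.mean()
        d = haversine_m(lon, lat, cen_lon, cen_lat)
        keep = np.argsort(d)[: n - n_drop]
        lon, lat = lon[keep], lat[keep]
    hull = MultiPoint(list(zip(lon, lat))).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("points are collinear: MCP is degenerate")
    buffer_m = buffer_m_per_month * flight_months
    fwd, inv = _local_metric_transforms(hull)
    metric_hull = shp_transform(fwd, hull)
    buffered = shp_transform(inv, metric_hull.buffer(buffer_m, quad_segs=32))
    sp = species_id or (occ["species"].iloc[0] if "species" in occ.columns else "?")
    return AccessibleArea(sp, hull, buffer_m, buffered)


def sample_background(area: AccessibleArea, n_presences: int, grid: RasterGrid,
                      seed: int = 0,
                      presence_cells: set[tuple[int, int]] | None = None,
                      factor: int = 2) -> pd.DataFrame:
    """Background (pseudo-absence) points inside the buffered accessible area.

    Returns exactly ``factor * n_presences`` points (default: twice the
    presences) at the centres of grid cells chosen uniformly *without*
    replacement among eligible cells (inside the buffered polygon, not a
    presence cell).  If fewer eligible cells exist than points requested, the
    draw falls back to sampling with replacement and logs a warning.
    """
    n_points = factor * n_presences
    lons, lats = np.meshgrid(grid.lon_centers(), grid.lat_centers())
    inside = shapely.contains_xy(area.buffered, lons.ravel(), lats.ravel())
    rows, cols = np.unravel_index(np.flatnonzero(inside), grid.shape)
    if presence_cells:
        keep = [i for i, rc in enumerate(zip(rows, cols)) if (rc[0], rc[1]) not in presence_cells]
        rows, cols = rows[keep], cols[keep]
    if rows.size == 0:
        raise ValueError("buffered polygon contains no eligible grid cells")
    rng = np.random.default_rng(seed)
    if rows.size >= n_points:
        pick = rng.choice(rows.size, size=n_points, replace=False)
    else:
        logger.warning("sample_background: only %d eligible cells for %d points; "
                       "sampling with replacement", rows.size, n_points)
        pick = rng.choice(rows.size, size=n_points, replace=True)
    rr, cc = rows[pick], cols[pick]
    lon0, lat0 = grid.origin
    cs = grid.cell_size
    return pd.DataFrame({
        "species": area.species_id,
        "lon": lon0 + (cc + 0.5) * cs,
        "lat": lat0 - (rr + 0.5) * cs,
        "row": rr, "col": cc,
    })
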