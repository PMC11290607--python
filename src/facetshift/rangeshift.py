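"""Per-species range-shift response metrics.

From a species' current and future binary range maps: the ratio of future to
current range size (relative area change), the difference in mean elevation
over suitable cells (altitude difference, m), the great-circle distance
between range centroids (centroid difference, m) and the signed centroid
latitude shift (degrees, positive = poleward in the northern hemisphere).
Centroids are unweighted means of suitable-cell centre coordinates; a
cos(latitude) area weighting is available as an option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import RasterGrid
from .occurrences import haversine_m

__all__ = ["range_metrics", "summarise_shifts", "gain_loss_map"]


def _centroid(mask: np.ndarray, grid: RasterGrid, area_weighted: bool) -> tuple[float, float]:
    rows, cols = np.nonzero(mask)
    lon = grid.origin[0] + (cols + 0.5) * grid.cell_size
    lat = grid.origin[1] - (rows + 0.5) * grid.cell_size
    if area_weighted:
        w = np.cos(np.radians(lat))
        return float(np.average(lon, weights=w)), float(np.average(lat, weights=w))
    return float(lon.mean()), float(lat.mean())


def range_metrics(current: RasterGrid, future: RasterGrid, elevation: RasterGrid,
                  species_id: str = "", scenario: str = "", period: str = "",
                  area_weighted_centroid: bool = False) -> dict:
    """Response metrics for one species x scenario x period.

    ``current`` must be non-empty.  If the future range is empty, the area
    ratio is 0 and altitude/centroid differences are missing (NaN).
    """
    for g in (future, elevation):
        if not g.same_grid(current):
            raise ValueError("maps and elevation must share the grid")
    cur = current.values > 0.5
    fut = future.values > 0.5
    n_cur = int(cur.sum())
    n_fut = int(fut.sum())
    if n_cur == 0:
        raise ValueError("current range is empty")
    row = {
        "species": species_id, "scenario": scenario, "period": period,
        "current_cells": n_cur, "future_cells": n_fut,
        "relative_area_change": n_fut / n_cur,
    }
    if n_fut == 0:
        row.update(altitude_difference=np.nan, centroid_difference=np.nan,
                   centroid_latitude_shift=np.nan)
        return row
    row["altitude_difference"] = float(elevation.values[fut].mean()
                                       - elevation.values[cur].mean())
    lon_c, lat_c = _centroid(cur, current, area_weighted_centroid)
    lon_f, lat_f = _centroid(fut, current, area_weighted_centroid)
    row["centroid_difference"] = float(haversine_m(lon_c, lat_c, lon_f, lat_f))
    row["centroid_latitude_shift"] = lat_f - lat_c
    return row


def summarise_shifts(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- standard error of the shifts per scenario x period, with the
    counts of species shifting poleward / upward.

    SE = sd / sqrt(n) (ddof=1); undefined (NaN) for a single species.
    """
    if table.empty:
        raise ValueError("empty shift table")

    def agg(grp: pd.DataFrame) -> pd.Series:
        out = {}
        n = len(grp)
        for metric in ("centroid_latitude_shift", "altitude_difference",
                       "relative_area_change", "centroid_difference"):
            if metric not in grp.columns:
                continue
            v = grp[metric].dropna()
            out[f"{metric}_mean"] = v.mean()
            out[f"{metric}_se"] = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
        out["n_species"] = n
        if "centroid_latitude_shift" in grp.columns:
            out["n_northward"] = int((grp["centroid_latitude_shift"] > 0).sum())
        if "altitude_difference" in grp.columns:
            out["n_upward"] = int((grp["altitude_difference"] > 0).sum())
        return pd.Series(out)

    return table.groupby(["scenario", "period"]).apply(agg, include_groups=False).reset_index()


def gain_loss_map(current: RasterGrid, future: RasterGrid) -> RasterGrid:
    """Per-cell gain/loss raster: +1 gained, -1 lost, 0 stable/absent."""
    cur = current.values > 0.5
    fut = future.values > 0.5
    vals = np.zeros(cur.shape)
    vals[fut & ~cur] = 1.0
    vals[cur & ~fut] = -1.0
    return current.like(vals, name="gain_loss")
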