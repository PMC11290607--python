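"""Georeferenced regular lon/lat grids.

:class:`RasterGrid` is the common currency of the whole pipeline: climate
predictors, habitat-suitability surfaces, binary range maps and diversity maps
are all 2-D fields on a shared regular grid.  Row 0 is the northernmost row
(the usual raster convention); cell values refer to cell centres.

Grids round-trip through the plain-text ESRI ASCII grid format
(``.asc``: a 6-line header followed by whitespace-separated rows), which every
GIS reads and which keeps the artefacts human-inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RasterGrid", "PredictorStack", "resample_bilinear"]

_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single named 2-D field on a regular geographic grid.

    Parameters
    ----------
    values : ndarray (rows, cols)
        Cell values; rows run north to south.
    origin : (lon, lat)
        Coordinates of the *upper-left corner* of the grid (not a cell centre).
    cell_size : float
        Cell edge in decimal degrees (square cells).
    name : str
        Layer name (``"bio10"``, ``"alpha_PD"``, ...).
    mask : ndarray of bool, optional
        True where the cell holds no data.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    name: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def lon_centers(self) -> np.ndarray:
        lon0 = self.origin[0]
        return lon0 + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        lat0 = self.origin[1]
        return lat0 - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin[0] + (col + 0.5) * self.cell_size,
            self.origin[1] - (row + 0.5) * self.cell_size,
        )

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing (lon, lat); raises if outside."""
        col = int(np.floor((lon - self.origin[0]) / self.cell_size))
        row = int(np.floor((self.origin[1] - lat) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({lon}, {lat}) outside grid")
        return row, col

    def indices_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised :meth:`index_of`; points outside get row/col = -1."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.origin[1] - lat) / self.cell_size).astype(int)
        bad = (row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)
        row[bad] = -1
        col[bad] = -1
        return row, col

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) < tol
            and abs(self.origin[0] - other.origin[0]) < tol
            and abs(self.origin[1] - other.origin[1]) < tol
        )

    def like(self, values: np.ndarray, name: str = "", mask: np.ndarray | None = None) -> "RasterGrid":
        """New grid sharing this grid's georeferencing."""
        return RasterGrid(values=np.asarray(values, dtype=float), origin=self.origin,
                          cell_size=self.cell_size, name=name, mask=mask)

    # --------------------------------------------------------------------- I/O
    def to_ascii(self, path) -> None:
        """Write as ESRI ASCII grid (masked cells become the nodata value)."""
        vals = self.values.copy()
        if self.mask is not None:
            vals[self.mask] = _NODATA
        yll = self.origin[1] - self.n_rows * self.cell_size
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.origin[0]:.10g}\n"
            f"yllcorner {yll:.10g}\n"
            f"cellsize {self.cell_size:.10g}\n"
            f"NODATA_value {_NODATA:.10g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.8g")

    @classmethod
    def from_ascii(cls, path, name: str = "") -> "RasterGrid":
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        nrows = int(hdr["nrows"])
        ncols = int(hdr["ncols"])
        if vals.shape != (nrows, ncols):
            raise ValueError(f"ASCII grid body {vals.shape} does not match header ({nrows}, {ncols})")
        nodata = hdr.get("nodata_value", _NODATA)
        mask = vals == nodata
        origin = (hdr["xllcorner"], hdr["yllcorner"] + nrows * hdr["cellsize"])
        return cls(values=vals, origin=origin, cell_size=hdr["cellsize"], name=name,
                   mask=mask if mask.any() else None)


@dataclass
class PredictorStack:
    """An ordered set of co-registered predictor layers.

    All layers must share the reference grid; layers on a different grid must
    be bilinearly resampled (:func:`resample_bilinear`) before stacking.
    """

    layers: dict[str, RasterGrid] = field(default_factory=dict)
    scenario: str = "current"
    period: str = "current"

    def __post_init__(self) -> None:
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names in stack")
        ref = None
        for name, layer in self.layers.items():
            if ref is None:
                ref = layer
            elif not layer.same_grid(ref):
                raise ValueError(f"layer {name!r} is not on the reference grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def add(self, layer: RasterGrid, name: str | None = None) -> None:
        name = name or layer.name
        if not name:
            raise ValueError("layer needs a name")
        if name in self.layers:
            raise ValueError(f"duplicate layer name {name!r}")
        if self.layers and not layer.same_grid(self.grid):
            raise ValueError(f"layer {name!r} is not on the reference grid")
        self.layers[name] = layer

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def subset(self, names: list[str]) -> "PredictorStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers missing from stack: {missing}")
        return PredictorStack({n: self.layers[n] for n in names},
                              scenario=self.scenario, period=self.period)

    def as_matrix(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> np.ndarray:
        """Cell values as an (n_cells, n_layers) matrix.

        With no arguments, all cells in row-major order.
        """
        if rows is None:
            mats = [g.values.ravel() for g in self.layers.values()]
        else:
            mats = [g.values[rows, cols] for g in self.layers.values()]
        return np.column_stack(mats)

    def sample_frame(self, n: int, seed: int):
        """Random cell sample of all layers as a pandas DataFrame (for the
        collinearity analysis)."""
        import pandas as pd

        rng = np.random.default_rng(seed)
        grid = self.grid
        total = grid.n_rows * grid.n_cols
        idx = rng.choice(total, size=min(n, total), replace=False)
        rows, cols = np.unravel_index(idx, grid.shape)
        return pd.DataFrame(self.as_matrix(rows, cols), columns=self.names)


def resample_bilinear(src: RasterGrid, ref: RasterGrid, name: str | None = None) -> RasterGrid:
    """Bilinearly resample ``src`` onto the grid of ``ref``.

    Sampling happens at ``ref``'s cell centres in geographic coordinates;
    points beyond ``src``'s centre lattice are clamped to the edge (constant
    extrapolation).
    """
    from scipy.interpolate import RegularGridInterpolator

    # interpolator wants ascending axes; src rows run north->south
    lats = src.lat_centers()[::-1]
    lons = src.lon_centers()
    interp = RegularGridInterpolator(
        (lats, lons), src.values[::-1, :], method="linear", bounds_error=False, fill_value=None
    )
    ref_lon, ref_lat = np.meshgrid(ref.lon_centers(), ref.lat_centers())
    pts = np.column_stack([
        np.clip(ref_lat.ravel(), lats[0], lats[-1]),
        np.clip(ref_lon.ravel(), lons[0], lons[-1]),
    ])
    out = interp(pts).reshape(ref.shape)
    return replace(ref, values=out, name=name or src.name, mask=None)
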