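"""Regular geographic grids and a plain-text raster format.

A :class:`GridLayer` is a single-band raster on a regular WGS84 grid:
a 2-D value array plus the geotransform (west edge, north edge, cell
sizes). Row 0 is the northernmost row. Cells are half-open intervals
``[x, x + dx) x (y - dy, y]`` so that any point on a shared edge belongs
to exactly one cell and point sampling is deterministic.

Layers are serialised as ESRI ASCII grids (``.asc``), a widely supported
plain-text raster format; a :class:`RasterStack` is a set of layers
sharing one grid geometry, written as one ``.asc`` per layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["GridLayer", "RasterStack", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class GridLayer:
    """Single-band raster on a regular WGS84 grid (row 0 = north)."""

    name: str
    values: np.ndarray          # 2-D float array, NaN marks nodata
    x0: float                   # west edge of the grid (deg lon)
    y0: float                   # north edge of the grid (deg lat)
    dx: float                   # cell width (deg)
    dy: float                   # cell height (deg)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("GridLayer values must be 2-D")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) edges in degrees."""
        return (self.x0, self.y0 - self.nrows * self.dy,
                self.x0 + self.ncols * self.dx, self.y0)

    def lon_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.ncols) + 0.5) * self.dx

    def lat_centers(self) -> np.ndarray:
        return self.y0 - (np.arange(self.nrows) + 0.5) * self.dy

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of cell-centre (lon, lat), each shaped (nrows, ncols)."""
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    def cell_index(self, lons, lats) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col) under the half-open cell convention.

        Returns (rows, cols, inside) where ``inside`` flags points that
        fall within the grid extent. Out-of-extent points get row/col -1.
        """
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        tx = (lons - self.x0) / self.dx
        ty = (self.y0 - lats) / self.dy
        cols = np.floor(tx).astype(int)
        # top edge of a cell is inclusive: lat exactly on the boundary
        # y0 - k*dy belongs to row k (ty == k -> row k); floor handles it.
        rows = np.floor(ty).astype(int)
        inside = (cols >= 0) & (cols < self.ncols) & (rows >= 0) & (rows < self.nrows) \
            & (tx >= 0) & (ty >= 0)
        rows = np.where(inside, rows, -1)
        cols = np.where(inside, cols, -1)
        return rows, cols, inside

    def sample(self, lons, lats) -> np.ndarray:
        """Value of the containing cell per point; NaN outside the extent."""
        rows, cols, inside = self.cell_index(lons, lats)
        out = np.full(np.shape(rows), np.nan, dtype=float)
        if np.any(inside):
            out[inside] = self.values[rows[inside], cols[inside]]
        return out

    def same_grid(self, other: "GridLayer", tol: float = 1e-9) -> bool:
        return (self.values.shape == other.values.shape
                and abs(self.x0 - other.x0) < tol and abs(self.y0 - other.y0) < tol
                and abs(self.dx - other.dx) < tol and abs(self.dy - other.dy) < tol)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "GridLayer":
        return replace(self, values=np.asarray(values, dtype=float),
                       name=self.name if name is None else name)


@dataclass
class RasterStack:
    """Named raster layers sharing one grid geometry."""

    layers: dict[str, GridLayer] = field(default_factory=dict)

    def add(self, layer: GridLayer) -> None:
        if self.layers:
            ref = next(iter(self.layers.values()))
            if not ref.same_grid(layer):
                raise ValueError(f"layer {layer.name!r} is not on the stack grid")
        self.layers[layer.name] = layer

    def __getitem__(self, name: str) -> GridLayer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self):
        return iter(self.layers.values())

    def __len__(self) -> int:
        return len(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> GridLayer:
        """A reference layer carrying the shared grid geometry."""
        if not self.layers:
            raise ValueError("empty stack has no grid")
        return next(iter(self.layers.values()))

    def sample(self, lons, lats, names: list[str] | None = None) -> dict[str, np.ndarray]:
        names = self.names if names is None else names
        return {n: self.layers[n].sample(lons, lats) for n in names}

    def write_dir(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        return [write_ascii_grid(layer, directory / f"{layer.name}.asc")
                for layer in self]

    @classmethod
    def read_dir(cls, directory: str | Path) -> "RasterStack":
        stack = cls()
        for path in sorted(Path(directory).glob("*.asc")):
            stack.add(read_ascii_grid(path))
        return stack


def write_ascii_grid(layer: GridLayer, path: str | Path, nodata: float = -9999.0) -> Path:
    """Write a layer as an ESRI ASCII grid (square cells required)."""
    if not math.isclose(layer.dx, layer.dy, rel_tol=1e-9):
        raise ValueError("ESRI ASCII grids require square cells (dx == dy)")
    path = Path(path)
    vals = np.where(np.isnan(layer.values), nodata, layer.values)
    header = (f"ncols {layer.ncols}\n"
              f"nrows {layer.nrows}\n"
              f"xllcorner {layer.x0:.10f}\n"
              f"yllcorner {layer.y0 - layer.nrows * layer.dy:.10f}\n"
              f"cellsize {layer.dx:.10f}\n"
              f"NODATA_value {nodata}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")
    return path


def read_ascii_grid(path: str | Path) -> GridLayer:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        vals = np.loadtxt(fh, dtype=float, ndmin=2)
    nodata = header.get("nodata_value", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    cell = header["cellsize"]
    return GridLayer(name=path.stem, values=vals,
                     x0=header["xllcorner"],
                     y0=header["yllcorner"] + header["nrows"] * cell,
                     dx=cell, dy=cell)
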