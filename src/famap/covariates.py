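"""Point-level covariate preparation.

Survey locations are published displaced and clustered (several
households at one point); kriging needs unique locations, so coincident
points are re-jittered by a small random offset (<= 50 m by default).
Covariate rasters are aggregated to the analysis resolution (5
arc-minutes by default, ~10 km at the equator) and sampled at the
household points. Soil carbon stock is derived from bulk density and
soil organic carbon over three depth layers:

    SCARB_i = BD_i * dz_i * SOC_i * 1e4,   mean over layers i

computed literally per layer and averaged. (The source tabulates SCARB
with unit kg C Mg-1, which is not dimensionally consistent with
BD * dz * SOC * 1e4 — the product is a mass of carbon per hectare per
layer; the formula is reproduced as printed and the unit question is
documented in the methods note.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import destination_point
from .grids import GridLayer, RasterStack

__all__ = ["jitter_duplicates", "resample_stack", "sample_at_points",
           "compute_scarb", "SoilProfileStack", "SOIL_LAYER_THICKNESS_M"]

#: Depth-layer thicknesses (m) for 0-5 cm, 5-15 cm and 15-30 cm.
SOIL_LAYER_THICKNESS_M = (0.05, 0.10, 0.15)


def jitter_duplicates(lons, lats, max_offset_m: float = 50.0,
                      seed: int | np.random.Generator = 0,
                      max_retries: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Displace points by <= max_offset_m at uniform random bearing until unique.

    Every point is moved (uniform distance in [0, max_offset_m], uniform
    bearing); residual collisions are re-jittered, up to ``max_retries``
    rounds. Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lons = np.asarray(lons, dtype=float).copy()
    lats = np.asarray(lats, dtype=float).copy()
    n = lons.size
    if max_offset_m == 0:
        if len(set(zip(lons, lats))) < n:
            raise ValueError("coincident points cannot be separated with "
                             "max_offset_m == 0")
        return lons, lats

    out_lon, out_lat = lons.copy(), lats.copy()
    todo = np.ones(n, dtype=bool)
    for _ in range(max_retries):
        idx = np.flatnonzero(todo)
        if idx.size == 0:
            break
        bearings = rng.uniform(0.0, 360.0, idx.size)
        dists = rng.uniform(0.0, max_offset_m / 1000.0, idx.size)
        out_lon[idx], out_lat[idx] = destination_point(
            lons[idx], lats[idx], bearings, dists)
        seen: dict[tuple[float, float], int] = {}
        todo = np.zeros(n, dtype=bool)
        for i in range(n):
            key = (out_lon[i], out_lat[i])
            if key in seen:
                todo[i] = True
            else:
                seen[key] = i
    else:
        raise RuntimeError("could not obtain unique locations after re-jittering")
    return out_lon, out_lat


def resample_stack(stack: RasterStack, target_resolution_deg: float = 5.0 / 60.0
                   ) -> RasterStack:
    """Aggregate all layers to a common grid at the target resolution.

    Continuous layers are aggregated by the mean of the source cells
    whose centres fall in each target cell; nodata source cells are
    skipped and target cells with no valid source cell become nodata.
    The target grid origin is the source grid origin of each layer
    (layers must already share their grid, as enforced by the stack).
    """
    if target_resolution_deg <= 0:
        raise ValueError("target resolution must be positive")
    out = RasterStack()
    for layer in stack:
        out.add(_resample_layer(layer, target_resolution_deg))
    return out


def _resample_layer(layer: GridLayer, res: float) -> GridLayer:
    ncols = int(np.ceil(layer.ncols * layer.dx / res - 1e-9))
    nrows = int(np.ceil(layer.nrows * layer.dy / res - 1e-9))
    if ncols < 1 or nrows < 1:
        raise ValueError("target resolution coarser than the layer extent")
    lon, lat = layer.center_mesh()
    target = GridLayer(layer.name, np.zeros((nrows, ncols)), layer.x0, layer.y0,
                       res, res)
    rows, cols, inside = target.cell_index(lon.ravel(), lat.ravel())
    vals = layer.values.ravel()
    ok = inside & np.isfinite(vals)
    flat = rows[ok] * ncols + cols[ok]
    sums = np.bincount(flat, weights=vals[ok], minlength=nrows * ncols)
    counts = np.bincount(flat, minlength=nrows * ncols)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    target.values = mean.reshape(nrows, ncols)
    return target


def sample_at_points(stack: RasterStack, lons, lats,
                     ids=None) -> pd.DataFrame:
    """Covariate table at points: one row per point, one column per layer.

    Points outside the extent or on nodata cells in any layer are kept
    in the table (with NaN) and flagged in the ``complete`` column so
    they can be excluded downstream with a log entry.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    data = {"lon": lons, "lat": lats}
    if ids is not None:
        data = {"household_id": ids, **data}
    for layer in stack:
        data[layer.name] = layer.sample(lons, lats)
    df = pd.DataFrame(data)
    df["complete"] = df[stack.names].notna().all(axis=1)
    return df


@dataclass
class SoilProfileStack:
    """Bulk density and organic carbon over the three standard depth layers."""
    bd: np.ndarray            # Mg m-3, shape (3, ...) one slice per layer
    soc: np.ndarray           # kg C Mg-1, same shape
    dz: tuple[float, float, float] = SOIL_LAYER_THICKNESS_M

    def __post_init__(self):
        self.bd = np.asarray(self.bd, dtype=float)
        self.soc = np.asarray(self.soc, dtype=float)
        if self.bd.shape != self.soc.shape or self.bd.shape[0] != 3:
            raise ValueError("BD and SOC must share a shape with 3 leading layers")
        if len(self.dz) != 3 or any(d <= 0 for d in self.dz):
            raise ValueError("three positive layer thicknesses required")
        if np.any(self.bd[np.isfinite(self.bd)] <= 0):
            raise ValueError("bulk density must be positive")


def compute_scarb(profile: SoilProfileStack) -> tuple[np.ndarray, np.ndarray]:
    """Soil carbon stock per layer and its mean across the three layers.

    SCARB_i = BD_i * dz_i * SOC_i * 1e4; returns (per-layer array of
    shape (3, ...), mean array).
    """
    dz = np.asarray(profile.dz, dtype=float).reshape(
        (3,) + (1,) * (profile.bd.ndim - 1))
    per_layer = profile.bd * dz * profile.soc * 1e4
    return per_layer, per_layer.mean(axis=0)
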