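"""Final indicator maps with 95% prediction intervals.

For log-scale (FA) surfaces the kriging mean back-transforms to the
lognormal *median* E(Y) = exp(mu) and the interval bounds to
exp(mu +/- 1.96 sigma). For proportion indicators the kriged
normal-score residual surfaces (mean and mu +/- 1.96 sigma) are
back-transformed through the inverse normal score map — the mean of the
transformed residuals becomes the median of the back-transformed
residuals — and added to the (deterministic) regression prediction
surface; sums outside [0, 1] are clamped after the addition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geostat import KrigedSurface, NormalScoreMap, inverse_normal_score
from .grids import GridLayer

__all__ = [
    "UncertaintyMaps", "backtransform_lognormal_median", "mlr_pi_bounds",
    "mibr_pi_bounds", "compose_final_map", "compose_pi_maps", "Z_95",
]

Z_95 = 1.96


@dataclass
class UncertaintyMaps:
    """Median map bracketed by the 95% prediction-interval maps."""
    median: GridLayer
    lower: GridLayer
    upper: GridLayer
    scale: str                      # "kcal" for FA, "proportion" for shares

    def __post_init__(self):
        for other in (self.lower, self.upper):
            if not self.median.same_grid(other):
                raise ValueError("uncertainty maps must share one grid")
        bad = (self.lower.values > self.median.values + 1e-12) \
            | (self.median.values > self.upper.values + 1e-12)
        if np.any(bad & np.isfinite(self.median.values)
                  & np.isfinite(self.lower.values)
                  & np.isfinite(self.upper.values)):
            raise ValueError("cell-wise ordering lower <= median <= upper "
                             "violated")


def backtransform_lognormal_median(mu_surface: GridLayer) -> GridLayer:
    """E(Y) = exp(mu): the median of a lognormal on the data scale."""
    return mu_surface.with_values(np.exp(mu_surface.values), name="median")


def mlr_pi_bounds(mu_surface: GridLayer, sd_surface: GridLayer
                  ) -> tuple[GridLayer, GridLayer]:
    """Back-transformed 95% PI bounds exp(mu -/+ 1.96 sigma) for log-scale mu."""
    if not mu_surface.same_grid(sd_surface):
        raise ValueError("mu and sigma surfaces must share one grid")
    if np.any(sd_surface.values[np.isfinite(sd_surface.values)] < 0):
        raise ValueError("sigma surface must be non-negative")
    lower = np.exp(mu_surface.values - Z_95 * sd_surface.values)
    upper = np.exp(mu_surface.values + Z_95 * sd_surface.values)
    return (mu_surface.with_values(lower, name="pi95_lower"),
            mu_surface.with_values(upper, name="pi95_upper"))


def mibr_pi_bounds(kriged: KrigedSurface, nsmap: NormalScoreMap
                   ) -> tuple[GridLayer, GridLayer, GridLayer]:
    """Back-transformed residual median and 95% PI bounds.

    mu, mu - 1.96 sigma and mu + 1.96 sigma on the normal-score scale,
    each mapped through the inverse normal score transform (monotone, so
    the bound ordering survives). Returns (median, lower, upper) on the
    residual data scale.
    """
    mu = kriged.mean.values
    sd = kriged.sd.values
    grids = []
    for name, surf in (("residual_median", mu),
                       ("residual_pi95_lower", mu - Z_95 * sd),
                       ("residual_pi95_upper", mu + Z_95 * sd)):
        back = inverse_normal_score(surf.ravel(), nsmap).reshape(surf.shape)
        back = np.where(np.isfinite(surf), back, np.nan)
        grids.append(kriged.mean.with_values(back, name=name))
    return tuple(grids)


def _clamp(values: np.ndarray, scale: str) -> np.ndarray:
    if scale == "proportion":
        return np.clip(values, 0.0, 1.0)
    if scale == "kcal":
        return np.clip(values, 0.0, None)
    return values


def compose_final_map(prediction: GridLayer, residual_median: GridLayer,
                      scale: str = "proportion") -> GridLayer:
    """Cell-wise prediction + residual median, clamped to the valid range."""
    if not prediction.same_grid(residual_median):
        raise ValueError("prediction and residual maps must share one grid")
    total = _clamp(prediction.values + residual_median.values, scale)
    return prediction.with_values(total, name="final")


def compose_pi_maps(prediction: GridLayer, residual_median: GridLayer,
                    residual_lower: GridLayer, residual_upper: GridLayer,
                    scale: str = "proportion") -> UncertaintyMaps:
    """Compose the final map and its 95% PI maps; clamping after addition."""
    for layer in (residual_median, residual_lower, residual_upper):
        if not prediction.same_grid(layer):
            raise ValueError("all maps must share one grid")
    median = _clamp(prediction.values + residual_median.values, scale)
    lower = _clamp(prediction.values + residual_lower.values, scale)
    upper = _clamp(prediction.values + residual_upper.values, scale)
    # enforce ordering against numerical noise in the back-transform
    lower = np.minimum(lower, median)
    upper = np.maximum(upper, median)
    return UncertaintyMaps(
        median=prediction.with_values(median, name="final"),
        lower=prediction.with_values(lower, name="pi95_lower"),
        upper=prediction.with_values(upper, name="pi95_upper"),
        scale=scale)
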