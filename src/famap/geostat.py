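"""Residual geostatistics: normal scores, variograms, kriging.

The workflow interpolates regression residuals. Because kriging assumes
(approximately) Gaussian variables, residuals from the inflated-beta
models are first passed through a quantile-based normal score
transformation (100 intervals, distribution tails beyond the 0.5% and
99.5% quantiles truncated). Spatial structure is quantified by a
method-of-moments empirical variogram (great-circle distances in km)
and a variogram model — spherical or Matern with smoothness fixed at
kappa = 0.5 (the exponential model) — fitted by minimising the weighted
sum of squared errors with weights N(h) / h^2 (pair count over squared
mean lag distance). The nugget-sill ratio (nugget over *total* sill)
summarises how much residual variance is spatially unstructured; ratios
at or below 0.7 are taken to indicate spatial autocorrelation.

Interpolation is ordinary kriging by default (simple kriging with a
known mean is available, which suits near-zero-mean normal-score
residuals); predictions use the full data set below a size cutoff and a
nearest-neighbour search above it. Leave-one-out cross-validation
reports mean error, RMSE and the mean standardised squared error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, spatial, stats

from .geo import pairwise_distance_km
from .grids import GridLayer, RasterStack
from .regression import FittedModel, fit_mlr

__all__ = [
    "NormalScoreMap", "VariogramEstimate", "VariogramModel", "KrigedSurface",
    "normal_score_transform", "inverse_normal_score",
    "empirical_variogram", "fit_variogram_model", "variogram_value",
    "nugget_sill_ratio", "classify_spatial_structure",
    "krige_residuals", "krige_points", "regression_krige",
    "loo_cross_validate", "DEFAULT_LAG_BOUNDARIES_KM", "DEFAULT_CUTOFF_KM",
]

log = logging.getLogger(__name__)

#: Default lag-bin upper boundaries and pair cutoff (km).
DEFAULT_LAG_BOUNDARIES_KM = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0,
                             90.0, 100.0, 150.0, 200.0)
DEFAULT_CUTOFF_KM = 200.0

#: Global kriging below this many data points; nearest-neighbour above.
GLOBAL_KRIGING_LIMIT = 2000
DEFAULT_NEIGHBOURS = 64


# ---------------------------------------------------------------------------
# Normal score transformation

@dataclass
class NormalScoreMap:
    """Quantile table pairing data values with standard-normal scores."""
    values: np.ndarray            # monotone non-decreasing data quantiles
    scores: np.ndarray            # matching N(0,1) quantiles
    lower_prob: float = 0.005
    upper_prob: float = 0.995

    @property
    def lower_value(self) -> float:
        return float(self.values[0])

    @property
    def upper_value(self) -> float:
        return float(self.values[-1])


def normal_score_transform(values, n_intervals: int = 100,
                           truncate: tuple[float, float] = (0.005, 0.995)
                           ) -> tuple[np.ndarray, NormalScoreMap]:
    """Quantile-based normal score transformation.

    The empirical quantiles of ``values`` over ``n_intervals`` equal
    probability intervals (spanning the truncation probabilities) are
    mapped to the matching standard-normal quantiles; scores are
    obtained by piecewise-linear interpolation in that table, so the
    output is approximately N(0, 1). Values in the distribution tails
    beyond the truncation quantiles map to the boundary scores. Ties
    share a score (monotone map). Constant input is an error.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0 or np.all(values == values.flat[0]):
        raise ValueError("normal score transform undefined for constant input")
    if values.size < n_intervals:
        log.warning("normal score transform: %d values < %d intervals",
                    values.size, n_intervals)
    lo, hi = truncate
    probs = np.linspace(lo, hi, n_intervals + 1)
    quantiles = np.quantile(values, probs)
    quantiles = np.maximum.accumulate(quantiles)
    scores_tab = stats.norm.ppf(probs)
    nsmap = NormalScoreMap(values=quantiles, scores=scores_tab,
                           lower_prob=lo, upper_prob=hi)
    transformed = _forward(values, nsmap)
    return transformed, nsmap


def _forward(values: np.ndarray, nsmap: NormalScoreMap) -> np.ndarray:
    # np.interp clamps outside the table: tail truncation comes for free
    return np.interp(values, nsmap.values, nsmap.scores)


def inverse_normal_score(scores, nsmap: NormalScoreMap) -> np.ndarray:
    """Piecewise-linear inverse of the quantile table.

    Scores beyond the truncation bounds clamp to the boundary data
    values.
    """
    scores = np.asarray(scores, dtype=float)
    return np.interp(scores, nsmap.scores, nsmap.values)


# ---------------------------------------------------------------------------
# Variograms

@dataclass
class VariogramEstimate:
    """Method-of-moments semivariances per lag bin."""
    bin_edges: np.ndarray         # length nbins + 1, starting at 0
    mean_distance: np.ndarray     # mean pair distance per bin (NaN if empty)
    semivariance: np.ndarray      # NaN for empty bins
    pair_count: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lag_lower_km": self.bin_edges[:-1],
            "lag_upper_km": self.bin_edges[1:],
            "mean_distance_km": self.mean_distance,
            "semivariance": self.semivariance,
            "pair_count": self.pair_count})


@dataclass
class VariogramModel:
    """Fitted bounded variogram model.

    ``sill`` is the *total* sill (nugget + partial sill); the nugget-sill
    ratio divides by it, matching the arithmetic of the published
    variogram tables.
    """
    shape: str                    # "spherical" or "matern" (kappa = 0.5)
    nugget: float
    sill: float                   # total sill
    range_km: float
    kappa: float = 0.5
    wsse: float = np.nan
    converged: bool = True

    def __post_init__(self):
        if not (0 <= self.nugget <= self.sill + 1e-12):
            raise ValueError("require 0 <= nugget <= sill")
        if self.range_km <= 0:
            raise ValueError("range must be positive")

    @property
    def partial_sill(self) -> float:
        return self.sill - self.nugget

    @property
    def nugget_sill_ratio(self) -> float:
        return nugget_sill_ratio(self)[0]


def empirical_variogram(lons, lats, values,
                        lag_boundaries=DEFAULT_LAG_BOUNDARIES_KM,
                        cutoff_km: float = DEFAULT_CUTOFF_KM
                        ) -> VariogramEstimate:
    """All-pairs method-of-moments semivariance per lag bin.

    gamma(bin) = 1 / (2 N_bin) * sum over pairs in the bin of
    (z_i - z_j)^2, with great-circle pair distances in km; pairs beyond
    the cutoff (and exactly coincident pairs, distance 0) fall in no
    positive-lag bin. Empty bins are reported with count 0 and NaN
    semivariance.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    values = np.asarray(values, dtype=float)
    if lons.size < 2:
        raise ValueError("need at least two points")
    edges = np.concatenate([[0.0], np.asarray(lag_boundaries, dtype=float)])
    edges = edges[edges <= cutoff_km + 1e-12]
    nbins = edges.size - 1

    d = pairwise_distance_km(lons, lats)
    iu, ju = np.triu_indices(lons.size, k=1)
    dist = d[iu, ju]
    diff2 = (values[iu] - values[ju]) ** 2
    keep = (dist > 0) & (dist <= cutoff_km)
    dist, diff2 = dist[keep], diff2[keep]
    # bin k covers (edges[k], edges[k+1]]
    idx = np.searchsorted(edges, dist, side="left") - 1
    idx = np.clip(idx, 0, nbins - 1)
    count = np.bincount(idx, minlength=nbins)
    sum_d = np.bincount(idx, weights=dist, minlength=nbins)
    sum_g = np.bincount(idx, weights=diff2, minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_d = np.where(count > 0, sum_d / np.maximum(count, 1), np.nan)
        gamma = np.where(count > 0, sum_g / (2.0 * np.maximum(count, 1)), np.nan)
    return VariogramEstimate(bin_edges=edges, mean_distance=mean_d,
                             semivariance=gamma, pair_count=count)


def _correlation(shape: str, h: np.ndarray, a: float) -> np.ndarray:
    """Autocorrelation rho(h) of the structured component."""
    h = np.asarray(h, dtype=float)
    if shape == "spherical":
        r = np.where(h < a, 1.0 - 1.5 * h / a + 0.5 * (h / a) ** 3, 0.0)
        return np.where(h <= 0, 1.0, r)
    if shape == "matern":                 # kappa = 0.5 -> exponential
        return np.exp(-h / a)
    raise ValueError(f"unknown variogram shape {shape!r}")


def variogram_value(model: VariogramModel, h) -> np.ndarray:
    """gamma(h) = nugget + partial_sill * (1 - rho(h)); gamma(0) = nugget."""
    h = np.asarray(h, dtype=float)
    rho = _correlation(model.shape, h, model.range_km)
    return model.nugget + model.partial_sill * (1.0 - rho)


def fit_variogram_model(estimate: VariogramEstimate,
                        shapes: tuple[str, ...] = ("spherical", "matern")
                        ) -> VariogramModel:
    """Weighted least-squares fit; best candidate shape wins.

    Minimises sum over non-empty bins of N/h^2 (gamma_emp - gamma_mod)^2
    over (nugget >= 0, partial sill >= 0, range > 0), from several
    starting ranges, returning the shape with the smallest weighted SSE.
    """
    ok = (estimate.pair_count > 0) & np.isfinite(estimate.semivariance)
    if int(ok.sum()) < 3:
        raise ValueError("need at least 3 non-empty lag bins")
    h = estimate.mean_distance[ok]
    g = estimate.semivariance[ok]
    n = estimate.pair_count[ok].astype(float)
    w = np.sqrt(n) / h                       # residual weights: sqrt(N)/h

    gvar = max(float(np.nanmax(g)), 1e-12)
    hmax = float(np.max(h))

    best: VariogramModel | None = None
    for shape in shapes:
        for a0 in (0.15 * hmax, 0.35 * hmax, 0.7 * hmax, 1.2 * hmax):
            for f0 in (0.0, 0.5, 0.9):
                x0 = np.array([f0 * gvar, max((1 - f0), 0.05) * gvar, a0])

                def resid(x):
                    nug, psill, a = x
                    m = nug + psill * (1.0 - _correlation(shape, h, max(a, 1e-9)))
                    return w * (m - g)

                try:
                    # the range is bounded near the largest observed lag:
                    # structure beyond the sampled lags is not identifiable
                    res = optimize.least_squares(
                        resid, x0,
                        bounds=([0.0, 0.0, 1e-6],
                                [np.inf, np.inf, 1.5 * hmax]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
                except Exception as exc:
                    log.warning("variogram fit failed (%s, start %s): %s",
                                shape, x0, exc)
                    continue
                nug, psill, a = res.x
                wsse = float(np.sum(res.fun ** 2))
                cand = VariogramModel(shape=shape, nugget=float(nug),
                                      sill=float(nug + psill),
                                      range_km=float(a), wsse=wsse)
                if best is None or wsse < best.wsse - 1e-15:
                    best = cand
    if best is None:
        raise RuntimeError("variogram model fitting failed for all candidate "
                           "shapes and starting values")
    return best


def nugget_sill_ratio(model: VariogramModel | tuple[float, float]
                      ) -> tuple[float, float]:
    """(nugget / total sill, spatially structured variance fraction in %).

    Accepts a fitted model or a raw (nugget, sill) pair, e.g. values
    read from a published variogram table.
    """
    if isinstance(model, VariogramModel):
        nugget, sill = model.nugget, model.sill
    else:
        nugget, sill = model
    if sill <= 0:
        raise ValueError("nugget-sill ratio undefined for sill <= 0")
    ratio = nugget / sill
    return float(ratio), float((1.0 - ratio) * 100.0)


def classify_spatial_structure(models: dict[str, "VariogramModel | float"],
                               threshold: float = 0.7) -> list[str]:
    """Indicators whose nugget-sill ratio is at or below the threshold.

    Values may be fitted models or pre-computed ratios. Indicators with
    a missing ratio (NaN, e.g. a non-converging model) are never
    flagged.
    """
    flagged = []
    for name, m in models.items():
        ratio = m.nugget_sill_ratio if isinstance(m, VariogramModel) else float(m)
        if np.isfinite(ratio) and ratio <= threshold:
            flagged.append(name)
    return flagged


# ---------------------------------------------------------------------------
# Kriging

@dataclass
class KrigedSurface:
    """Gridded kriging mean and standard deviation (transformed scale)."""
    mean: GridLayer
    sd: GridLayer
    scale: str = "transformed"


def _covariance(model: VariogramModel, h: np.ndarray,
                include_nugget_at_zero: bool = True) -> np.ndarray:
    c = model.partial_sill * _correlation(model.shape, h, model.range_km)
    if include_nugget_at_zero and model.nugget > 0:
        c = np.where(np.asarray(h) <= 0, c + model.nugget, c)
    return c


def _to_xyz(lons, lats) -> np.ndarray:
    lon = np.radians(np.asarray(lons, dtype=float))
    lat = np.radians(np.asarray(lats, dtype=float))
    return np.column_stack([np.cos(lat) * np.cos(lon),
                            np.cos(lat) * np.sin(lon),
                            np.sin(lat)])


def krige_points(data_lons, data_lats, values, model: VariogramModel,
                 pred_lons, pred_lats, method: str = "ordinary",
                 simple_mean: float = 0.0,
                 n_neighbors: int | None = None,
                 jitter: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Kriging prediction mean and standard deviation at arbitrary points.

    Ordinary kriging (weights constrained to sum to one, locally
    estimated mean) by default; ``method="simple"`` uses the known mean
    ``simple_mean``. Data sets larger than the global limit, or an
    explicit ``n_neighbors``, switch to per-point nearest-neighbour
    kriging. A singular system is retried with a jittered diagonal.
    """
    data_lons = np.asarray(data_lons, dtype=float)
    data_lats = np.asarray(data_lats, dtype=float)
    values = np.asarray(values, dtype=float)
    pred_lons = np.atleast_1d(np.asarray(pred_lons, dtype=float))
    pred_lats = np.atleast_1d(np.asarray(pred_lats, dtype=float))
    n = data_lons.size
    if len({(x, y) for x, y in zip(data_lons, data_lats)}) < n:
        raise ValueError("kriging requires unique data locations")
    if n_neighbors is None and n > GLOBAL_KRIGING_LIMIT:
        n_neighbors = DEFAULT_NEIGHBOURS
    if n_neighbors is not None and n_neighbors < n:
        return _krige_local(data_lons, data_lats, values, model,
                            pred_lons, pred_lats, method, simple_mean,
                            int(n_neighbors))

    d = pairwise_distance_km(data_lons, data_lats)
    C = _covariance(model, d)
    c0 = model.partial_sill + model.nugget
    cross = _covariance(model, pairwise_distance_km(
        data_lons, data_lats, pred_lons, pred_lats))

    if method == "simple":
        lam = _solve_psd(C, cross, jitter)
        mean = simple_mean + lam.T @ (values - simple_mean)
        var = c0 - np.einsum("ij,ij->j", lam, cross)
    elif method == "ordinary":
        m = pred_lons.size
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = C
        A[n, :n] = A[:n, n] = 1.0
        B = np.vstack([cross, np.ones(m)])
        sol = _solve_sym(A, B, jitter)
        lam, lagrange = sol[:n], sol[n]
        mean = lam.T @ values
        var = c0 - np.einsum("ij,ij->j", lam, cross) - lagrange
    else:
        raise ValueError(f"unknown kriging method {method!r}")
    sd = np.sqrt(np.clip(var, 0.0, None))
    return mean, sd


def _solve_psd(C, B, jitter):
    try:
        return np.linalg.solve(C, B)
    except np.linalg.LinAlgError:
        log.warning("singular kriging matrix; retrying with jittered diagonal")
        return np.linalg.solve(C + jitter * np.trace(C) / len(C) * np.eye(len(C)), B)


def _solve_sym(A, B, jitter):
    try:
        return np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        log.warning("singular kriging matrix; retrying with jittered diagonal")
        n = len(A) - 1
        A = A.copy()
        A[:n, :n] += jitter * np.trace(A[:n, :n]) / n * np.eye(n)
        return np.linalg.solve(A, B)


def _krige_local(data_lons, data_lats, values, model, pred_lons, pred_lats,
                 method, simple_mean, k):
    tree = spatial.cKDTree(_to_xyz(data_lons, data_lats))
    q = _to_xyz(pred_lons, pred_lats)
    _, nn = tree.query(q, k=k)
    nn = np.atleast_2d(nn)
    mean = np.empty(pred_lons.size)
    sd = np.empty(pred_lons.size)
    for i in range(pred_lons.size):
        idx = nn[i]
        m, s = krige_points(data_lons[idx], data_lats[idx], values[idx], model,
                            pred_lons[i:i + 1], pred_lats[i:i + 1],
                            method=method, simple_mean=simple_mean,
                            n_neighbors=None)
        mean[i], sd[i] = m[0], s[0]
    return mean, sd


def krige_residuals(lons, lats, transformed_residuals, model: VariogramModel,
                    grid: GridLayer, method: str = "ordinary",
                    n_neighbors: int | None = None) -> KrigedSurface:
    """Krige (transformed) residuals onto the cells of a grid."""
    lon_mesh, lat_mesh = grid.center_mesh()
    mean, sd = krige_points(lons, lats, transformed_residuals, model,
                            lon_mesh.ravel(), lat_mesh.ravel(),
                            method=method, n_neighbors=n_neighbors)
    shape = grid.values.shape
    return KrigedSurface(
        mean=grid.with_values(mean.reshape(shape), name="residual_mean"),
        sd=grid.with_values(sd.reshape(shape), name="residual_sd"))


def regression_krige(y_log, cov: pd.DataFrame, names: list[str],
                     lons, lats, stack: RasterStack,
                     lag_boundaries=DEFAULT_LAG_BOUNDARIES_KM,
                     cutoff_km: float = DEFAULT_CUTOFF_KM
                     ) -> tuple[KrigedSurface, FittedModel, VariogramModel]:
    """Regression kriging of a log-scale response.

    Fits the linear trend by OLS, models the residual variogram, kriges
    the residuals onto the covariate grid and combines trend + residual
    into the prediction mean; the prediction standard deviation is the
    residual kriging standard deviation (the trend is treated as
    deterministic). All surfaces stay on the log scale.
    """
    from .regression import predict_surface  # local import: avoid cycle at import time
    y_log = np.asarray(y_log, dtype=float)
    mlr = fit_mlr(y_log, cov, names)
    resid = y_log - mlr.predict(cov, n=y_log.size)
    est = empirical_variogram(lons, lats, resid, lag_boundaries, cutoff_km)
    vmodel = fit_variogram_model(est)
    trend = predict_surface(mlr, stack)
    kriged = krige_residuals(np.asarray(lons, dtype=float),
                             np.asarray(lats, dtype=float), resid, vmodel,
                             stack.grid)
    mean = trend.values + kriged.mean.values
    surface = KrigedSurface(
        mean=trend.with_values(mean, name="log_prediction"),
        sd=kriged.sd.with_values(kriged.sd.values, name="log_sd"),
        scale="log")
    return surface, mlr, vmodel


def loo_cross_validate(lons, lats, values, model: VariogramModel,
                       method: str = "ordinary") -> dict[str, float]:
    """Leave-one-out kriging diagnostics.

    Reports mean error, RMSE and the mean standardised squared error
    MSSE = mean(((z - z_hat) / sd_hat)^2), which is ~1 when the
    variogram model describes the data. Uses the closed-form LOO
    identities of the (projected) precision matrix, so one factorisation
    serves all points.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 10:
        raise ValueError("need at least 10 points for cross-validation")
    C = _covariance(model, pairwise_distance_km(lons, lats))
    try:
        P = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        P = np.linalg.inv(C + 1e-10 * np.trace(C) / n * np.eye(n))
    if method == "ordinary":
        # filter the (locally re-estimated) mean out of the precision
        u = P @ np.ones(n)
        P = P - np.outer(u, u) / u.sum()
    elif method != "simple":
        raise ValueError(f"unknown kriging method {method!r}")
    diag = np.diag(P)
    errors = (P @ values) / diag               # z_i - z_hat_{-i}
    variances = 1.0 / diag
    std2 = errors ** 2 / variances
    return {"mean_error": float(np.mean(errors)),
            "rmse": float(np.sqrt(np.mean(errors ** 2))),
            "msse": float(np.mean(std2)),
            "n": int(n)}
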