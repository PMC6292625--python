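"""Synthetic survey scenes with known ground truth.

Emulates the structure of an LSMS-ISA-style geo-referenced agricultural
survey so the full mapping pipeline can be exercised end-to-end against
known truth, with no external data:

* covariate rasters: Gaussian random fields with chosen marginal mean,
  sd and spatial range on a common WGS84 grid;
* households clustered in enumeration areas (EAs), with publication
  locations randomly displaced (<= 10 km by default, as publishing
  authorities do for privacy);
* proportion-valued indicators drawn from zero-and-one-inflated beta
  distributions whose parameters follow link-scale linear predictors of
  the covariates plus a spatially correlated latent residual field;
* survey response tables (rosters, production, sales, income)
  constructed by inverting the food-availability computation, so that
  recomputing FA and contribution shares from the records reproduces
  the simulated targets.

The indicator truths are recorded in a :class:`SyntheticTruth` ledger
(coefficients, residual variograms, seeds) for recovery tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .beinf import beinf_rvs
from .food_availability import (EnergyConversionTable, HouseholdSurveyRecord,
                                MAEWeights, ProductRecord, compute_mae)
from .geo import destination_point, pairwise_distance_km
from .geostat import VariogramModel, _correlation
from .grids import GridLayer, RasterStack
from .regression import _LINKS_INV, BEINF_PARAMS, INTERCEPT

__all__ = [
    "LayerSpec", "IndicatorTruth", "SyntheticTruth", "SyntheticScene",
    "SceneConfig", "generate_covariate_rasters", "generate_enumeration_areas",
    "displace_for_privacy", "simulate_inflated_beta_field",
    "simulate_survey_responses", "generate_scene", "standardize_covariates",
]

#: Exact (Cholesky) random-field simulation below this many grid cells;
#: FFT circulant embedding above it.
CHOLESKY_CELL_LIMIT = 5000

_GROUP_PRODUCT = {"banana": "banana", "sorghum": "sorghum", "maize": "maize",
                  "cassava": "cassava", "beans": "beans", "coffee": "coffee",
                  "crop_other": "sweet_potato", "cattle": "cattle",
                  "poultry": "poultry", "livestock_other": "goat"}


@dataclass
class LayerSpec:
    """Marginal and spatial parameters of one synthetic covariate layer.

    ``range_km`` is the distance parameter of the exponential
    correlation exp(-h / range_km) of the generating field.
    """
    name: str
    mean: float
    sd: float
    range_km: float

    def __post_init__(self):
        if self.sd < 0 or self.range_km <= 0:
            raise ValueError("sd must be >= 0 and range positive")


@dataclass
class IndicatorTruth:
    """Generating model of one proportion indicator.

    Coefficients are on the link scale and apply to *standardised*
    covariates (z-scores under the layer-spec nominal mean/sd), keyed
    per distribution parameter with an ``"(Intercept)"`` term. A single
    shared latent residual field (drawn from ``residual_variogram``)
    enters each parameter's linear predictor scaled by
    ``residual_scale[param]``.
    """
    coefficients: dict[str, dict[str, float]]
    residual_variogram: VariogramModel
    residual_scale: dict[str, float] = field(
        default_factory=lambda: {"mu": 1.0, "sigma": 0.0, "nu": 0.0, "tau": 0.0})


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for a generated scene."""
    indicators: dict[str, IndicatorTruth]
    fa_coefficients: dict[str, float]           # log-FA, standardised covariates
    fa_residual_variogram: VariogramModel
    layer_specs: list[LayerSpec]
    seed: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        raw = {
            "seed": self.seed,
            "layer_specs": [asdict(s) for s in self.layer_specs],
            "fa_coefficients": self.fa_coefficients,
            "fa_residual_variogram": asdict(self.fa_residual_variogram),
            "indicators": {
                name: {"coefficients": t.coefficients,
                       "residual_scale": t.residual_scale,
                       "residual_variogram": asdict(t.residual_variogram)}
                for name, t in self.indicators.items()}}
        path.write_text(json.dumps(raw, indent=2))
        return path


@dataclass
class SyntheticScene:
    """A complete generated scene: rasters, households, locations, truth."""
    covariates: RasterStack
    households: list[HouseholdSurveyRecord]
    true_lons: np.ndarray
    true_lats: np.ndarray
    public_lons: np.ndarray
    public_lats: np.ndarray
    truth: SyntheticTruth
    targets: pd.DataFrame        # simulated FA and share targets per household


# ---------------------------------------------------------------------------
# Random fields

def _grf_at_points(lons, lats, range_km, rng, shape: str = "matern") -> np.ndarray:
    """Unit-variance correlated field at scattered points (exact, Cholesky)."""
    h = pairwise_distance_km(lons, lats)
    C = _correlation(shape, h, range_km) + 1e-9 * np.eye(len(h))
    L = np.linalg.cholesky(C)
    return L @ rng.standard_normal(len(h))


def _grf_on_grid(grid: GridLayer, range_km: float, rng) -> np.ndarray:
    """Unit-variance exponential-correlation field on the grid cells.

    Exact Cholesky simulation below ``CHOLESKY_CELL_LIMIT`` cells;
    above it, FFT circulant embedding (negative embedding eigenvalues,
    if any, are clipped — a documented approximation).
    """
    ncell = grid.nrows * grid.ncols
    if ncell <= CHOLESKY_CELL_LIMIT:
        lon, lat = grid.center_mesh()
        z = _grf_at_points(lon.ravel(), lat.ravel(), range_km, rng)
        return z.reshape(grid.values.shape)
    # circulant embedding on a locally flat metric
    lat_c = 0.5 * (grid.extent[1] + grid.extent[3])
    dx_km = grid.dx * 111.320 * np.cos(np.radians(lat_c))
    dy_km = grid.dy * 110.574
    M, N = 2 * grid.nrows, 2 * grid.ncols
    wrap_y = np.minimum(np.arange(M), M - np.arange(M)) * dy_km
    wrap_x = np.minimum(np.arange(N), N - np.arange(N)) * dx_km
    h = np.hypot(wrap_y[:, None], wrap_x[None, :])
    lam = np.fft.fft2(np.exp(-h / range_km)).real
    lam = np.clip(lam, 0.0, None)
    w = rng.standard_normal((M, N)) + 1j * rng.standard_normal((M, N))
    z = np.fft.fft2(w * np.sqrt(lam / (M * N))).real
    return z[:grid.nrows, :grid.ncols]


# ---------------------------------------------------------------------------
# Scene building blocks

def generate_covariate_rasters(extent: tuple[float, float, float, float],
                               resolution_deg: float,
                               layer_specs: list[LayerSpec],
                               seed: int) -> RasterStack:
    """Gaussian-random-field covariate rasters on a common grid.

    ``extent`` is (west, south, east, north) in degrees. Each layer is
    an independent field with approximately the requested marginal
    mean/sd and exponential spatial range. Identical seeds give
    identical stacks.
    """
    west, south, east, north = extent
    if east <= west or north <= south:
        raise ValueError("degenerate extent")
    if resolution_deg <= 0:
        raise ValueError("resolution must be positive")
    ncols = max(int(round((east - west) / resolution_deg)), 1)
    nrows = max(int(round((north - south) / resolution_deg)), 1)
    rng = np.random.default_rng(seed)
    stack = RasterStack()
    for spec in layer_specs:
        grid = GridLayer(spec.name, np.zeros((nrows, ncols)), west, north,
                         resolution_deg, resolution_deg)
        if spec.sd == 0:
            vals = np.full((nrows, ncols), spec.mean)
        else:
            vals = spec.mean + spec.sd * _grf_on_grid(grid, spec.range_km, rng)
        stack.add(grid.with_values(vals))
    return stack


def generate_enumeration_areas(n_ea: int, households_per_ea: int,
                               extent: tuple[float, float, float, float],
                               cluster_sd_km: float, seed: int
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clustered household locations: EA centroids + Gaussian scatter.

    Returns (lons, lats, ea_index) for n_ea * households_per_ea points,
    all inside the extent (out-of-extent scatter is rejection-resampled).
    """
    if n_ea < 1 or households_per_ea < 1:
        raise ValueError("counts must be >= 1")
    west, south, east, north = extent
    if east <= west or north <= south:
        raise ValueError("degenerate extent")
    rng = np.random.default_rng(seed)
    ea_lon = rng.uniform(west, east, n_ea)
    ea_lat = rng.uniform(south, north, n_ea)
    lons = np.empty(n_ea * households_per_ea)
    lats = np.empty_like(lons)
    ea_idx = np.repeat(np.arange(n_ea), households_per_ea)
    for i in range(n_ea):
        for j in range(households_per_ea):
            k = i * households_per_ea + j
            for attempt in range(1000):
                if cluster_sd_km == 0:
                    lon, lat = ea_lon[i], ea_lat[i]
                else:
                    dx = rng.normal(0.0, cluster_sd_km)
                    dy = rng.normal(0.0, cluster_sd_km)
                    bearing = np.degrees(np.arctan2(dx, dy))
                    lon, lat = destination_point(ea_lon[i], ea_lat[i], bearing,
                                                 float(np.hypot(dx, dy)))
                    lon, lat = float(lon), float(lat)
                if west <= lon <= east and south <= lat <= north:
                    lons[k], lats[k] = lon, lat
                    break
            else:
                raise ValueError("extent too small to place clustered "
                                 "households")
    return lons, lats, ea_idx


def displace_for_privacy(lons, lats, max_offset_km: float, seed: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Random displacement <= max_offset_km at uniform bearing (privacy)."""
    if max_offset_km < 0:
        raise ValueError("max offset must be >= 0")
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if max_offset_km == 0:
        return lons.copy(), lats.copy()
    rng = np.random.default_rng(seed)
    bearings = rng.uniform(0.0, 360.0, lons.size)
    dists = rng.uniform(0.0, max_offset_km, lons.size)
    return destination_point(lons, lats, bearings, dists)


def standardize_covariates(table: pd.DataFrame,
                           layer_specs: list[LayerSpec]) -> pd.DataFrame:
    """Z-score covariate columns with the nominal layer-spec mean/sd."""
    out = table.copy()
    for spec in layer_specs:
        if spec.name in out and spec.sd > 0:
            out[spec.name] = (out[spec.name] - spec.mean) / spec.sd
    return out


def simulate_inflated_beta_field(lons, lats, covariates: RasterStack | pd.DataFrame,
                                 truth: IndicatorTruth,
                                 layer_specs: list[LayerSpec],
                                 seed: int,
                                 latent: np.ndarray | None = None
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Draw one proportion indicator at the given locations.

    Per location the four distribution parameters come from link-scale
    linear predictors of the standardised covariates plus the shared
    latent residual field (drawn from the truth variogram unless
    supplied); the value is then drawn from the zero-and-one-inflated
    beta mixture. Returns (values, valid_mask); locations with missing
    covariate values are flagged invalid (NaN value) with a warning.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    rng = np.random.default_rng(seed)
    if isinstance(covariates, RasterStack):
        table = pd.DataFrame(covariates.sample(lons, lats))
    else:
        table = covariates.copy()
    table = standardize_covariates(table, layer_specs)

    needed = sorted({t for coefs in truth.coefficients.values()
                     for t in coefs if t != INTERCEPT})
    for name in needed:
        if name not in table:
            raise KeyError(f"truth references missing covariate {name!r}")
    valid = np.ones(lons.size, dtype=bool)
    for name in needed:
        valid &= np.isfinite(np.asarray(table[name], dtype=float))
    if not np.all(valid):
        warnings.warn(f"{int((~valid).sum())} locations with missing covariate "
                      "values excluded from the simulated field")

    if latent is None:
        vg = truth.residual_variogram
        structured = np.zeros(lons.size)
        if vg.partial_sill > 0:
            structured = np.sqrt(vg.partial_sill) * _grf_at_points(
                lons, lats, vg.range_km, rng, shape=vg.shape)
        latent = structured + np.sqrt(vg.nugget) * rng.standard_normal(lons.size)

    params = {}
    for param in BEINF_PARAMS:
        coefs = truth.coefficients.get(param, {})
        eta = np.full(lons.size, coefs.get(INTERCEPT, 0.0))
        for term, c in coefs.items():
            if term != INTERCEPT:
                eta = eta + c * np.asarray(table[term], dtype=float)
        eta = eta + truth.residual_scale.get(param, 0.0) * latent
        params[param] = _LINKS_INV[param](eta)

    y = np.full(lons.size, np.nan)
    y[valid] = beinf_rvs(params["mu"][valid], params["sigma"][valid],
                         params["nu"][valid], params["tau"][valid],
                         size=int(valid.sum()), rng=rng)
    return y, valid


# ---------------------------------------------------------------------------
# Survey inversion

def simulate_survey_responses(lons, lats, fa_values, shares: pd.DataFrame,
                              energy_table: EnergyConversionTable,
                              seed: int,
                              weights: MAEWeights | None = None,
                              sell_fraction: float = 0.3
                              ) -> list[HouseholdSurveyRecord]:
    """Build survey records whose derived FA and shares equal the targets.

    ``shares`` has one row per household and one column per contribution
    group (crop groups, livestock groups, ``"offfarm"``); rows must sum
    to <= 1 and any shortfall is assigned to the residual crop group.
    Each on-farm group's target energy is met by production of a
    representative product; a ``sell_fraction`` of production is sold at
    the energy-neutral price (product kcal value per currency equal to
    the staple's), which leaves FA and shares unchanged while exercising
    the sales-income pathway. Off-farm energy becomes income via the
    staple conversion. Rosters, land and herd size are drawn from simple
    household distributions.
    """
    rng = np.random.default_rng(seed)
    weights = weights or MAEWeights.default()
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    fa_values = np.asarray(fa_values, dtype=float)
    n = lons.size
    shares = shares.copy()
    unknown = set(shares.columns) - set(_GROUP_PRODUCT) - {"offfarm"}
    if unknown:
        raise ValueError(f"unknown share groups: {sorted(unknown)}")
    total = shares.sum(axis=1).to_numpy()
    if np.any(total > 1.0 + 1e-9):
        raise ValueError("household shares sum to more than 1")
    if np.any((fa_values <= 0) & (total > 0)):
        raise ValueError("FA must be positive wherever any share is positive")
    remainder = np.clip(1.0 - total, 0.0, None)
    if "crop_other" in shares:
        shares["crop_other"] = shares["crop_other"].to_numpy() + remainder
    else:
        shares["crop_other"] = remainder

    kcal_per_currency = energy_table.staple_energy / energy_table.staple_price
    records = []
    for i in range(n):
        members: list[tuple[float, str]] = [(float(rng.integers(20, 60)), "male")]
        n_extra = int(rng.poisson(3.5))
        for _ in range(n_extra):
            if rng.uniform() < 0.35:
                members.append((float(rng.integers(18, 60)), "female"))
            else:
                members.append((float(rng.integers(0, 18)),
                                "male" if rng.uniform() < 0.5 else "female"))
        n_mae = compute_mae(members, weights)
        e_total = fa_values[i] * 365.0 * n_mae

        crop_recs, ls_recs = [], []
        offfarm = 0.0
        herd = 0.0
        for group in shares.columns:
            s = float(shares.iloc[i][group])
            if s <= 0:
                continue
            energy = s * e_total
            if group == "offfarm":
                offfarm = energy / kcal_per_currency
                continue
            product = _GROUP_PRODUCT[group]
            density = energy_table.density(product)
            if density <= 0:
                raise ValueError(f"cannot realise share for {group!r}: "
                                 "product has no energy value")
            frac = 0.9 if group == "coffee" else sell_fraction
            neutral_price = density / kcal_per_currency
            produced = energy / density
            sold = frac * produced
            rec = ProductRecord(product, produced, sold, neutral_price)
            if group in ("cattle", "poultry", "livestock_other"):
                ls_recs.append(rec)
                if group == "cattle":
                    herd += s * 15.0
                elif group == "poultry":
                    herd += s * 2.0
                else:
                    herd += s * 4.0
            else:
                crop_recs.append(rec)
        herd = herd * float(rng.lognormal(0.0, 0.3)) + float(rng.uniform(0, 0.3))
        land = float(rng.lognormal(0.2, 0.6))
        records.append(HouseholdSurveyRecord(
            household_id=f"hh{i:05d}", lon=float(lons[i]), lat=float(lats[i]),
            members=members, crop_records=crop_recs, livestock_records=ls_recs,
            offfarm_income=offfarm, land_area_ha=land, herd_size_tlu=herd))
    return records


# ---------------------------------------------------------------------------
# Full scenes

def _default_layer_specs() -> list[LayerSpec]:
    return [
        LayerSpec("DEM", 1200.0, 350.0, 120.0),
        LayerSpec("TEMP", 21.5, 2.2, 120.0),
        LayerSpec("TEMP_R", 11.0, 1.5, 100.0),
        LayerSpec("RAIN", 1180.0, 220.0, 150.0),
        LayerSpec("RAIN_V", 55.0, 12.0, 130.0),
        LayerSpec("LGP", 210.0, 45.0, 180.0),
        LayerSpec("SCARB", 55000.0, 18000.0, 90.0),
        LayerSpec("POP", 120.0, 80.0, 60.0),
        LayerSpec("TRAV", 180.0, 90.0, 90.0),
    ]


def _default_indicators() -> dict[str, IndicatorTruth]:
    """Generating truths emulating the study's qualitative contrast.

    ``banana`` and ``sorghum`` are driven by environmental gradients
    with spatially structured residuals (low nugget-sill ratio);
    ``beans`` is ubiquitous: no covariate effect and a pure-nugget
    residual; ``offfarm`` and ``cattle`` are weakly structured.
    """
    return {
        "banana": IndicatorTruth(
            coefficients={
                "mu": {INTERCEPT: -0.8, "TEMP": -1.4, "RAIN": 1.0},
                "sigma": {INTERCEPT: -1.3},
                "nu": {INTERCEPT: -0.6, "TEMP": 1.5},
                "tau": {INTERCEPT: -2.5}},
            residual_variogram=VariogramModel("spherical", nugget=0.15,
                                              sill=1.80, range_km=90.0),
            residual_scale={"mu": 1.0, "sigma": 0.0, "nu": -1.5, "tau": 0.0}),
        "sorghum": IndicatorTruth(
            coefficients={
                "mu": {INTERCEPT: -1.0, "RAIN_V": 1.7, "LGP": -1.2},
                "sigma": {INTERCEPT: -1.3},
                "nu": {INTERCEPT: 0.0, "RAIN_V": -1.7},
                "tau": {INTERCEPT: -6.0}},
            residual_variogram=VariogramModel("spherical", nugget=0.15,
                                              sill=1.60, range_km=140.0),
            residual_scale={"mu": 1.0, "sigma": 0.0, "nu": -1.5, "tau": 0.0}),
        "beans": IndicatorTruth(
            coefficients={
                "mu": {INTERCEPT: -1.3},
                "sigma": {INTERCEPT: -0.7},
                "nu": {INTERCEPT: -0.8},
                "tau": {INTERCEPT: -6.0}},
            residual_variogram=VariogramModel("matern", nugget=0.40,
                                              sill=0.40, range_km=30.0),
            residual_scale={"mu": 1.0, "sigma": 0.0, "nu": 0.0, "tau": 0.0}),
        "offfarm": IndicatorTruth(
            coefficients={
                "mu": {INTERCEPT: -1.0, "TRAV": -0.3},
                "sigma": {INTERCEPT: -0.7},
                "nu": {INTERCEPT: -1.2, "TRAV": 0.3},
                "tau": {INTERCEPT: -6.0}},
            residual_variogram=VariogramModel("matern", nugget=0.45,
                                              sill=0.55, range_km=60.0),
            residual_scale={"mu": 1.0, "sigma": 0.0, "nu": 0.0, "tau": 0.0}),
        "cattle": IndicatorTruth(
            coefficients={
                "mu": {INTERCEPT: -1.6},
                "sigma": {INTERCEPT: -0.7},
                "nu": {INTERCEPT: 0.6, "RAIN": -0.4},
                "tau": {INTERCEPT: -6.0}},
            residual_variogram=VariogramModel("matern", nugget=0.35,
                                              sill=0.60, range_km=45.0),
            residual_scale={"mu": 1.0, "sigma": 0.0, "nu": -0.5, "tau": 0.0}),
    }


@dataclass
class SceneConfig:
    """Configuration of a synthetic scene.

    Defaults emulate the study's scale: a ~5.5 x 5.5 degree country-size
    extent, a 5 arc-minute covariate grid, ~1.9 thousand households
    clustered in enumeration areas, publication displacement <= 10 km.
    """
    extent: tuple[float, float, float, float] = (29.5, -1.5, 35.0, 4.0)
    resolution_deg: float = 5.0 / 60.0
    layer_specs: list[LayerSpec] = field(default_factory=_default_layer_specs)
    n_ea: int = 160
    households_per_ea: int = 12
    cluster_sd_km: float = 2.0
    displacement_km: float = 10.0
    indicators: dict[str, IndicatorTruth] = field(
        default_factory=_default_indicators)
    fa_coefficients: dict[str, float] = field(default_factory=lambda: {
        INTERCEPT: 8.0, "LGP": 0.30, "SCARB": 0.35, "RAIN_V": -0.25,
        "POP": -0.22, "TRAV": -0.18})
    fa_residual_variogram: VariogramModel = field(
        default_factory=lambda: VariogramModel("matern", nugget=1.05,
                                               sill=1.30, range_km=87.0))

    @classmethod
    def from_dict(cls, raw: dict) -> "SceneConfig":
        kwargs = dict(raw)
        if "extent" in kwargs:
            kwargs["extent"] = tuple(kwargs["extent"])
        if "layer_specs" in kwargs:
            kwargs["layer_specs"] = [LayerSpec(**s) for s in kwargs["layer_specs"]]
        if "indicators" in kwargs:
            kwargs["indicators"] = {
                name: IndicatorTruth(
                    coefficients=spec["coefficients"],
                    residual_variogram=VariogramModel(**spec["residual_variogram"]),
                    residual_scale=spec.get("residual_scale",
                                            {"mu": 1.0, "sigma": 0.0,
                                             "nu": 0.0, "tau": 0.0}))
                for name, spec in kwargs["indicators"].items()}
        if "fa_residual_variogram" in kwargs:
            kwargs["fa_residual_variogram"] = VariogramModel(
                **kwargs["fa_residual_variogram"])
        return cls(**kwargs)


def generate_scene(config: SceneConfig | None = None, seed: int = 0,
                   energy_table: EnergyConversionTable | None = None
                   ) -> SyntheticScene:
    """Generate a full survey scene with its ground-truth ledger.

    Sub-seeds for each stage are derived from ``seed`` by fixed offsets,
    so identical (config, seed) pairs give bit-identical scenes. The
    generating fields are evaluated at the *true* household locations;
    the published (displaced) locations are what downstream analysis
    sees, reproducing the spatial-mismatch noise of real surveys.
    """
    config = config or SceneConfig()
    energy_table = energy_table or EnergyConversionTable.default()
    covariates = generate_covariate_rasters(config.extent, config.resolution_deg,
                                            config.layer_specs, seed)
    lons, lats, _ = generate_enumeration_areas(
        config.n_ea, config.households_per_ea, config.extent,
        config.cluster_sd_km, seed + 1)
    pub_lons, pub_lats = displace_for_privacy(lons, lats,
                                              config.displacement_km, seed + 2)

    targets = pd.DataFrame(index=range(lons.size))
    valid_all = np.ones(lons.size, dtype=bool)
    for j, (name, truth) in enumerate(sorted(config.indicators.items())):
        y, valid = simulate_inflated_beta_field(
            lons, lats, covariates, truth, config.layer_specs,
            seed=seed + 10 + j)
        targets[name] = y
        valid_all &= valid

    # log-FA: linear predictor of standardised covariates + spatial residual
    table = standardize_covariates(
        pd.DataFrame(covariates.sample(lons, lats)), config.layer_specs)
    rng = np.random.default_rng(seed + 5)
    eta = np.full(lons.size, config.fa_coefficients.get(INTERCEPT, 0.0))
    for term, c in config.fa_coefficients.items():
        if term != INTERCEPT:
            eta = eta + c * np.asarray(table[term], dtype=float)
    vg = config.fa_residual_variogram
    resid = np.sqrt(vg.partial_sill) * _grf_at_points(lons, lats, vg.range_km,
                                                      rng, shape=vg.shape) \
        + np.sqrt(vg.nugget) * rng.standard_normal(lons.size)
    fa = np.exp(eta + resid)
    targets["FA"] = fa

    # scale overflowing share rows back into the simplex
    share_cols = [c for c in targets.columns if c != "FA"]
    share_sum = targets[share_cols].sum(axis=1).to_numpy()
    over = share_sum > 1.0
    if np.any(over):
        targets.loc[over, share_cols] = (
            targets.loc[over, share_cols].to_numpy()
            / share_sum[over][:, None])

    records = simulate_survey_responses(
        lons[valid_all], lats[valid_all], fa[valid_all],
        targets.loc[valid_all, share_cols].reset_index(drop=True),
        energy_table, seed=seed + 6)
    # records carry the *public* locations, as a publishing authority would
    for rec, plon, plat in zip(records, pub_lons[valid_all],
                               pub_lats[valid_all]):
        rec.lon, rec.lat = float(plon), float(plat)

    truth = SyntheticTruth(indicators=config.indicators,
                           fa_coefficients=config.fa_coefficients,
                           fa_residual_variogram=config.fa_residual_variogram,
                           layer_specs=config.layer_specs, seed=seed)
    return SyntheticScene(covariates=covariates, households=records,
                          true_lons=lons, true_lats=lats,
                          public_lons=pub_lons, public_lats=pub_lats,
                          truth=truth,
                          targets=targets.loc[valid_all].reset_index(drop=True))
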