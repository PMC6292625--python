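"""End-to-end orchestration: indicators -> regression -> kriging -> maps.

For each requested indicator the pipeline applies the stepwise
procedure: family choice (log-scale linear regression for FA, inflated
beta regression for contribution shares), univariate screening at
p < 0.1, VIF screening (< 10), stepwise AIC selection, the
one-coefficient simplification step, a nested EVHR refit adding the
household resource covariates (cultivated land, herd size, household
size), residual computation, normal-score transformation (share
indicators), variogram modelling with leave-one-out cross-validation,
kriging of residuals and composition of the final map with its 95%
prediction-interval maps. Per-indicator failures are isolated and
reported; the run is deterministic under the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import jitter_duplicates, sample_at_points
from .food_availability import (EnergyConversionTable, MAEWeights,
                                fa_table, filter_households,
                                read_households_csv)
from .geostat import (DEFAULT_CUTOFF_KM, DEFAULT_LAG_BOUNDARIES_KM,
                      classify_spatial_structure, empirical_variogram,
                      fit_variogram_model, krige_residuals,
                      loo_cross_validate, normal_score_transform,
                      nugget_sill_ratio, regression_krige)
from .grids import RasterStack
from .mapping import (backtransform_lognormal_median, compose_pi_maps,
                      mibr_pi_bounds, mlr_pi_bounds, UncertaintyMaps)
from .regression import (choose_inflation_family, fit_beinf, fit_mlr,
                         predict_surface, pseudo_r2, simplify_beinf,
                         stepwise_select, univariate_screen, vif_screen)
from .synthetic import SceneConfig, generate_scene

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report"]

log = logging.getLogger(__name__)

#: Household-resource covariates added in the nested EVHR fit.
HR_COVARIATES = {"LAND": "land_area_ha", "TLU": "herd_size_tlu",
                 "HH_SIZE": "household_size"}

ACTIVITY_COLUMNS = {"crop": "act_crop", "livestock": "act_livestock",
                    "offfarm": "act_offfarm"}


def _indicator_column(name: str, columns) -> str:
    if name == "FA":
        return "FA"
    for cand in (name, ACTIVITY_COLUMNS.get(name, ""),
                 f"crop_{name}", f"livestock_{name}"):
        if cand and cand in columns:
            return cand
    raise KeyError(f"indicator {name!r} not found in the household table")


@dataclass
class PipelineConfig:
    """Inputs, settings and output location for one pipeline run."""
    # data source: a synthetic scene spec, or paths to survey + raster inputs
    scene: SceneConfig | None = None
    households_dir: str | None = None        # CSV tables (households/members/production)
    covariates_dir: str | None = None        # ASCII-grid raster stack
    energy_table_csv: str | None = None
    mae_weights_yaml: str | None = None

    indicators: list[str] = field(default_factory=lambda: ["FA", "banana",
                                                           "beans"])
    screen_alpha: float = 0.1
    screen_mode: str = "mu"                  # or "any"
    vif_threshold: float = 10.0
    simplify_rule: str = "corrected"         # or "literal"
    lag_boundaries_km: tuple = DEFAULT_LAG_BOUNDARIES_KM
    cutoff_km: float = DEFAULT_CUTOFF_KM
    kriging_method: str = "ordinary"         # or "simple"
    nugget_sill_threshold: float = 0.7
    jitter_max_m: float = 50.0
    seed: int = 0
    out_dir: str | None = None
    overwrite: bool = False
    fit_evhr: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scene" in raw and raw["scene"] is not None:
            raw["scene"] = SceneConfig.from_dict(raw["scene"])
        if "lag_boundaries_km" in raw:
            raw["lag_boundaries_km"] = tuple(raw["lag_boundaries_km"])
        if "indicators" in raw:
            raw["indicators"] = list(raw["indicators"])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)
        blob = json.dumps(self.__dict__, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-indicator results of one run, plus provenance."""
    rows: list[dict]
    seed: int
    config_hash: str
    version: str = __version__
    n_households_input: int = 0
    n_households_retained: int = 0
    spatial_structure_threshold: float = 0.7

    @property
    def flagged(self) -> list[str]:
        return [r["indicator"] for r in self.rows
                if r.get("spatial_structure") is True]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"seed": self.seed, "config_hash": self.config_hash,
                   "version": self.version,
                   "n_households_input": self.n_households_input,
                   "n_households_retained": self.n_households_retained,
                   "spatial_structure_threshold": self.spatial_structure_threshold,
                   "rows": self.rows}
        path.write_text(json.dumps(payload, indent=2, default=_jsonable))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunReport":
        raw = json.loads(Path(path).read_text())
        return cls(rows=raw["rows"], seed=raw["seed"],
                   config_hash=raw["config_hash"], version=raw["version"],
                   n_households_input=raw["n_households_input"],
                   n_households_retained=raw["n_households_retained"],
                   spatial_structure_threshold=raw["spatial_structure_threshold"])


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    return str(o)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full stepwise procedure for every requested indicator."""
    t0 = time.time()
    energy = (EnergyConversionTable.from_csv(config.energy_table_csv)
              if config.energy_table_csv else EnergyConversionTable.default())
    weights = (MAEWeights.from_yaml(config.mae_weights_yaml)
               if config.mae_weights_yaml else MAEWeights.default())

    if config.scene is not None:
        scene = generate_scene(config.scene, seed=config.seed,
                               energy_table=energy)
        households = scene.households
        stack = scene.covariates
    elif config.households_dir and config.covariates_dir:
        households = read_households_csv(config.households_dir)
        stack = RasterStack.read_dir(config.covariates_dir)
    else:
        raise ValueError("config needs either a synthetic scene or input paths")

    n_input = len(households)
    households, exclusion_log = filter_households(households)
    log.info("household filter: %d retained, %d excluded",
             len(households), len(exclusion_log))

    hh = fa_table(households, energy, weights)
    lons, lats = jitter_duplicates(hh["lon"].to_numpy(), hh["lat"].to_numpy(),
                                   max_offset_m=config.jitter_max_m,
                                   seed=config.seed + 101)
    hh["lon_jit"], hh["lat_jit"] = lons, lats

    cov = sample_at_points(stack, lons, lats, ids=hh["household_id"])
    complete = cov["complete"].to_numpy()
    if not complete.all():
        log.info("%d households on nodata/out-of-extent cells excluded",
                 int((~complete).sum()))
    hh = hh.loc[complete].reset_index(drop=True)
    cov = cov.loc[complete].reset_index(drop=True)
    env_names = stack.names
    env_table = cov[env_names]
    hr_table = pd.DataFrame({code: hh[col].to_numpy()
                             for code, col in HR_COVARIATES.items()})

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        if out_dir.exists() and any(out_dir.iterdir()) and not config.overwrite:
            raise FileExistsError(f"{out_dir} is not empty; pass overwrite=True")
        out_dir.mkdir(parents=True, exist_ok=True)
        exclusion_log.to_csv(out_dir / "exclusions.csv", index=False)

    rows = []
    vmodels = {}
    for indicator in config.indicators:
        try:
            row, vmodel = _run_indicator(indicator, hh, env_table, hr_table,
                                         stack, config, out_dir)
            if vmodel is not None:
                vmodels[indicator] = vmodel
        except Exception as exc:                  # crash isolation per indicator
            log.exception("indicator %s failed", indicator)
            row = {"indicator": indicator, "status": f"failed: {exc}"}
        rows.append(row)

    flagged = classify_spatial_structure(vmodels,
                                         config.nugget_sill_threshold)
    for row in rows:
        if row["indicator"] in vmodels:
            row["spatial_structure"] = row["indicator"] in flagged

    report = RunReport(rows=rows, seed=config.seed,
                       config_hash=config.config_hash(),
                       n_households_input=n_input,
                       n_households_retained=len(hh),
                       spatial_structure_threshold=config.nugget_sill_threshold)
    log.info("pipeline finished in %.1f s (%d indicators, %d flagged)",
             time.time() - t0, len(rows), len(flagged))
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _screen_and_select(y, env_table, family, config):
    screen = univariate_screen(y, env_table, family,
                               alpha=config.screen_alpha,
                               mode=config.screen_mode)
    kept = screen.retained
    dropped_vif = []
    if len(kept) >= 2:
        vif_table, dropped_vif = vif_screen(env_table[kept],
                                            threshold=config.vif_threshold)
        kept = list(vif_table["covariate"])
    if kept:
        model = stepwise_select(y, env_table, kept, family)
    else:
        model = (fit_mlr(y, None, []) if family == "mlr"
                 else fit_beinf(y, None, None, family=family))
    return model, screen, kept, dropped_vif


def _run_indicator(indicator, hh, env_table, hr_table, stack, config, out_dir):
    t0 = time.time()
    col = _indicator_column(indicator, hh.columns)
    y_raw = hh[col].to_numpy(dtype=float)
    lons = hh["lon_jit"].to_numpy()
    lats = hh["lat_jit"].to_numpy()
    data = pd.concat([env_table.reset_index(drop=True),
                      hr_table.reset_index(drop=True)], axis=1)

    row = {"indicator": indicator, "status": "ok", "n": int(y_raw.size)}
    sub_dir = (out_dir / indicator) if out_dir is not None else None
    if sub_dir is not None:
        sub_dir.mkdir(parents=True, exist_ok=True)

    if indicator == "FA":
        if np.any(y_raw <= 0):
            keep = y_raw > 0
            log.info("FA: dropping %d non-positive values before the log "
                     "transform", int((~keep).sum()))
            y_raw, lons, lats = y_raw[keep], lons[keep], lats[keep]
            data = data.loc[keep].reset_index(drop=True)
        y = np.log(y_raw)
        family = "mlr"
        ev_model, screen, kept, dropped_vif = _screen_and_select(
            y, data[env_table.columns], family, config)
        row.update(family="MLR", fit_stat=ev_model.fit_stat,
                   aic=ev_model.aic, covariates=dict(ev_model.cov_names))
        if config.fit_evhr:
            evhr = _stepwise_forward_hr_mlr(y, data, ev_model,
                                            list(HR_COVARIATES))
            row.update(fit_stat_evhr=evhr.fit_stat, aic_evhr=evhr.aic,
                       covariates_evhr=dict(evhr.cov_names))
        surface, mlr, vmodel = regression_krige(
            y, data, ev_model.cov_names["mean"], lons, lats, stack,
            config.lag_boundaries_km, config.cutoff_km)
        resid = y - mlr.predict(data, n=y.size)
        cv = loo_cross_validate(lons, lats, resid, vmodel,
                                method=config.kriging_method)
        median = backtransform_lognormal_median(surface.mean)
        lower, upper = mlr_pi_bounds(surface.mean, surface.sd)
        maps = UncertaintyMaps(median=median, lower=lower, upper=upper,
                               scale="kcal")
    else:
        family = choose_inflation_family(y_raw)
        y = y_raw
        if family == "beinf0" and np.any(y == 1.0):
            # too few exact ones to model them; unusable under the
            # zero-inflated-only family
            keep = y < 1.0
            log.info("%s: excluding %d observation(s) with y == 1 under "
                     "MIBR-0", indicator, int((~keep).sum()))
            y, lons, lats = y[keep], lons[keep], lats[keep]
            data = data.loc[keep].reset_index(drop=True)
            row["n"] = int(y.size)
        ev_model, screen, kept, dropped_vif = _screen_and_select(
            y, data[env_table.columns], family, config)
        ev_model, decision = simplify_beinf(ev_model, y,
                                            data[env_table.columns],
                                            rule=config.simplify_rule)
        row.update(family={"beinf": "MIBR", "beinf0": "MIBR-0"}[family],
                   fit_stat=ev_model.fit_stat, aic=ev_model.aic,
                   covariates=dict(ev_model.cov_names),
                   simplification=decision["accepted"])
        if config.fit_evhr:
            evhr = _stepwise_forward_hr_beinf(y, data, ev_model,
                                              list(HR_COVARIATES), family)
            row.update(fit_stat_evhr=evhr.fit_stat, aic_evhr=evhr.aic,
                       covariates_evhr=dict(evhr.cov_names))
        pred = ev_model.predict(data, n=y.size)
        resid = y - pred
        transformed, nsmap = normal_score_transform(resid)
        est = empirical_variogram(lons, lats, transformed,
                                  config.lag_boundaries_km, config.cutoff_km)
        vmodel = fit_variogram_model(est)
        cv = loo_cross_validate(lons, lats, transformed, vmodel,
                                method=config.kriging_method)
        kriged = krige_residuals(lons, lats, transformed, vmodel, stack.grid,
                                 method=config.kriging_method)
        res_median, res_lower, res_upper = mibr_pi_bounds(kriged, nsmap)
        prediction = predict_surface(ev_model, stack)
        maps = compose_pi_maps(prediction, res_median, res_lower, res_upper,
                               scale="proportion")

    ratio, fraction = nugget_sill_ratio(vmodel)
    row.update(screen_kept=kept, vif_dropped=dropped_vif,
               variogram_shape=vmodel.shape, nugget=vmodel.nugget,
               sill=vmodel.sill, range_km=vmodel.range_km,
               nugget_sill_ratio=ratio, spatial_fraction_pct=fraction,
               cv_msse=cv["msse"], cv_rmse=cv["rmse"],
               runtime_s=round(time.time() - t0, 2))
    if sub_dir is not None:
        from .grids import write_ascii_grid
        paths = {}
        for tag, layer in (("final", maps.median), ("pi95_lower", maps.lower),
                           ("pi95_upper", maps.upper)):
            paths[tag] = str(write_ascii_grid(
                layer, sub_dir / f"{indicator}_{tag}.asc"))
        row["outputs"] = paths
    return row, vmodel


def _stepwise_forward_hr_mlr(y, data, ev_model, hr_names):
    """Nested EVHR fit: EV covariates kept, HR covariates added forward."""
    selected = list(ev_model.cov_names["mean"])
    current = fit_mlr(y, data, selected)
    improved = True
    while improved:
        improved = False
        best = (current.aic, None)
        for name in hr_names:
            if name in selected:
                continue
            cand = fit_mlr(y, data, selected + [name])
            if cand.aic < best[0] - 1e-9:
                best = (cand.aic, name)
        if best[1] is not None:
            selected.append(best[1])
            current = fit_mlr(y, data, selected)
            improved = True
    return current


def _stepwise_forward_hr_beinf(y, data, ev_model, hr_names, family):
    """Forward HR additions per distribution parameter, EV terms retained."""
    cov_names = {p: list(v) for p, v in ev_model.cov_names.items()}
    current = fit_beinf(y, data, cov_names, family=family)
    params = list(cov_names)
    improved = True
    while improved:
        improved = False
        best = (current.aic, None, None)
        for param in params:
            for name in hr_names:
                if name in cov_names[param]:
                    continue
                trial = {p: list(v) for p, v in cov_names.items()}
                trial[param] = trial[param] + [name]
                try:
                    cand = fit_beinf(y, data, trial, family=family)
                except Exception:
                    continue
                if cand.converged and cand.aic < best[0] - 1e-9:
                    best = (cand.aic, param, name)
        if best[1] is not None:
            cov_names[best[1]].append(best[2])
            current = fit_beinf(y, data, cov_names, family=family)
            improved = True
    return current


def write_report(report: RunReport, out_dir: str | Path,
                 formats: tuple[str, ...] = ("csv", "json", "summary")
                 ) -> dict[str, Path]:
    """Write the run report as CSV, JSON and a human-readable summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    table_cols = ["indicator", "status", "family", "n", "fit_stat",
                  "fit_stat_evhr", "aic", "aic_evhr", "variogram_shape",
                  "nugget", "sill", "range_km", "nugget_sill_ratio",
                  "spatial_fraction_pct", "spatial_structure", "cv_msse",
                  "cv_rmse"]
    if "csv" in formats:
        frame = report.as_frame()
        for c in table_cols:
            if c not in frame.columns:
                frame[c] = np.nan
        paths["csv"] = out_dir / "report.csv"
        frame[table_cols].to_csv(paths["csv"], index=False)
    if "json" in formats:
        paths["json"] = report.to_json(out_dir / "report.json")
    if "summary" in formats:
        lines = [f"famap {report.version} run (seed {report.seed}, "
                 f"config {report.config_hash})",
                 f"households: {report.n_households_retained} retained of "
                 f"{report.n_households_input}"]
        flagged = report.flagged
        lines.append(f"spatial structure (nugget-sill ratio <= "
                     f"{report.spatial_structure_threshold}): "
                     f"{len(flagged)} indicator(s): "
                     + (", ".join(flagged) if flagged else "none"))
        for row in report.rows:
            if row.get("status") != "ok":
                lines.append(f"  {row['indicator']}: {row.get('status')}")
                continue
            lines.append(
                f"  {row['indicator']}: {row.get('family')}, "
                f"fit={row.get('fit_stat', float('nan')):.3f}, "
                f"ratio={row.get('nugget_sill_ratio', float('nan')):.2f}, "
                f"range={row.get('range_km', float('nan')):.0f} km")
        paths["summary"] = out_dir / "summary.txt"
        paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
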