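"""Regression models for FA and contribution shares.

Two model families:

* multiple linear regression (MLR) on log-FA, fitted by ordinary least
  squares;
* multiple zero-and-one-inflated beta regression (MIBR) on contribution
  shares, with link-scale linear predictors for all four distribution
  parameters (logit for mu and sigma, log for nu and tau), fitted by
  maximum likelihood. The zero-inflated-only variant (MIBR-0, no tau
  predictor) is used when the sample holds <= 3 exact ones.

Covariate selection follows the study workflow: univariate screening at
p < 0.1, collinearity screening by variance inflation factor (VIF < 10),
stepwise AIC selection (forward for MLR; forward-then-backward cycling
over the four parameters for MIBR), and a final one-coefficient
simplification step guarded by an AIC-difference rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools import numdiff

from .beinf import beinf_expectation, beinf_loglik
from .grids import GridLayer, RasterStack

__all__ = [
    "FittedModel", "ResidualSet", "ScreeningReport",
    "fit_mlr", "fit_beinf", "choose_inflation_family",
    "univariate_screen", "vif_screen", "stepwise_select", "simplify_beinf",
    "pseudo_r2", "predict_surface", "compute_residuals",
    "BEINF_PARAMS",
]

log = logging.getLogger(__name__)

BEINF_PARAMS = ("mu", "sigma", "nu", "tau")
INTERCEPT = "(Intercept)"

_ETA_CLIP = 30.0


def _logit_inv(eta):
    return special.expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


def _log_inv(eta):
    return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


_LINKS_INV = {"mu": _logit_inv, "sigma": _logit_inv,
              "nu": _log_inv, "tau": _log_inv}
LINKS = {"mu": "logit", "sigma": "logit", "nu": "log", "tau": "log"}


def _design(cov: pd.DataFrame | None, names: list[str], n: int) -> np.ndarray:
    cols = [np.ones(n)]
    for name in names:
        if cov is None or name not in cov:
            raise KeyError(f"covariate {name!r} not available")
        cols.append(np.asarray(cov[name], dtype=float))
    return np.column_stack(cols)


@dataclass
class ResidualSet:
    """Observed minus predicted indicator values at household locations."""
    lon: np.ndarray
    lat: np.ndarray
    y_observed: np.ndarray
    y_predicted: np.ndarray

    @property
    def residuals(self) -> np.ndarray:
        return self.y_observed - self.y_predicted


@dataclass
class FittedModel:
    """A fitted MLR or (zero-and-one-)inflated beta regression model.

    ``family`` is one of ``"mlr"``, ``"beinf"`` (MIBR) or ``"beinf0"``
    (MIBR-0). ``coef_table`` holds one row per coefficient with its
    standard error (from the observed information for the MIBR families)
    and p-value; ``cov_names`` lists the selected covariates per
    distribution parameter (the single entry ``"mean"`` for MLR).
    """
    family: str
    coef_table: pd.DataFrame          # columns: param, term, coef, se, stat, p
    cov_names: dict[str, list[str]]
    loglik: float
    aic: float
    nobs: int
    converged: bool = True
    fit_stat: float = np.nan          # R^2 (MLR) or pseudo-R^2 (MIBR)
    extras: dict = field(default_factory=dict)
    selection_trace: list = field(default_factory=list)

    @property
    def k_params(self) -> int:
        return len(self.coef_table)

    def coefs(self, param: str) -> pd.Series:
        sub = self.coef_table[self.coef_table["param"] == param]
        return pd.Series(sub["coef"].to_numpy(), index=sub["term"].to_numpy())

    # -- prediction ---------------------------------------------------------

    def linear_predictor(self, param: str, cov: pd.DataFrame | None,
                         n: int | None = None) -> np.ndarray:
        names = self.cov_names.get(param, [])
        if n is None:
            if cov is None:
                raise ValueError("covariate table required")
            n = len(cov)
        X = _design(cov, names, n)
        return X @ self.coefs(param).to_numpy()

    def predict_params(self, cov: pd.DataFrame | None, n: int | None = None
                       ) -> dict[str, np.ndarray]:
        if self.family == "mlr":
            raise ValueError("distribution parameters are defined for the "
                             "inflated-beta families only")
        if n is None:
            n = len(cov) if cov is not None else 1
        out = {}
        for param in BEINF_PARAMS:
            if param == "tau" and self.family == "beinf0":
                out[param] = np.zeros(n)
                continue
            eta = self.linear_predictor(param, cov, n)
            out[param] = _LINKS_INV[param](eta)
        return out

    def predict(self, cov: pd.DataFrame | None, n: int | None = None) -> np.ndarray:
        """E(y) for the inflated-beta families; linear predictor for MLR."""
        if self.family == "mlr":
            return self.linear_predictor("mean", cov, n)
        p = self.predict_params(cov, n)
        return np.asarray(beinf_expectation(p["mu"], p["nu"], p["tau"]))


def compute_residuals(model: FittedModel, y, cov: pd.DataFrame | None,
                      lon, lat) -> ResidualSet:
    """Raw-scale residuals y_observed - y_predicted at the data locations."""
    y = np.asarray(y, dtype=float)
    pred = model.predict(cov, n=y.size)
    return ResidualSet(lon=np.asarray(lon, dtype=float),
                       lat=np.asarray(lat, dtype=float),
                       y_observed=y, y_predicted=pred)


# ---------------------------------------------------------------------------
# MLR

def fit_mlr(y, cov: pd.DataFrame | None, names: list[str] | None = None
            ) -> FittedModel:
    """Ordinary least squares fit with an intercept.

    ``y`` is the (already log-transformed, where applicable) response.
    Raises on rank-deficient designs, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    names = list(names or [])
    X = _design(cov, names, y.size)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of dependent columns by greedy scan
        bad = []
        kept = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept):
                bad.append(names[j - 1])
            else:
                kept.append(j)
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {bad}")
    res = sm.OLS(y, X).fit()
    terms = [INTERCEPT] + names
    table = pd.DataFrame({
        "param": "mean", "term": terms, "coef": res.params,
        "se": res.bse, "stat": res.tvalues, "p": res.pvalues})
    if np.var(y) == 0:
        r2 = 0.0
    else:
        r2 = float(res.rsquared)
    betas = {}
    sd_y = float(np.std(y, ddof=1)) if y.size > 1 else np.nan
    for j, name in enumerate(names):
        sd_x = float(np.std(X[:, j + 1], ddof=1))
        betas[name] = float(res.params[j + 1]) * sd_x / sd_y if sd_y else np.nan
    return FittedModel(
        family="mlr", coef_table=table, cov_names={"mean": names},
        loglik=float(res.llf), aic=float(res.aic), nobs=y.size,
        fit_stat=r2,
        extras={"adj_r2": float(res.rsquared_adj) if np.var(y) > 0 else 0.0,
                "f_stat": float(res.fvalue) if names else np.nan,
                "resid_var": float(res.mse_resid),
                "std_beta": betas})


# ---------------------------------------------------------------------------
# MIBR maximum likelihood

def choose_inflation_family(y) -> str:
    """``"beinf0"`` when the sample has <= 3 exact ones, else ``"beinf"``."""
    y = np.asarray(y, dtype=float)
    return "beinf0" if int(np.sum(y == 1.0)) <= 3 else "beinf"


def _active_params(family: str) -> tuple[str, ...]:
    return BEINF_PARAMS[:3] if family == "beinf0" else BEINF_PARAMS


def _start_values(y: np.ndarray, cov_names: dict[str, list[str]],
                  family: str) -> np.ndarray:
    """Moment-based intercepts; zero slopes."""
    mid = y[(y > 0) & (y < 1)]
    m = float(np.mean(mid)) if mid.size else 0.5
    m = min(max(m, 1e-3), 1 - 1e-3)
    if mid.size > 1 and np.var(mid) > 0:
        s2 = min(max(float(np.var(mid)) / (m * (1 - m)), 1e-4), 1 - 1e-4)
    else:
        s2 = 0.25
    p0 = max(float(np.mean(y == 0.0)), 1e-4)
    p1 = max(float(np.mean(y == 1.0)), 1e-4)
    pc = max(1.0 - p0 - p1, 1e-4)
    starts = {"mu": special.logit(m),
              "sigma": special.logit(np.sqrt(s2)),
              "nu": np.log(p0 / pc),
              "tau": np.log(p1 / pc)}
    x0 = []
    for param in _active_params(family):
        x0.append(starts[param])
        x0.extend([0.0] * len(cov_names.get(param, [])))
    return np.asarray(x0)


def _unpack(theta: np.ndarray, designs: dict[str, np.ndarray], family: str
            ) -> dict[str, np.ndarray]:
    out, pos = {}, 0
    for param in _active_params(family):
        X = designs[param]
        k = X.shape[1]
        out[param] = _LINKS_INV[param](X @ theta[pos:pos + k])
        pos += k
    if family == "beinf0":
        out["tau"] = 0.0
    return out


def fit_beinf(y, cov: pd.DataFrame | None,
              cov_names: dict[str, list[str]] | None = None,
              family: str | None = None,
              x0: np.ndarray | None = None,
              maxiter: int = 500) -> FittedModel:
    """Maximum-likelihood fit of the (zero-and-one-)inflated beta regression.

    ``cov_names`` maps each distribution parameter to its covariate list
    (empty = intercept-only). Optimisation is quasi-Newton (BFGS) on the
    joint link-scale coefficient vector; standard errors come from the
    inverse observed information at the optimum; AIC = -2 loglik + 2k.
    Non-convergence is flagged on the returned model, never silent.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("observations must lie in [0, 1]")
    auto_family = family is None
    family = family or choose_inflation_family(y)
    if family == "beinf0" and np.any(y == 1.0):
        if not auto_family:
            raise ValueError("family 'beinf0' cannot model data containing "
                             "y == 1")
        # the zero-only variant is chosen when the sample holds too few
        # exact ones to model them; those observations carry no
        # information under the model and are excluded
        keep = y < 1.0
        log.warning("excluding %d observation(s) with y == 1 under the "
                    "zero-inflated-only family", int((~keep).sum()))
        y = y[keep]
        if cov is not None:
            cov = cov.loc[keep].reset_index(drop=True)
    cov_names = {p: list((cov_names or {}).get(p, []))
                 for p in _active_params(family)}
    designs = {p: _design(cov, names, y.size)
               for p, names in cov_names.items()}
    k = sum(X.shape[1] for X in designs.values())
    if y.size <= k:
        raise ValueError("more coefficients than observations")

    def nll(theta):
        params = _unpack(theta, designs, family)
        try:
            ll = beinf_loglik(y, params["mu"], params["sigma"], params["nu"],
                              params["tau"], family="beinf")
        except (ValueError, FloatingPointError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    if x0 is None:
        x0 = _start_values(y, cov_names, family)
    res = optimize.minimize(nll, x0, method="BFGS",
                            options={"maxiter": maxiter, "gtol": 1e-6})
    # one polishing pass helps when BFGS stops on a loose line search
    if not res.success:
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"maxiter": 2000, "fatol": 1e-9,
                                          "xatol": 1e-8})
        if res2.fun <= res.fun:
            res = res2
    theta = res.x
    ll = -float(res.fun)
    converged = bool(np.isfinite(ll)) and res.fun < 1e11

    se = np.full(k, np.nan)
    if converged:
        try:
            H = numdiff.approx_hess1(theta, nll)
            cov_theta = np.linalg.inv(H)
            diag = np.diag(cov_theta)
            se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
        except np.linalg.LinAlgError:
            pass

    rows, pos = [], 0
    for param in _active_params(family):
        terms = [INTERCEPT] + cov_names[param]
        for term in terms:
            c, s = theta[pos], se[pos]
            z = c / s if np.isfinite(s) and s > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({"param": param, "term": term, "coef": c,
                         "se": s, "stat": z, "p": p})
            pos += 1
    table = pd.DataFrame(rows)

    model = FittedModel(family=family, coef_table=table, cov_names=cov_names,
                        loglik=ll, aic=-2.0 * ll + 2.0 * k, nobs=y.size,
                        converged=converged)
    fitted = model.predict(cov, n=y.size)
    model.fit_stat = pseudo_r2(fitted, y)
    return model


def pseudo_r2(fitted, observed) -> float:
    """Squared Pearson correlation of fitted and observed; 0 when undefined."""
    fitted = np.asarray(fitted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if fitted.size != observed.size:
        raise ValueError("length mismatch")
    if np.std(fitted) == 0 or np.std(observed) == 0:
        log.warning("pseudo-R^2 undefined for a constant vector; returning 0")
        return 0.0
    r = np.corrcoef(fitted, observed)[0, 1]
    return float(r ** 2)


# ---------------------------------------------------------------------------
# Screening

@dataclass
class ScreeningReport:
    """Univariate p-values, keep/drop flags, and the VIF drop order."""
    univariate: pd.DataFrame       # columns: covariate, p, kept
    vif: pd.DataFrame | None = None  # columns: covariate, vif (final values)
    vif_drop_order: list[str] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        if self.vif is not None:
            return list(self.vif["covariate"])
        return list(self.univariate.loc[self.univariate["kept"], "covariate"])


def univariate_screen(y, cov: pd.DataFrame, family: str,
                      alpha: float = 0.1, mode: str = "mu") -> ScreeningReport:
    """One single-covariate model per covariate; keep iff slope p < alpha.

    For the inflated-beta families the covariate enters the mu predictor
    (``mode="mu"``, default) or each parameter in turn with the smallest
    p-value taken (``mode="any"``).
    """
    y = np.asarray(y, dtype=float)
    rows = []
    for name in cov.columns:
        try:
            p = _univariate_p(y, cov, name, family, mode)
        except Exception as exc:                     # non-convergence: drop
            log.warning("univariate screen: %s dropped (%s)", name, exc)
            p = np.nan
        rows.append({"covariate": name, "p": p,
                     "kept": bool(np.isfinite(p) and p < alpha)})
    return ScreeningReport(univariate=pd.DataFrame(
        rows, columns=["covariate", "p", "kept"]))


def _univariate_p(y, cov, name, family, mode) -> float:
    if family == "mlr":
        m = fit_mlr(y, cov, [name])
        return float(m.coef_table.loc[m.coef_table["term"] == name, "p"].iloc[0])
    params = _active_params(family) if mode == "any" else ("mu",)
    best = np.inf
    for param in params:
        m = fit_beinf(y, cov, {param: [name]}, family=family)
        if not m.converged:
            continue
        sub = m.coef_table
        p = sub.loc[(sub["param"] == param) & (sub["term"] == name), "p"].iloc[0]
        if np.isfinite(p):
            best = min(best, float(p))
    if not np.isfinite(best):
        raise RuntimeError("no converged univariate fit")
    return best


def vif_screen(cov: pd.DataFrame, threshold: float = 10.0
               ) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop the highest-VIF covariate until all VIF < threshold.

    Returns (final VIF table, drop order). VIFs are computed with an
    intercept in the auxiliary regressions.
    """
    cols = list(cov.columns)
    dropped: list[str] = []
    while len(cols) >= 2:
        X = np.column_stack([np.ones(len(cov))]
                            + [np.asarray(cov[c], dtype=float) for c in cols])
        with np.errstate(divide="ignore", invalid="ignore"):
            vifs = np.array([variance_inflation_factor(X, j + 1)
                             for j in range(len(cols))])
        vifs = np.where(np.isfinite(vifs), vifs, np.inf)
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        dropped.append(cols.pop(worst))
    if len(cols) >= 2:
        X = np.column_stack([np.ones(len(cov))]
                            + [np.asarray(cov[c], dtype=float) for c in cols])
        vifs = [variance_inflation_factor(X, j + 1) for j in range(len(cols))]
    else:
        vifs = [1.0] * len(cols)
    table = pd.DataFrame({"covariate": cols, "vif": vifs})
    return table, dropped


# ---------------------------------------------------------------------------
# Stepwise selection and simplification

def stepwise_select(y, cov: pd.DataFrame, candidates: list[str],
                    family: str, max_cycles: int = 10) -> FittedModel:
    """AIC-driven covariate selection.

    MLR: forward selection — repeatedly add the candidate that lowers
    AIC most, until no addition improves it. MIBR families: cycle over
    the distribution parameters (mu, sigma, nu, tau), doing forward
    additions then backward eliminations on each parameter's predictor,
    until a full cycle makes no move. Failed candidate fits are skipped
    with a log entry. Deterministic for a fixed candidate order.
    """
    y = np.asarray(y, dtype=float)
    if family == "mlr":
        return _stepwise_mlr(y, cov, candidates)
    return _stepwise_beinf(y, cov, candidates, family, max_cycles)


def _stepwise_mlr(y, cov, candidates) -> FittedModel:
    selected: list[str] = []
    trace = []
    current = fit_mlr(y, cov, selected)
    improved = True
    while improved:
        improved = False
        best_aic, best_name, best_model = current.aic, None, None
        for name in candidates:
            if name in selected:
                continue
            try:
                cand = fit_mlr(y, cov, selected + [name])
            except Exception as exc:
                log.warning("stepwise: candidate %s skipped (%s)", name, exc)
                continue
            if cand.aic < best_aic - 1e-9:
                best_aic, best_name, best_model = cand.aic, name, cand
        if best_name is not None:
            selected.append(best_name)
            current = best_model
            trace.append(("add", "mean", best_name, best_aic))
            improved = True
    current.selection_trace = trace
    return current


def _stepwise_beinf(y, cov, candidates, family, max_cycles) -> FittedModel:
    cov_names: dict[str, list[str]] = {p: [] for p in _active_params(family)}
    current = fit_beinf(y, cov, cov_names, family=family)
    trace = []
    for _ in range(max_cycles):
        moved = False
        for param in _active_params(family):
            # forward additions on this parameter
            improved = True
            while improved:
                improved = False
                best = (current.aic, None, None)
                for name in candidates:
                    if name in cov_names[param]:
                        continue
                    trial = {p: list(v) for p, v in cov_names.items()}
                    trial[param] = trial[param] + [name]
                    cand = _try_fit(y, cov, trial, family)
                    if cand is not None and cand.aic < best[0] - 1e-9:
                        best = (cand.aic, name, cand)
                if best[1] is not None:
                    cov_names[param].append(best[1])
                    current = best[2]
                    trace.append(("add", param, best[1], best[0]))
                    improved = moved = True
            # backward eliminations on this parameter
            improved = True
            while improved and cov_names[param]:
                improved = False
                best = (current.aic, None, None)
                for name in cov_names[param]:
                    trial = {p: list(v) for p, v in cov_names.items()}
                    trial[param] = [t for t in trial[param] if t != name]
                    cand = _try_fit(y, cov, trial, family)
                    if cand is not None and cand.aic < best[0] - 1e-9:
                        best = (cand.aic, name, cand)
                if best[1] is not None:
                    cov_names[param].remove(best[1])
                    current = best[2]
                    trace.append(("drop", param, best[1], best[0]))
                    improved = moved = True
        if not moved:
            break
    current.selection_trace = trace
    return current


def _try_fit(y, cov, cov_names, family) -> FittedModel | None:
    try:
        m = fit_beinf(y, cov, cov_names, family=family)
    except Exception as exc:
        log.warning("stepwise: candidate %s skipped (%s)", cov_names, exc)
        return None
    return m if m.converged else None


def simplify_beinf(full: FittedModel, y, cov: pd.DataFrame,
                   rule: str = "corrected",
                   p_threshold: float = 0.1,
                   aic_window: float = 10.0) -> tuple[FittedModel, dict]:
    """One-step simplification of the selected model to curb overfitting.

    The candidate removal is the last-added coefficient of each
    distribution parameter. Under the default ``"corrected"`` rule a
    coefficient is a removal candidate when it is *not* significant
    (p >= p_threshold) and the simplification is accepted unless it
    worsens AIC by more than ``aic_window``. The ``"literal"`` rule
    applies the source wording verbatim: candidates are coefficients
    with p < p_threshold, and the simplified model is rejected when
    AIC_full - AIC_simplified > aic_window. Returns (accepted model,
    decision record).
    """
    if rule not in ("corrected", "literal"):
        raise ValueError(f"unknown simplification rule {rule!r}")
    y = np.asarray(y, dtype=float)
    decision = {"rule": rule, "candidates": [], "accepted": []}
    current = full
    for param in _active_params(full.family):
        names = current.cov_names.get(param, [])
        if not names:
            continue
        last = names[-1]
        sub = current.coef_table
        pval = sub.loc[(sub["param"] == param) & (sub["term"] == last),
                       "p"].iloc[0]
        if rule == "corrected":
            is_candidate = not (np.isfinite(pval) and pval < p_threshold)
        else:
            is_candidate = bool(np.isfinite(pval) and pval < p_threshold)
        decision["candidates"].append(
            {"param": param, "term": last, "p": float(pval)
             if np.isfinite(pval) else np.nan, "candidate": is_candidate})
        if not is_candidate:
            continue
        trial = {p: list(v) for p, v in current.cov_names.items()}
        trial[param] = trial[param][:-1]
        simplified = _try_fit(y, cov, trial, current.family)
        if simplified is None:
            continue
        if rule == "corrected":
            accept = simplified.aic <= current.aic + aic_window
        else:
            accept = not (current.aic - simplified.aic > aic_window)
        if accept:
            decision["accepted"].append({"param": param, "term": last,
                                         "aic_full": current.aic,
                                         "aic_simplified": simplified.aic})
            current = simplified
    return current, decision


# ---------------------------------------------------------------------------
# Prediction surfaces

def predict_surface(model: FittedModel, stack: RasterStack) -> GridLayer:
    """Per-cell model prediction on the covariate grid.

    E(y) for the inflated-beta families, the linear predictor (log
    scale) for MLR. Cells with nodata in any selected covariate become
    nodata.
    """
    needed = sorted({n for names in model.cov_names.values() for n in names})
    for name in needed:
        if name not in stack:
            raise KeyError(f"covariate layer {name!r} missing from stack")
    grid = stack.grid
    shape = grid.values.shape
    flat = {name: stack[name].values.ravel() for name in needed}
    cov = pd.DataFrame(flat) if flat else None
    n = shape[0] * shape[1]
    ok = np.ones(n, dtype=bool)
    for name in needed:
        ok &= np.isfinite(flat[name])
    pred = np.full(n, np.nan)
    if np.any(ok):
        sub = cov.loc[ok].reset_index(drop=True) if cov is not None else None
        pred[ok] = model.predict(sub, n=int(ok.sum()))
    return grid.with_values(pred.reshape(shape), name="prediction")
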