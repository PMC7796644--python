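"""Time-varying Cox models on counting-process data, WCE estimation,
AIC comparison and proportional-hazards diagnostics.

The partial-likelihood engine is a Newton–Raphson maximiser written
directly on the ``(start, stop]`` representation: a row contributes to
the risk set of every cohort event time ``t_e`` with
``start < t_e <= stop``.  Risk-set sums are accumulated with a
difference-array trick (each row covers a contiguous range of event
indices), which keeps every iteration O(rows × params²) without
materialising per-event risk sets.  Efron (default) and Breslow tie
corrections are supported.

The weighted-cumulative-exposure (WCE) model enters through artificial
covariates ``D_j(t)``: a joint Cox fit of the ``D_j`` plus adjustment
covariates yields spline coefficients whose linear combination is the
estimated weight function ``w(u)`` of time-since-dose, with pointwise
delta-method bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import (DoseHistory, SplineBasis, WeightFunction,
                       make_spline_basis, wce_artificial_covariates)

__all__ = [
    "CoxFitResult", "WeightEstimate", "HRPattern", "PHTestResult",
    "WindowSelection", "fit_cox_tv", "aic", "deviance", "fit_wce",
    "select_window", "hr_for_dose_pattern", "delta_method_band",
    "grambsch_global_test", "schoenfeld_residuals",
    "ConvergenceError", "SingularDesignError",
]


class ConvergenceError(RuntimeError):
    """Newton–Raphson failed to converge (possibly monotone likelihood)."""


class SingularDesignError(ValueError):
    """The design matrix is singular (e.g. a constant covariate)."""


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class CoxFitResult:
    """A fitted time-varying Cox model.

    ``aic = 2k - 2 loglik`` and ``deviance = -2 loglik`` so that
    ``aic = deviance + 2k`` by construction.
    """

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    ties: str
    n_events: int
    n_rows: int
    n_iter: int
    score_norm: float

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def deviance(self) -> float:
        return -2 * self.loglik

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Per-coefficient table: coef, se, HR with Wald CI, z, p."""
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        z = self.params.to_numpy() / se
        zq = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame({
            "term": self.params.index,
            "coef": self.params.to_numpy(),
            "se": se,
            "HR": np.exp(self.params.to_numpy()),
            "CI_low": np.exp(self.params.to_numpy() - zq * se),
            "CI_high": np.exp(self.params.to_numpy() + zq * se),
            "z": z,
            "p": 2 * stats.norm.sf(np.abs(z)),
        })


def aic(fit: CoxFitResult) -> float:
    return fit.aic


def deviance(fit: CoxFitResult) -> float:
    return fit.deviance


@dataclass
class WeightEstimate:
    """Estimated WCE weight function with its coefficient covariance."""

    weight: WeightFunction
    cov: np.ndarray
    window: float

    @property
    def basis(self) -> SplineBasis:
        return self.weight.basis


@dataclass
class HRPattern:
    """Hazard-ratio-versus-time curve for a dosing pattern.

    Reference is a patient with no doses inside the exposure window.
    """

    t: np.ndarray
    hr: np.ndarray
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None


@dataclass
class PHTestResult:
    """Grambsch–Therneau proportional-hazards test."""

    statistic: float
    df: int
    p_value: float
    per_covariate: pd.DataFrame
    transform: str


# ---------------------------------------------------------------------------
# partial-likelihood engine
# ---------------------------------------------------------------------------

def _interval_sums(lo: np.ndarray, hi: np.ndarray, v: np.ndarray, n_events: int) -> np.ndarray:
    """Sum ``v`` over rows covering each event index (difference trick)."""
    acc = (np.bincount(lo, weights=v, minlength=n_events + 1)
           - np.bincount(hi, weights=v, minlength=n_events + 1))
    return np.cumsum(acc)[:n_events]


class _PLData:
    """Preprocessed design for the counting-process partial likelihood."""

    def __init__(self, table: pd.DataFrame, covariates: Sequence[str]):
        self.names = list(covariates)
        missing = [c for c in self.names if c not in table.columns]
        if missing:
            raise ValueError(f"covariate column(s) not in table: {missing}")
        X = table[self.names].to_numpy(float)
        if np.isnan(X).any():
            bad = [c for c in self.names if table[c].isna().any()]
            raise ValueError(f"NaN values in covariate column(s): {bad}")
        start = table["start"].to_numpy(float)
        stop = table["stop"].to_numpy(float)
        ev = table["event"].to_numpy(bool)
        if (start >= stop).any():
            raise ValueError("rows with start >= stop")
        const = [c for c, col in zip(self.names, X.T) if np.ptp(col) == 0]
        if const:
            raise SingularDesignError(f"constant covariate column(s): {const}")
        # centre and scale internally (exact reparametrisation) so the
        # Newton iteration is well conditioned for covariates of any
        # magnitude; estimates are mapped back in fit_cox_tv
        self.center = X.mean(axis=0)
        self.scale = X.std(axis=0)
        X = (X - self.center) / self.scale

        self.event_times = np.unique(stop[ev])
        if self.event_times.size == 0:
            raise ValueError("no events in the table")
        self.E = self.event_times.size
        self.X = X
        self.p = X.shape[1]
        self.n_rows = X.shape[0]
        # row i is at risk for event indices [lo_i, hi_i)
        self.lo = np.searchsorted(self.event_times, start, side="right")
        self.hi = np.searchsorted(self.event_times, stop, side="right")
        # death rows grouped by event time
        self.ev_rows = np.nonzero(ev)[0]
        self.ev_idx = np.searchsorted(self.event_times, stop[self.ev_rows])
        self.d = np.bincount(self.ev_idx, minlength=self.E).astype(float)
        self.sum_x_events = np.zeros(self.p)
        for j in range(self.p):
            self.sum_x_events[j] = X[self.ev_rows, j].sum()
        self.pairs = [(j, k) for j in range(self.p) for k in range(j, self.p)]

    def loglik_score_info(self, beta: np.ndarray, ties: str):
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            return self._loglik_score_info(beta, ties)

    def _loglik_score_info(self, beta: np.ndarray, ties: str):
        X, E, p = self.X, self.E, self.p
        eta = X @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)

        S0 = _interval_sums(self.lo, self.hi, w, E)
        S1 = np.empty((E, p))
        for j in range(p):
            S1[:, j] = _interval_sums(self.lo, self.hi, w * X[:, j], E)
        S2 = np.empty((E, p, p))
        for j, k in self.pairs:
            s = _interval_sums(self.lo, self.hi, w * X[:, j] * X[:, k], E)
            S2[:, j, k] = s
            S2[:, k, j] = s

        if ties == "breslow":
            loglik = eta[self.ev_rows].sum() - float(self.d @ np.log(S0))
            mean = S1 / S0[:, None]
            score = self.sum_x_events - self.d @ mean
            V = S2 / S0[:, None, None] - mean[:, :, None] * mean[:, None, :]
            info = np.einsum("e,ejk->jk", self.d, V)
            return loglik, score, info

        # Efron: subtract fractions of the tied-death sums from the risk sums
        w_ev = w[self.ev_rows]
        s0d = np.bincount(self.ev_idx, weights=w_ev, minlength=E)
        s1d = np.zeros((E, p))
        s2d = np.zeros((E, p, p))
        for j in range(p):
            s1d[:, j] = np.bincount(self.ev_idx, weights=w_ev * X[self.ev_rows, j],
                                    minlength=E)
        for j, k in self.pairs:
            s = np.bincount(self.ev_idx,
                            weights=w_ev * X[self.ev_rows, j] * X[self.ev_rows, k],
                            minlength=E)
            s2d[:, j, k] = s
            s2d[:, k, j] = s

        loglik = eta[self.ev_rows].sum()
        score = self.sum_x_events.copy()
        info = np.zeros((p, p))
        max_d = int(self.d.max())
        for l in range(max_d):
            m = self.d > l
            frac = (l / self.d[m])
            S0l = S0[m] - frac * s0d[m]
            S1l = S1[m] - frac[:, None] * s1d[m]
            S2l = S2[m] - frac[:, None, None] * s2d[m]
            loglik -= float(np.log(S0l).sum())
            mean = S1l / S0l[:, None]
            score -= mean.sum(axis=0)
            V = S2l / S0l[:, None, None] - mean[:, :, None] * mean[:, None, :]
            info += V.sum(axis=0)
        return loglik, score, info

    def loglik_only(self, beta: np.ndarray, ties: str) -> float:
        return self.loglik_score_info(beta, ties)[0]


def fit_cox_tv(table: pd.DataFrame, covariates: Sequence[str], ties: str = "efron",
               tol: float = 1e-8, max_iter: int = 100) -> CoxFitResult:
    """Fit a Cox model on a counting-process table by Newton–Raphson.

    ``covariates`` name numeric columns of ``table``; every covariate
    must be constant within a row.  Convergence requires the score's
    infinity norm to fall below ``tol``.  Raises
    :class:`SingularDesignError` for constant/collinear designs and
    :class:`ConvergenceError` for non-convergence (including diverging
    coefficients symptomatic of a monotone likelihood).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    data = _PLData(table, covariates)
    beta = np.zeros(data.p)
    loglik, score, info = data.loglik_score_info(beta, ties)
    plateau = False
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(
                f"singular information matrix for covariates {data.names}") from exc
        # step-halving on the log partial likelihood
        improved = False
        for _ in range(30):
            cand = beta + step
            ll_new = data.loglik_only(cand, ties)
            if np.isfinite(ll_new) and ll_new >= loglik - 1e-12:
                improved = True
                break
            step = step / 2
        if not improved:
            plateau = True
            break   # loglik flat at double precision; score check decides
        beta = cand
        loglik, score, info = data.loglik_score_info(beta, ties)
        if np.max(np.abs(beta)) > 30:
            raise ConvergenceError(
                "coefficients diverging; likely monotone partial likelihood")
    else:
        it = max_iter
    score_norm = float(np.max(np.abs(score)))
    # On large tables the log likelihood flattens at double precision
    # (|loglik| * eps) before the score reaches the strict tolerance;
    # a standardized score of 1e-4 corresponds to a coefficient
    # perturbation orders of magnitude below statistical precision, so
    # a plateau there still counts as converged (cf. coxph's relative
    # loglik criterion).
    if score_norm >= 1e-4:
        raise ConvergenceError(
            f"no convergence after {it} iterations (score norm {score_norm:.3g})")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError("singular information at the optimum") from exc
    beta = beta / data.scale
    cov = cov / np.outer(data.scale, data.scale)
    return CoxFitResult(
        params=pd.Series(beta, index=data.names),
        cov=pd.DataFrame(cov, index=data.names, columns=data.names),
        loglik=float(loglik), ties=ties, n_events=len(data.ev_rows),
        n_rows=data.n_rows, n_iter=it, score_norm=score_norm)


# ---------------------------------------------------------------------------
# WCE estimation
# ---------------------------------------------------------------------------

def _lag_quantile_knots(table: pd.DataFrame, histories: Mapping, window: float,
                        n_interior: int) -> np.ndarray | None:
    """Interior knots at quantiles of observed (event-time − dose-time) lags."""
    ev = table.loc[table["event"].astype(bool), "stop"].to_numpy(float)
    dose_times = np.concatenate([h.times for h in histories.values() if len(h)]
                                or [np.empty(0)])
    if ev.size == 0 or dose_times.size == 0:
        return None
    if dose_times.size > 4000:
        dose_times = dose_times[:: dose_times.size // 4000 + 1]
    lags = ev[:, None] - dose_times[None, :]
    lags = lags[(lags > 0) & (lags <= window)]
    if lags.size < 10 * n_interior:
        return None
    q = np.quantile(lags, np.arange(1, n_interior + 1) / (n_interior + 1))
    q = np.unique(q[(q > 0) & (q < window)])
    return q if q.size == n_interior else None


def add_wce_columns(table: pd.DataFrame, histories: Mapping, basis: SplineBasis,
                    prefix: str = "wce_d") -> list:
    """Append artificial covariates D_1..D_J evaluated at each row's stop."""
    J = basis.n_basis
    names = [f"{prefix}{j + 1}" for j in range(J)]
    D = np.zeros((len(table), J))
    stops = table["stop"].to_numpy(float)
    pids = table["patient_id"].to_numpy()
    for pid, idx in pd.Series(np.arange(len(table))).groupby(pids).groups.items():
        hist = histories.get(pid)
        if hist is not None and len(hist):
            loc = np.asarray(idx)
            D[loc] = wce_artificial_covariates(hist, basis, stops[loc])
    for j, name in enumerate(names):
        table[name] = D[:, j]
    return names


def fit_wce(table: pd.DataFrame, histories: Mapping, window: float,
            n_interior_knots: int = 1, constrained: bool = False,
            adjust_covariates: Sequence[str] = (), ties: str = "efron",
            knot_placement: str = "lag_quantiles"):
    """Estimate the WCE weight function by a joint Cox fit.

    Builds the cubic B-spline basis on [0, window] (interior knots at
    quantiles of the observed dose lags by default, equally spaced as
    fallback), appends the artificial covariates to a copy of the
    table, fits them jointly with ``adjust_covariates`` and returns
    ``(CoxFitResult, WeightEstimate)``.
    """
    interior = None
    if knot_placement == "lag_quantiles":
        interior = _lag_quantile_knots(table, histories, window, n_interior_knots)
    basis = make_spline_basis(window, n_interior_knots, constrained,
                              interior_knots=interior)
    work = table.copy()
    dnames = add_wce_columns(work, histories, basis)
    fit = fit_cox_tv(work, list(dnames) + list(adjust_covariates), ties=ties)
    theta = fit.params[dnames].to_numpy()
    cov_theta = fit.cov.loc[dnames, dnames].to_numpy()
    west = WeightEstimate(weight=WeightFunction(theta, basis), cov=cov_theta,
                          window=float(window))
    return fit, west


@dataclass
class WindowSelection:
    """AIC-based choice among candidate exposure windows."""

    best_window: float
    aic_table: pd.DataFrame          # window, aic, converged, note
    fits: dict = field(default_factory=dict)   # window -> (CoxFitResult, WeightEstimate)


def select_window(table: pd.DataFrame, histories: Mapping,
                  candidate_windows: Sequence[float] = (120.0, 365.0, 730.0),
                  **fit_kwargs) -> WindowSelection:
    """Fit one WCE model per candidate window and pick the minimum AIC.

    Ties prefer the smaller window.  Candidates that fail to converge
    are recorded in the AIC table (with the failure reason) and
    excluded from the argmin.
    """
    if len(candidate_windows) < 2:
        raise ValueError("need at least 2 candidate windows")
    rows, fits = [], {}
    for w in sorted(candidate_windows):
        try:
            fit, west = fit_wce(table, histories, w, **fit_kwargs)
            fits[w] = (fit, west)
            rows.append({"window": w, "aic": fit.aic, "converged": True, "note": ""})
        except (ConvergenceError, SingularDesignError) as exc:
            import warnings
            warnings.warn(f"WCE window {w}: {exc}")
            rows.append({"window": w, "aic": np.nan, "converged": False,
                         "note": str(exc)})
    tab = pd.DataFrame(rows)
    ok = tab[tab["converged"]]
    if ok.empty:
        raise ConvergenceError("no candidate window converged")
    best = float(ok.sort_values(["aic", "window"]).iloc[0]["window"])
    return WindowSelection(best_window=best, aic_table=tab, fits=fits)


# ---------------------------------------------------------------------------
# HR curves and bands
# ---------------------------------------------------------------------------

def hr_for_dose_pattern(weight_or_unit_loghr, pattern: Sequence, t_grid,
                        half_life: float = 20.0) -> HRPattern:
    """Hazard ratio over time for a dosing pattern versus no exposure.

    ``pattern`` is a sequence of ``(day, dose)`` administrations.  With
    a :class:`WeightFunction`/:class:`WeightEstimate` first argument,
    ``HR(t) = exp(sum_k X(t_k) w(t - t_k))`` with contributions only
    from lags inside the window (an estimate with covariance also gets
    pointwise 95% delta-method bands).  With a scalar first argument it
    is interpreted as the unit log-HR of the theoretical-blood-
    concentration model: ``HR(t) = exp(loghr * TBC(t))`` with the given
    half-life.
    """
    t_arr = np.atleast_1d(np.asarray(t_grid, dtype=float))
    times = np.asarray([p[0] for p in pattern], dtype=float)
    doses = np.asarray([p[1] for p in pattern], dtype=float)
    hist = DoseHistory(times, doses)

    if isinstance(weight_or_unit_loghr, (int, float, np.floating)):
        from .exposure import tbc
        conc = tbc(hist, t_arr, half_life=half_life) if len(hist) else np.zeros_like(t_arr)
        lp = float(weight_or_unit_loghr) * np.atleast_1d(conc)
        return HRPattern(t=t_arr, hr=np.exp(lp))

    if isinstance(weight_or_unit_loghr, WeightEstimate):
        weight, cov = weight_or_unit_loghr.weight, weight_or_unit_loghr.cov
    else:
        weight, cov = weight_or_unit_loghr, None
    basis = weight.basis
    b = wce_artificial_covariates(hist, basis, t_arr)   # (m, J): sum_k X_k B(t-t_k)
    lp = b @ weight.coefficients
    lo = hi = None
    if cov is not None:
        var = np.einsum("ij,jk,ik->i", b, cov, b)
        se = np.sqrt(np.maximum(var, 0.0))
        lo, hi = np.exp(lp - 1.96 * se), np.exp(lp + 1.96 * se)
    return HRPattern(t=t_arr, hr=np.exp(lp), lo=lo, hi=hi)


def hr_at_concentration(unit_hr: float, concentration) -> np.ndarray | float:
    """HR of the concentration model at a given blood level.

    With a fitted hazard ratio ``unit_hr`` per 1 mg/kg, a patient at
    ``concentration`` mg/kg has ``HR = unit_hr ** concentration``
    versus an unexposed patient.
    """
    return unit_hr ** np.asarray(concentration, dtype=float) if np.ndim(concentration) \
        else float(unit_hr) ** float(concentration)


def delta_method_band(weight_estimate: WeightEstimate, u_grid) -> pd.DataFrame:
    """Pointwise 95% band for the weight function: w(u) ± 1.96·se(u).

    ``var(w(u)) = b(u)' Cov(theta) b(u)`` with ``b(u)`` the basis
    evaluations.  Where the covariance is degenerate (non-finite) the
    band is reported as NaN.
    """
    u = np.atleast_1d(np.asarray(u_grid, dtype=float))
    B = weight_estimate.basis.evaluate(u)
    w = B @ weight_estimate.weight.coefficients
    cov = weight_estimate.cov
    if not np.all(np.isfinite(cov)):
        se = np.full(u.shape, np.nan)
    else:
        var = np.einsum("ij,jk,ik->i", B, cov, B)
        se = np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame({"u": u, "w": w, "lo": w - 1.96 * se, "hi": w + 1.96 * se})


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics
# ---------------------------------------------------------------------------

def schoenfeld_residuals(fit: CoxFitResult, table: pd.DataFrame):
    """Per-death Schoenfeld residuals ``x_i - xbar(t_i; beta-hat)``.

    Returns ``(death_times, residual matrix)`` ordered by event time.
    The risk-set mean uses Breslow weighting; with continuous event
    times (no ties) this coincides with the Efron form.
    """
    data = _PLData(table, list(fit.params.index))
    beta = fit.params.to_numpy() * data.scale       # internal standardized scale
    w = np.exp(np.clip(data.X @ beta, -500, 500))
    S0 = _interval_sums(data.lo, data.hi, w, data.E)
    S1 = np.empty((data.E, data.p))
    for j in range(data.p):
        S1[:, j] = _interval_sums(data.lo, data.hi, w * data.X[:, j], data.E)
    xbar = S1 / S0[:, None]
    order = np.argsort(data.ev_idx, kind="stable")
    rows = data.ev_rows[order]
    idx = data.ev_idx[order]
    resid = (data.X[rows] - xbar[idx]) * data.scale  # back to original scale
    return data.event_times[idx], resid


def _km_survival(table: pd.DataFrame, event_times: np.ndarray) -> np.ndarray:
    """Kaplan–Meier S(t) at each event time (right-continuous)."""
    start = table["start"].to_numpy(float)
    stop = table["stop"].to_numpy(float)
    ev = table["event"].to_numpy(bool)
    lo = np.searchsorted(event_times, start, side="right")
    hi = np.searchsorted(event_times, stop, side="right")
    n_at_risk = _interval_sums(lo, hi, np.ones(len(table)), event_times.size)
    d = np.bincount(np.searchsorted(event_times, stop[ev]),
                    minlength=event_times.size).astype(float)
    return np.cumprod(1.0 - d / n_at_risk)


def grambsch_global_test(fit: CoxFitResult, table: pd.DataFrame,
                         transform: str = "km") -> PHTestResult:
    """Global Grambsch–Therneau test of proportional hazards.

    Regresses the scaled Schoenfeld residuals on a transform g(t) of
    event time (``km`` default: g = 1 − KM(t); also ``identity`` and
    ``rank``) and tests the slope.  Uses the classic pooled-variance
    approximation ``V(t) ≈ I / d``: the global statistic is
    ``d · U' I⁻¹ U / Σ (g − ḡ)²`` with ``U = Σ (g_k − ḡ) s_k``,
    chi-square with df = number of coefficients under the null.
    """
    if fit.n_events == 0:
        raise ValueError("no events: proportional-hazards test undefined")
    times, resid = schoenfeld_residuals(fit, table)
    d = resid.shape[0]
    uniq = np.unique(times)
    if transform == "km":
        surv = _km_survival(table, uniq)
        g = 1.0 - surv[np.searchsorted(uniq, times)]
    elif transform == "identity":
        g = times.astype(float)
    elif transform == "rank":
        g = stats.rankdata(times)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    gc = g - g.mean()
    denom = float(gc @ gc)
    U = gc @ resid                                     # (p,)
    inv_info = fit.cov.to_numpy()                      # I^{-1} at beta-hat
    global_stat = float(d * U @ inv_info @ U / denom)
    p_global = float(stats.chi2.sf(global_stat, fit.k))

    scaled = d * (resid @ inv_info)                    # scaled Schoenfeld residuals
    num = gc @ scaled                                  # d * (U inv_info)
    per_stat = num ** 2 / (d * np.diag(inv_info) * denom)
    per = pd.DataFrame({
        "term": fit.params.index,
        "chisq": per_stat,
        "df": 1,
        "p": stats.chi2.sf(per_stat, 1),
    })
    return PHTestResult(statistic=global_stat, df=fit.k, p_value=p_global,
                        per_covariate=per, transform=transform)
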