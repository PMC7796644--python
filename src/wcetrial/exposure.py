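"""Time-varying drug-exposure metrics computed from dose histories.

Five metrics summarise a patient's past dosing at analysis time ``t``:

* **CE** — cumulative dose, the plain sum of all doses given strictly
  before ``t``.
* **CEQ** — quantile categories of CE(t) within the risk set at ``t``
  (tertiles or quartiles of the non-zero values).
* **StCE** — risk-set z-score standardisation of CE(t).
* **TBC** — theoretical blood concentration: doses weighted by
  one-compartment exponential decay ``0.5**((t - t_k)/half_life)``.
* **WCE** — weighted cumulative exposure: doses weighted by an arbitrary
  smooth weight function ``w(t - t_k)`` represented on a cubic B-spline
  basis, estimated from the data via artificial covariates.

All metrics use the strict-past convention: a dose administered exactly
at ``t`` does not contribute to the exposure at ``t`` (it contributes at
every later time).  Doses are in treatment units; one unit is one cure
(5 mg/kg for the motivating drug).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "DoseHistory",
    "ExposureSpec",
    "SplineBasis",
    "WeightFunction",
    "cumulative_exposure",
    "quantile_categories",
    "standardize_exposure",
    "tbc",
    "make_spline_basis",
    "wce_artificial_covariates",
    "DegenerateRiskSetError",
]

SPLINE_DEGREE = 3


class DegenerateRiskSetError(ValueError):
    """Raised when quantile categories cannot be formed at some time."""


# ---------------------------------------------------------------------------
# dose histories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseHistory:
    """Ordered dose administrations ``(t_k, X(t_k))`` for one patient.

    Times are days relative to the analysis origin and must be strictly
    increasing; doses must be non-negative.  Negative times are allowed
    (doses received before a shifted baseline).
    """

    times: np.ndarray
    doses: np.ndarray

    def __init__(self, times: Sequence[float], doses: Sequence[float]):
        t = np.asarray(times, dtype=float)
        d = np.asarray(doses, dtype=float)
        if t.shape != d.shape or t.ndim != 1:
            raise ValueError("times and doses must be 1-d arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("dose times must be strictly increasing")
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "doses", d)

    def __len__(self) -> int:
        return self.times.size

    def restricted(self, min_time: float = 0.0) -> "DoseHistory":
        """History keeping only doses at ``time >= min_time`` (scope filter)."""
        keep = self.times >= min_time
        return DoseHistory(self.times[keep], self.doses[keep])

    @staticmethod
    def from_frame(doses: pd.DataFrame) -> dict:
        """Map patient_id -> DoseHistory from a (patient_id, time, dose) frame.

        Same-day administrations are summed into a single event.
        """
        out = {}
        for pid, grp in doses.groupby("patient_id", sort=False):
            agg = grp.groupby("time", sort=True)["dose"].sum()
            out[pid] = DoseHistory(agg.index.to_numpy(float), agg.to_numpy(float))
        return out


@dataclass(frozen=True)
class ExposureSpec:
    """Which metric to compute and with what parameters.

    scope 'cfi_only' drops doses received before the shifted baseline
    (negative times); 'overall' keeps them.
    """

    kind: Literal["CE", "CEQ", "StCE", "TBC", "WCE"]
    scope: Literal["cfi_only", "overall"] = "overall"
    n_quantiles: int = 4                      # CEQ: p
    scheme: Literal["model3a", "model3b"] = "model3b"
    half_life: float = 20.0                   # TBC: days
    window: float = 120.0                     # WCE: days
    n_interior_knots: int = 1
    constrained_right_end: bool = False

    def __post_init__(self):
        if self.half_life <= 0:
            raise ValueError("half_life must be > 0")
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.kind == "CEQ" and self.n_quantiles not in (3, 4):
            raise ValueError("n_quantiles must be 3 or 4")


# ---------------------------------------------------------------------------
# simple metrics
# ---------------------------------------------------------------------------

def cumulative_exposure(history: DoseHistory, t) -> np.ndarray | float:
    """CE(t) = sum of doses received strictly before ``t``.

    Vectorised over ``t``; returns a scalar for scalar input.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    csum = np.concatenate([[0.0], np.cumsum(history.doses)])
    idx = np.searchsorted(history.times, t_arr, side="left")
    out = csum[idx]
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def tbc(history: DoseHistory, t, half_life: float = 20.0) -> np.ndarray | float:
    """Theoretical blood concentration under one-compartment decay.

    TBC(t) = sum_{t_k < t} X(t_k) * 0.5**((t - t_k)/half_life).
    Units follow the dose units (multiply by 5 for mg/kg when one unit
    is a 5 mg/kg cure).
    """
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    if len(history):
        lags = t_arr[:, None] - history.times[None, :]
        w = np.where(lags > 0, 0.5 ** (np.maximum(lags, 0.0) / half_life), 0.0)
        out = w @ history.doses
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def standardize_exposure(ce_at_t: Sequence[float]) -> np.ndarray:
    """Risk-set z-scores of cumulative doses at one evaluation time.

    Uses the sample (n-1) standard deviation.  A degenerate risk set
    (sd = 0) maps every value to 0 by convention.
    """
    v = np.asarray(ce_at_t, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 patients at risk to standardize")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def quantile_categories(ce_at_t: Sequence[float], spec: ExposureSpec,
                        maintenance: Sequence[bool] | None = None,
                        t: float | None = None) -> np.ndarray:
    """Categorise risk-set cumulative doses into quantile groups.

    model3a (tertiles, CFI scope): labels 'control' (reference),
    'maintenance_zero' for maintenance patients with CE(t)=0, and
    'T1'..'T3' tertiles of the non-zero maintenance values.  Requires
    the ``maintenance`` indicator.

    model3b (quartiles, overall scope): labels 'Q1' (reference) .. 'Q4';
    cutpoints are quartiles of the non-zero values; zero values fall in
    'Q1'.

    Cutpoints use the linear-interpolation ("type 7") quantile
    convention on the risk-set values at this time; ties go to the
    lower category.
    """
    v = np.asarray(ce_at_t, dtype=float)
    p = 3 if spec.scheme == "model3a" else spec.n_quantiles
    where = f" at t={t}" if t is not None else ""

    if spec.scheme == "model3a":
        if maintenance is None:
            raise ValueError("model3a requires the maintenance-arm indicator")
        m = np.asarray(maintenance, dtype=bool)
        labels = np.full(v.shape, "control", dtype=object)
        labels[m & (v == 0)] = "maintenance_zero"
        pool = v[m & (v > 0)]
        names = [f"T{i}" for i in range(1, p + 1)]
        target = m & (v > 0)
    else:
        labels = np.empty(v.shape, dtype=object)
        pool = v[v > 0]
        names = [f"Q{i}" for i in range(1, p + 1)]
        labels[v == 0] = names[0]
        target = v > 0

    if pool.size < p or np.unique(pool).size < p:
        raise DegenerateRiskSetError(
            f"fewer than {p} distinct non-zero cumulative doses in the risk set{where}")
    cuts = np.quantile(pool, np.arange(1, p) / p)  # type-7 default
    if np.unique(cuts).size < p - 1:
        raise DegenerateRiskSetError(f"tied quantile cutpoints in the risk set{where}")
    # ties to the lower category: value == cutpoint stays below it
    cat = np.searchsorted(cuts, v[target], side="left")
    labels[target] = np.asarray(names, dtype=object)[cat]
    return labels


# ---------------------------------------------------------------------------
# spline basis and WCE artificial covariates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineBasis:
    """Cubic B-spline basis on the lag interval [0, window].

    ``evaluate(u)`` returns the (len(u), J) design matrix; lags outside
    (0, window] evaluate to zero rows, implementing the finite exposure
    window.  With ``constrained_right_end`` the last two basis functions
    are dropped so every representable weight function satisfies
    w(window) = 0 (and w'(window) = 0).
    """

    window: float
    knots: np.ndarray
    n_dropped: int = 0

    @property
    def n_basis(self) -> int:
        return len(self.knots) - SPLINE_DEGREE - 1 - self.n_dropped

    def evaluate(self, u) -> np.ndarray:
        u_arr = np.atleast_1d(np.asarray(u, dtype=float))
        out = np.zeros((u_arr.size, self.n_basis))
        ok = (u_arr >= 0) & (u_arr <= self.window)
        if ok.any():
            dm = BSpline.design_matrix(u_arr[ok], self.knots, SPLINE_DEGREE).toarray()
            out[ok] = dm[:, : self.n_basis]
        return out


def make_spline_basis(window: float, n_interior_knots: int = 1,
                      constrained_right_end: bool = False,
                      interior_knots: Sequence[float] | None = None) -> SplineBasis:
    """Build the cubic B-spline basis for weight-function estimation.

    Interior knots default to equally spaced positions; pass
    ``interior_knots`` explicitly (e.g. quantiles of observed dose lags)
    to override.  Unconstrained basis size is
    ``n_interior_knots + degree + 1``.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if interior_knots is None:
        if n_interior_knots not in (1, 2, 3):
            raise ValueError("n_interior_knots must be in {1, 2, 3}")
        interior = window * np.arange(1, n_interior_knots + 1) / (n_interior_knots + 1)
    else:
        interior = np.sort(np.asarray(interior_knots, dtype=float))
        if interior.size and (interior[0] <= 0 or interior[-1] >= window):
            raise ValueError("interior knots must lie strictly inside (0, window)")
    if interior.size and np.min(np.diff(np.r_[0.0, interior, window])) <= 0:
        raise ValueError("window too small for the requested knot spacing")
    knots = np.r_[[0.0] * (SPLINE_DEGREE + 1), interior, [window] * (SPLINE_DEGREE + 1)]
    return SplineBasis(window=float(window), knots=knots,
                       n_dropped=2 if constrained_right_end else 0)


@dataclass(frozen=True)
class WeightFunction:
    """w(u) = sum_j theta_j B_j(u) on [0, window]; zero outside."""

    coefficients: np.ndarray
    basis: SplineBasis

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (self.basis.n_basis,):
            raise ValueError("coefficient length must match basis size")
        object.__setattr__(self, "coefficients", c)

    def __call__(self, u) -> np.ndarray | float:
        out = self.basis.evaluate(u) @ self.coefficients
        return float(out[0]) if np.ndim(u) == 0 else out


def wce_artificial_covariates(history: DoseHistory, basis: SplineBasis, t) -> np.ndarray:
    """Artificial covariates D_j(t) = sum_{0 < t - t_k <= window} X(t_k) B_j(t - t_k).

    For any coefficient vector theta, ``D(t) @ theta`` equals the
    weighted cumulative exposure with weight function
    ``w = sum_j theta_j B_j``.  Vectorised over ``t``: returns shape
    (len(t), J), or (J,) for scalar ``t``.
    """
    scalar = np.ndim(t) == 0
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros((t_arr.size, basis.n_basis))
    if len(history):
        lags = t_arr[:, None] - history.times[None, :]          # (m, K)
        valid = (lags > 0) & (lags <= basis.window)
        if valid.any():
            rows, cols = np.nonzero(valid)
            bvals = basis.evaluate(lags[rows, cols])            # (nnz, J)
            contrib = bvals * history.doses[cols][:, None]
            np.add.at(out, rows, contrib)
    return out[0] if scalar else out


def project_weight_function(func, basis: SplineBasis, n_grid: int = 400) -> WeightFunction:
    """Least-squares projection of an arbitrary w(u) onto the basis.

    Used to express parametric weight shapes (e.g. exponential decay)
    in spline coordinates, for consistency checks between the TBC and
    WCE formulations.
    """
    u = np.linspace(0.0, basis.window, n_grid)
    B = basis.evaluate(u)
    y = np.asarray([func(x) for x in u], dtype=float)
    theta, *_ = np.linalg.lstsq(B, y, rcond=None)
    return WeightFunction(theta, basis)
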