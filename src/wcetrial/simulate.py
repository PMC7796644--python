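"""Synthetic maintenance-trial cohorts with a known exposure effect.

The generator emulates the structure of a two-arm maintenance RCT in
metastatic colorectal cancer: a 24-week biweekly induction in both
arms, then alternating chemotherapy-free intervals (CFI) — during which
only the maintenance arm keeps receiving the biologic — and 16-week
re-treatment chemotherapy sequences in both arms.  Dosing is thinned by
per-patient adherence and truncated at protocol discontinuation;
time-varying covariates are assessed every 8 weeks; survival times are
drawn by inverting a daily-piecewise-constant hazard whose linear
predictor contains a *known* function of past doses (exponential-decay
concentration or an explicit weight function), so that every estimator
in the package can be checked against the generating truth.

The default parameter values are the study conditions of the motivating
trial where published (arm balance, induction and re-treatment lengths,
discontinuation-category proportions, ~84% deaths, median time to death
about 16 months) and field-realistic placeholders where not (CFI-length
distribution, adherence, covariate volatilities); see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .exposure import DoseHistory, tbc
from .trial_data import TIME_VARYING_COLUMNS

__all__ = ["SimConfig", "TrueModel", "SimulatedCohort", "generate_cohort",
           "sample_periods", "generate_dosing", "generate_covariate_paths",
           "simulate_event_times", "simulate_cohort", "truth_report"]


@dataclass(frozen=True)
class SimConfig:
    """Generative specification of a synthetic maintenance-trial cohort."""

    n_patients: int = 382
    allocation_maintenance: float = 0.5
    induction_cycles: int = 12          # biweekly cycles, both arms
    cycle_days: float = 14.0
    cfi_median_days: float = 120.0      # log-normal CFI length
    cfi_log_sd: float = 0.5
    chemo_cycles: int = 8               # re-treatment sequence length
    adherence_prob: float = 0.8         # per scheduled CFI dose, maintenance arm
    discontinuation_rate: float = 5.1e-4    # per day; ~48% stop by 4 years
    discontinuation_weights: tuple = (0.287, 0.083, 0.113)  # investigator/toxicity/other
    progression_rate: float = 7.0e-4    # per day; ~11% progress within 6 months
    lost_prob: float = 0.003
    missing_covariate_prob: float = 0.027
    horizon_days: float = 1460.0        # administrative censoring from randomization
    assessment_interval: float = 56.0   # 8-weekly covariate updates
    ps_up_prob: float = 0.08
    ps_down_prob: float = 0.03
    tox_on_prob: float = 0.10           # per assessment with recent dosing
    tox_off_prob: float = 0.30
    weight_volatility: float = 1.0      # kg per assessment (random walk sd)
    hemoglobin_volatility: float = 0.3
    bilirubin_volatility: float = 0.05
    bp_volatility: float = 2.0

    def __post_init__(self):
        if not 0 <= self.allocation_maintenance <= 1:
            raise ValueError("allocation must be a probability")
        if self.horizon_days <= 0:
            raise ValueError("horizon must be positive")


@dataclass(frozen=True)
class TrueModel:
    """The generating hazard: h(t) = h0 * exp(effect·Exposure(t) + γ'Z(t)).

    ``exposure_kind`` 'tbc' uses log-HR ``loghr_per_unit`` per mg/kg of
    the exponential-decay concentration (one dose unit = ``mg_per_unit``
    mg/kg) with ``half_life``; the default −0.22/(mg/kg) is hazard
    ratio 0.80 per 1 mg/kg of circulating drug.  'wce' adds an explicit
    per-unit-dose weight function ``weight_function(u)`` supported on
    [0, window] directly to the log-hazard; 'none' removes the exposure
    effect.  ``covariate_loghr`` maps numeric design columns (e.g.
    'who_ps', 'sex_f') to log-HRs; ``arm_loghr`` is a direct,
    non-exposure arm effect for emulating confounding by indication.
    """

    baseline_hazard: float = 0.003      # per day (level after the last break)
    hazard_breaks: tuple = (182.0,)     # piecewise-constant baseline profile
    hazard_multipliers: tuple = (0.55, 1.0)
    exposure_kind: str = "tbc"
    loghr_per_unit: float = -0.22       # per mg/kg of TBC
    mg_per_unit: float = 5.0            # one cure = 5 mg/kg
    half_life: float = 20.0
    weight_function: Callable | None = None
    window: float = 120.0
    covariate_loghr: dict = field(default_factory=lambda: {"who_ps": 0.3, "sex_f": -0.15})
    arm_loghr: float = 0.0

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if len(self.hazard_multipliers) != len(self.hazard_breaks) + 1:
            raise ValueError("need one hazard multiplier per profile segment")
        if self.exposure_kind not in ("tbc", "wce", "none"):
            raise ValueError("exposure_kind must be 'tbc', 'wce' or 'none'")
        if self.exposure_kind == "wce" and self.weight_function is None:
            raise ValueError("exposure_kind 'wce' requires a weight_function")


@dataclass
class SimulatedCohort:
    """Generated records plus the generating truth (kept segregated)."""

    patients: pd.DataFrame
    doses: pd.DataFrame
    updates: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame       # validation only; never fed to estimators
    config: SimConfig
    true_model: TrueModel


# ---------------------------------------------------------------------------
# patients and protocol structure
# ---------------------------------------------------------------------------

_AGE_GROUPS = ["<65", "65-74", ">=75"]
_AGE_P = [0.52, 0.306, 0.174]
_SITES = ["left", "right_transverse", "unspecified_colon", "rectum"]
_SITE_P = [0.33, 0.23, 0.23, 0.21]
_PS_P = [0.54, 0.41, 0.05]


def generate_cohort(config: SimConfig, seed) -> pd.DataFrame:
    """Baseline patient records; arms balanced to the allocation ratio."""
    if config.n_patients < 2:
        raise ValueError("need at least 2 patients")
    rng = np.random.default_rng(seed)
    n = config.n_patients
    n_maint = int(round(n * config.allocation_maintenance))
    arms = np.array(["maintenance"] * n_maint + ["control"] * (n - n_maint), dtype=object)
    rng.shuffle(arms)
    pat = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "arm": arms,
        "age_group": rng.choice(_AGE_GROUPS, size=n, p=_AGE_P),
        "sex": rng.choice(["F", "M"], size=n, p=[0.35, 0.65]),
        "primary_resected": rng.random(n) < 0.5,
        "alk_phos_gt300": rng.random(n) < 0.18,
        "tumor_site": rng.choice(_SITES, size=n, p=_SITE_P),
        "randomization_time": 0.0,
    })
    miss = rng.random(n) < config.missing_covariate_prob
    pat.loc[miss, "tumor_site"] = np.nan
    return pat


def sample_periods(config: SimConfig, rng) -> list:
    """Alternating protocol periods (kind, start, end) up to the horizon."""
    periods = [("induction", 0.0, config.induction_cycles * config.cycle_days)]
    t = periods[0][2]
    while t < config.horizon_days:
        L = float(np.exp(rng.normal(np.log(config.cfi_median_days), config.cfi_log_sd)))
        # snap to whole treatment cycles so dosing stays on the biweekly grid
        L = max(config.cycle_days, round(L / config.cycle_days) * config.cycle_days)
        periods.append(("cfi", t, min(t + L, config.horizon_days)))
        t += L
        if t >= config.horizon_days:
            break
        chemo_len = config.chemo_cycles * config.cycle_days
        periods.append(("chemo", t, min(t + chemo_len, config.horizon_days)))
        t += chemo_len
    return periods


def generate_dosing(arm: str, periods: list, config: SimConfig, rng,
                    disc_time: float = np.inf) -> DoseHistory:
    """Unit doses under the protocol, thinned by adherence during CFI.

    Both arms dose biweekly during induction and re-treatment
    chemotherapy; only the maintenance arm doses during CFI, with each
    scheduled administration taken with probability ``adherence_prob``.
    No doses at or after ``disc_time`` (protocol discontinuation).
    """
    times = []
    for kind, t0, t1 in periods:
        if kind == "cfi" and arm != "maintenance":
            continue
        sched = np.arange(t0, t1, config.cycle_days)
        if kind == "cfi":
            sched = sched[rng.random(sched.size) < config.adherence_prob]
        times.append(sched)
    t = np.concatenate(times) if times else np.empty(0)
    t = np.unique(t[t < disc_time])
    return DoseHistory(t, np.ones_like(t))


def generate_covariate_paths(pat_row, config: SimConfig, rng,
                             dose_times: np.ndarray) -> pd.DataFrame:
    """8-weekly covariate assessments as bounded random walks.

    WHO performance status is a Markov chain on {0,1,2} drifting upward;
    the toxicity indicator can switch on after recent dosing and off
    otherwise; continuous covariates take Gaussian steps and are clipped
    to physiologic ranges.  Volatility 0 keeps every covariate at its
    baseline value.
    """
    days = np.arange(0.0, config.horizon_days, config.assessment_interval)
    m = days.size
    ps = np.empty(m, dtype=int)
    tox = np.zeros(m, dtype=bool)
    ps[0] = rng.choice([0, 1, 2], p=_PS_P)
    weight = np.empty(m)
    hb = np.empty(m)
    bili = np.empty(m)
    bp = np.empty(m)
    weight[0] = np.clip(rng.normal(70, 12), 45, 120)
    hb[0] = np.clip(rng.normal(12.5, 1.5), 8, 17)
    bili[0] = np.clip(rng.lognormal(np.log(8.0), 0.3), 2, 40)
    bp[0] = np.clip(rng.normal(130, 12), 90, 180)
    for i in range(1, m):
        u = rng.random()
        if u < config.ps_up_prob and ps[i - 1] < 2:
            ps[i] = ps[i - 1] + 1
        elif u < config.ps_up_prob + config.ps_down_prob and ps[i - 1] > 0:
            ps[i] = ps[i - 1] - 1
        else:
            ps[i] = ps[i - 1]
        recent = np.any((dose_times >= days[i] - config.assessment_interval)
                        & (dose_times < days[i]))
        if tox[i - 1]:
            tox[i] = rng.random() >= config.tox_off_prob
        else:
            tox[i] = recent and rng.random() < config.tox_on_prob
        weight[i] = np.clip(weight[i - 1] + rng.normal(0, config.weight_volatility)
                            if config.weight_volatility > 0 else weight[i - 1], 40, 130)
        hb[i] = np.clip(hb[i - 1] + rng.normal(0, config.hemoglobin_volatility)
                        if config.hemoglobin_volatility > 0 else hb[i - 1], 7, 18)
        bili[i] = np.clip(bili[i - 1] + rng.normal(0, config.bilirubin_volatility)
                          if config.bilirubin_volatility > 0 else bili[i - 1], 2, 50)
        bp[i] = np.clip(bp[i - 1] + rng.normal(0, config.bp_volatility)
                        if config.bp_volatility > 0 else bp[i - 1], 80, 200)
    return pd.DataFrame({
        "patient_id": pat_row["patient_id"], "time": days, "who_ps": ps,
        "any_toxicity": tox, "weight_kg": weight, "hemoglobin": hb,
        "bilirubin": bili, "blood_pressure": bp,
    })


# ---------------------------------------------------------------------------
# hazard and event times
# ---------------------------------------------------------------------------

def _exposure_at(times: np.ndarray, hist: DoseHistory, model: TrueModel) -> np.ndarray:
    """True exposure metric at arbitrary times (single source of truth)."""
    if model.exposure_kind == "none" or not len(hist):
        return np.zeros(times.size)
    if model.exposure_kind == "tbc":
        return model.mg_per_unit * np.atleast_1d(tbc(hist, times, half_life=model.half_life))
    lags = times[:, None] - hist.times[None, :]
    w = np.where((lags > 0) & (lags <= model.window),
                 model.weight_function(np.clip(lags, 0, model.window)), 0.0)
    return w @ hist.doses


def _linear_predictor(days_mid: np.ndarray, hist: DoseHistory, model: TrueModel,
                      fixed_lp: float, updates: pd.DataFrame) -> np.ndarray:
    lp = fixed_lp + np.zeros(days_mid.size)
    if model.exposure_kind == "tbc":
        lp += model.loghr_per_unit * _exposure_at(days_mid, hist, model)
    elif model.exposure_kind == "wce":
        lp += _exposure_at(days_mid, hist, model)
    tv_cols = [c for c in model.covariate_loghr if c in TIME_VARYING_COLUMNS]
    if tv_cols:
        upd_t = updates["time"].to_numpy(float)
        idx = np.clip(np.searchsorted(upd_t, days_mid, side="right") - 1, 0, None)
        for c in tv_cols:
            lp += model.covariate_loghr[c] * updates[c].to_numpy(float)[idx]
    return lp


_FIXED_ENCODERS = {
    "arm_maintenance": lambda r: float(r["arm"] == "maintenance"),
    "age_65_74": lambda r: float(r["age_group"] == "65-74"),
    "age_ge75": lambda r: float(r["age_group"] == ">=75"),
    "sex_f": lambda r: float(r["sex"] == "F"),
    "primary_resected": lambda r: float(bool(r["primary_resected"])),
    "alk_phos_gt300": lambda r: float(bool(r["alk_phos_gt300"])),
    "site_right_transverse": lambda r: float(r["tumor_site"] == "right_transverse"),
    "site_unspecified": lambda r: float(r["tumor_site"] == "unspecified_colon"),
    "site_rectum": lambda r: float(r["tumor_site"] == "rectum"),
}


def _fixed_lp(pat_row, model: TrueModel) -> float:
    lp = model.arm_loghr * float(pat_row["arm"] == "maintenance")
    for c, coef in model.covariate_loghr.items():
        if c in _FIXED_ENCODERS:
            lp += coef * _FIXED_ENCODERS[c](pat_row)
    return lp


def simulate_event_times(hist: DoseHistory, updates: pd.DataFrame, pat_row,
                         model: TrueModel, config: SimConfig, rng):
    """Invert the daily cumulative hazard for one patient.

    The hazard is constant on each day ``[d, d+1)`` with the linear
    predictor evaluated at the day's midpoint; the event time
    ``T = inf{t: H(t) >= E}`` with ``E ~ Exp(1)`` is then continuous.
    Returns ``(death_time or inf, daily linear predictor)``.
    """
    horizon = int(np.ceil(config.horizon_days))
    if horizon <= 0:
        raise ValueError("degenerate horizon: no follow-up to simulate")
    mids = np.arange(horizon) + 0.5
    lp = _linear_predictor(mids, hist, model, _fixed_lp(pat_row, model), updates)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite hazard in simulation")
    seg = np.searchsorted(np.asarray(model.hazard_breaks, float), mids, side="right")
    h0 = model.baseline_hazard * np.asarray(model.hazard_multipliers, float)[seg]
    haz = h0 * np.exp(lp)
    cum = np.cumsum(haz)
    e = rng.exponential()
    if e >= cum[-1]:
        return np.inf, lp
    d = int(np.searchsorted(cum, e))
    prev = cum[d - 1] if d > 0 else 0.0
    return d + (e - prev) / haz[d], lp


# ---------------------------------------------------------------------------
# cohort assembly and truth report
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig, true_model: TrueModel, seed) -> SimulatedCohort:
    """Generate a complete cohort; a pure function of (configs, seed)."""
    rng = np.random.default_rng(seed)
    patients = generate_cohort(config, rng)
    dose_frames, upd_frames, out_rows, truth_rows = [], [], [], []
    weights = np.asarray(config.discontinuation_weights, dtype=float)
    weights = weights / weights.sum()
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        periods = sample_periods(config, rng)
        disc_time = rng.exponential(1.0 / config.discontinuation_rate)
        disc_cat = rng.choice(["investigator", "toxicity", "other"], p=weights)
        hist = generate_dosing(row["arm"], periods, config, rng, disc_time=disc_time)
        updates = generate_covariate_paths(row, config, rng, hist.times)
        death, lp = simulate_event_times(hist, updates, row, true_model, config, rng)
        lost_time = (rng.uniform(30.0, config.horizon_days)
                     if rng.random() < config.lost_prob else np.inf)
        end = float(min(death, lost_time, config.horizon_days))
        event = death <= min(lost_time, config.horizon_days)
        prog = rng.exponential(1.0 / config.progression_rate)
        out_rows.append({"patient_id": pid, "followup_end": end, "event": bool(event),
                         "progression_day": prog if prog <= end else np.nan,
                         "discontinuation_day": disc_time if disc_time < end else np.nan,
                         "discontinuation_category": disc_cat if disc_time < end else ""})
        keep = hist.times < end
        dose_frames.append(pd.DataFrame({"patient_id": pid, "time": hist.times[keep],
                                         "dose": hist.doses[keep]}))
        upd_frames.append(updates[updates["time"] <= end])
        grid = np.arange(0.0, end, config.cycle_days)
        truth_rows.append(pd.DataFrame({
            "patient_id": pid, "day": grid,
            "true_exposure": _exposure_at(grid + 1e-9, hist, true_model),
            "true_lp": lp[np.minimum(grid.astype(int), lp.size - 1)],
        }))
    doses = pd.concat(dose_frames, ignore_index=True)
    updates = pd.concat(upd_frames, ignore_index=True)
    outcomes = pd.DataFrame(out_rows)
    truth = pd.concat(truth_rows, ignore_index=True)
    return SimulatedCohort(patients=patients, doses=doses, updates=updates,
                           outcomes=outcomes[["patient_id", "followup_end", "event",
                                              "progression_day"]],
                           truth=truth, config=config, true_model=true_model)


def truth_report(cohort: SimulatedCohort) -> pd.DataFrame:
    """Per-patient true exposure trajectory and linear predictor.

    Computed with the same exposure code paths as estimation; used only
    for validating parameter recovery, never as an analysis input.
    """
    return cohort.truth.copy()
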