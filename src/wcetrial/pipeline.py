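"""End-to-end analysis suite: landmark, build exposures, fit models 1–6.

The suite mirrors a maintenance-trial re-analysis plan: an ITT model
using only the randomization arm (model 1), cumulative-dose models in
continuous (2a/2b), quantile-categorised (3a/3b) and risk-set
standardised (4a/4b) form — 'a' restricting exposure to doses received
after the shifted baseline (the chemotherapy-free-interval scope), 'b'
counting all doses including induction — a fixed-half-life
theoretical-blood-concentration model (5) and the spline-estimated
weighted-cumulative-exposure model at the AIC-selected window (6).
Every model is fitted on the identical cohort, person-time and
adjustment set, with a global proportional-hazards test per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cox import (CoxFitResult, WindowSelection, fit_cox_tv, fit_wce,
                  grambsch_global_test, select_window, delta_method_band,
                  ConvergenceError, SingularDesignError)
from .exposure import (DoseHistory, DegenerateRiskSetError, ExposureSpec,
                       cumulative_exposure, quantile_categories,
                       standardize_exposure, tbc)
from .trial_data import (Cohort, build_counting_process, shift_baseline,
                         write_long_csv, TIME_VARYING_COLUMNS,
                         FIXED_DESIGN_COLUMNS, DEFAULT_LANDMARK_DAYS)

__all__ = ["RunConfig", "ModelRecord", "ModelSuiteResult", "run_model_suite",
           "sensitivity_suite", "render_reports", "add_recent_dose_indicator",
           "attach_ce", "attach_tbc", "attach_stce", "attach_ceq",
           "MODEL_IDS", "ADJUST_FIXED", "ADJUST_TV"]

MODEL_IDS = ["1", "2a", "2b", "3a", "3b", "4a", "4b", "5", "6"]
ADJUST_FIXED = [c for c in FIXED_DESIGN_COLUMNS if c != "arm_maintenance"]
ADJUST_TV = list(TIME_VARYING_COLUMNS)

_DESCRIPTIONS = {
    "1": "ITT: randomization arm only",
    "2a": "arm + cumulative dose (CFI scope)",
    "2b": "arm + cumulative dose (overall)",
    "3a": "cumulative-dose tertile categories (CFI scope)",
    "3b": "arm + cumulative-dose quartiles (overall)",
    "4a": "arm + standardized cumulative dose (CFI scope)",
    "4b": "arm + standardized cumulative dose (overall)",
    "5": "arm + theoretical blood concentration (h=20d)",
    "6": "arm + weighted cumulative exposure (AIC-selected window)",
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis suite."""

    landmark_days: float = DEFAULT_LANDMARK_DAYS
    adjustment: str = "full_tv"          # 'full_tv' | 'baseline_only'
    include_arm: bool = True             # arm indicator in models 2-6
    recent_dose_indicator: bool = False  # extra binary 'dose in last N days'
    recent_dose_window: float = 20.0
    wce_windows: tuple = (120.0, 365.0, 730.0)
    wce_n_interior_knots: int = 1
    wce_constrained: bool = False
    tbc_half_life: float = 20.0
    ceq_cfi_quantiles: int = 3
    ceq_overall_quantiles: int = 4
    ties: str = "efron"
    cut_policy: str = "union_of_change_times"
    models: tuple = tuple(MODEL_IDS)

    def __post_init__(self):
        if self.adjustment not in ("full_tv", "baseline_only"):
            raise ValueError("adjustment must be 'full_tv' or 'baseline_only'")
        if not self.wce_windows:
            raise ValueError("wce_windows must be non-empty")


@dataclass
class ModelRecord:
    model_id: str
    description: str
    status: str                      # 'ok' | 'failed'
    fit: CoxFitResult | None = None
    error: str = ""
    grambsch_p: float = np.nan
    note: str = ""


@dataclass
class ModelSuiteResult:
    models: dict
    table: pd.DataFrame
    cohort: Cohort
    window_selection: WindowSelection | None
    weight_estimate: object | None
    config: RunConfig
    n_events: int
    n_rows: int
    dropped_covariates: list = field(default_factory=list)

    def comparison(self) -> pd.DataFrame:
        rows = []
        for mid in self.config.models:
            rec = self.models[mid]
            f = rec.fit
            rows.append({
                "model_id": mid, "description": rec.description,
                "status": rec.status,
                "k": f.k if f else np.nan,
                "loglik": f.loglik if f else np.nan,
                "deviance": f.deviance if f else np.nan,
                "aic": f.aic if f else np.nan,
                "grambsch_p": rec.grambsch_p,
                "note": rec.note,
            })
        return pd.DataFrame(rows)

    def hr_table(self) -> pd.DataFrame:
        frames = []
        for mid in self.config.models:
            rec = self.models[mid]
            if rec.fit is not None:
                s = rec.fit.summary()
                s.insert(0, "model_id", mid)
                frames.append(s)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    @property
    def all_converged(self) -> bool:
        return all(self.models[m].status == "ok" for m in self.config.models)


# ---------------------------------------------------------------------------
# exposure column attachment
# ---------------------------------------------------------------------------

def _per_patient_apply(table: pd.DataFrame, histories: Mapping, func) -> np.ndarray:
    out = np.zeros(len(table))
    stops = table["stop"].to_numpy(float)
    pids = table["patient_id"].to_numpy()
    for pid, idx in pd.Series(np.arange(len(table))).groupby(pids).groups.items():
        hist = histories.get(pid)
        loc = np.asarray(idx)
        if hist is not None and len(hist):
            out[loc] = func(hist, stops[loc])
    return out


def attach_ce(table: pd.DataFrame, histories: Mapping, name: str) -> None:
    """Cumulative dose at each row's stop time."""
    table[name] = _per_patient_apply(table, histories,
                                     lambda h, t: cumulative_exposure(h, t))


def attach_tbc(table: pd.DataFrame, histories: Mapping, name: str,
               half_life: float = 20.0, mg_per_unit: float = 5.0) -> None:
    """Theoretical blood concentration at each row's stop time.

    Reported in mg/kg by default (one unit dose = 5 mg/kg), so the
    fitted hazard ratio reads "per 1 mg/kg of circulating drug".
    """
    table[name] = _per_patient_apply(
        table, histories, lambda h, t: mg_per_unit * tbc(h, t, half_life=half_life))


def _risk_set_frame(table: pd.DataFrame, histories: Mapping):
    """Per-patient CE at every event-time stop, with at-risk masks."""
    ev_times = np.unique(table.loc[table["event"].astype(bool), "stop"].to_numpy(float))
    ends = table.groupby("patient_id")["stop"].max()
    pids = ends.index.to_numpy()
    ce = np.zeros((pids.size, ev_times.size))
    for i, pid in enumerate(pids):
        h = histories.get(pid)
        if h is not None and len(h):
            ce[i] = cumulative_exposure(h, ev_times)
    at_risk = ends.to_numpy(float)[:, None] >= ev_times[None, :]
    return pids, ev_times, ce, at_risk


def attach_stce(table: pd.DataFrame, histories: Mapping, name: str) -> None:
    """Risk-set z-score of the cumulative dose, recomputed at event times.

    Requires the table to be cut at every cohort event time; rows
    ending between event times (which never enter the partial
    likelihood) carry the value of the preceding event time forward,
    zero before the first event.
    """
    pids, ev_times, ce, at_risk = _risk_set_frame(table, histories)
    z = np.zeros_like(ce)
    for j in range(ev_times.size):
        m = at_risk[:, j]
        z[m, j] = standardize_exposure(ce[m, j]) if m.sum() >= 2 else 0.0
    _assign_from_event_grid(table, pids, ev_times, {name: z})


def attach_ceq(table: pd.DataFrame, histories: Mapping, prefix: str,
               scheme: str, arm_by_pid: Mapping) -> list:
    """Quantile-category dummies of the cumulative dose at event times.

    model3a: dummies ``{prefix}_m_zero, {prefix}_T1..T3`` (control is
    the all-zero reference); model3b: ``{prefix}_Q2..Q4`` (first
    quartile, including zero-dose patients, is the reference).  Raises
    :class:`DegenerateRiskSetError` if an *event-time* risk set has too
    few distinct non-zero doses.
    """
    spec = ExposureSpec(kind="CEQ", scheme=scheme,
                        n_quantiles=3 if scheme == "model3a" else 4)
    pids, ev_times, ce, at_risk = _risk_set_frame(table, histories)
    maint = np.array([arm_by_pid[p] == "maintenance" for p in pids])
    levels = (["maintenance_zero", "T1", "T2", "T3"] if scheme == "model3a"
              else ["Q2", "Q3", "Q4"])
    names = [f"{prefix}_{lev}" if not lev.startswith("maintenance")
             else f"{prefix}_m_zero" for lev in levels]
    dummies = {n: np.zeros_like(ce) for n in names}
    for j in range(ev_times.size):
        m = at_risk[:, j]
        labels = quantile_categories(ce[m, j], spec, maintenance=maint[m],
                                     t=float(ev_times[j]))
        for lev, n in zip(levels, names):
            col = np.zeros(ce.shape[0])
            col[m] = (labels == lev)
            dummies[n][:, j] = col
    _assign_from_event_grid(table, pids, ev_times, dummies)
    return names


def _assign_from_event_grid(table: pd.DataFrame, pids: np.ndarray,
                            ev_times: np.ndarray, grids: dict) -> None:
    """Map per-(patient, event-time) values onto rows by their stop.

    Rows whose stop is not an event time take the preceding event
    time's value (zero before the first event).
    """
    pid_pos = {p: i for i, p in enumerate(pids)}
    row_pid = table["patient_id"].map(pid_pos).to_numpy()
    stops = table["stop"].to_numpy(float)
    j = np.searchsorted(ev_times, stops, side="right") - 1
    exact = np.isin(stops, ev_times)
    valid = j >= 0
    for name, grid in grids.items():
        vals = np.zeros(len(table))
        vals[valid] = grid[row_pid[valid], j[valid]]
        table[name] = vals
    table.attrs.setdefault("event_grid_exact", {}).update(
        {n: float(exact.mean()) for n in grids})


def add_recent_dose_indicator(table: pd.DataFrame, histories: Mapping,
                              window_days: float = 20.0,
                              name: str = "recent_dose") -> str:
    """Binary 'received a dose in the last ``window_days``' indicator.

    The indicator is 1 on rows whose *start* lies within
    ``window_days`` after any dose (0 <= start − t_k <= window_days).
    """
    if window_days <= 0:
        raise ValueError("window_days must be > 0")
    starts = table["start"].to_numpy(float)
    out = np.zeros(len(table))
    pids = table["patient_id"].to_numpy()
    for pid, idx in pd.Series(np.arange(len(table))).groupby(pids).groups.items():
        hist = histories.get(pid)
        if hist is None or not len(hist):
            continue
        loc = np.asarray(idx)
        lags = starts[loc][:, None] - hist.times[None, :]
        out[loc] = ((lags >= 0) & (lags <= window_days)).any(axis=1).astype(float)
    table[name] = out
    return name


# ---------------------------------------------------------------------------
# the suite
# ---------------------------------------------------------------------------

def _baseline_only(table: pd.DataFrame) -> pd.DataFrame:
    """Freeze each time-varying covariate at its baseline (first-row) value."""
    out = table.copy()
    first = out.sort_values("start").groupby("patient_id")[ADJUST_TV].first()
    for col in ADJUST_TV:
        out[col] = out["patient_id"].map(first[col]).to_numpy()
    return out


def prepare_table(patients, doses, updates, outcomes, config: RunConfig):
    """Landmark, cut, and attach every exposure column the suite needs."""
    cohort = shift_baseline(patients, doses, updates, outcomes,
                            landmark_days=config.landmark_days)
    table = build_counting_process(cohort, cut_policy=config.cut_policy)
    if config.adjustment == "baseline_only":
        table = _baseline_only(table)
    hist_all = DoseHistory.from_frame(cohort.doses)
    hist_overall = hist_all
    hist_cfi = {p: h.restricted(0.0) for p, h in hist_all.items()}
    arm_by_pid = cohort.patients.set_index("patient_id")["arm"].to_dict()

    attach_ce(table, hist_cfi, "ce_cfi")
    attach_ce(table, hist_overall, "ce_overall")
    attach_tbc(table, hist_overall, "tbc", half_life=config.tbc_half_life)
    attach_stce(table, hist_cfi, "stce_cfi")
    attach_stce(table, hist_overall, "stce_overall")
    ceq_cols = {}
    for mid, hists, scheme in (("3a", hist_cfi, "model3a"),
                               ("3b", hist_overall, "model3b")):
        try:
            ceq_cols[mid] = attach_ceq(table, hists, f"ceq{mid}", scheme, arm_by_pid)
        except DegenerateRiskSetError as exc:
            ceq_cols[mid] = exc
    if config.recent_dose_indicator:
        add_recent_dose_indicator(table, hist_overall, config.recent_dose_window)
    return cohort, table, hist_overall, hist_cfi, ceq_cols


def run_model_suite(patients, doses, updates, outcomes,
                    config: RunConfig = RunConfig()) -> ModelSuiteResult:
    """Fit the full suite of models 1–6 on one analysis cohort.

    Individual model failures (non-convergence, degenerate risk sets)
    are recorded per model without aborting the suite.
    """
    cohort, table, hist_overall, hist_cfi, ceq_cols = prepare_table(
        patients, doses, updates, outcomes, config)
    adjust = list(ADJUST_FIXED) + ADJUST_TV
    if config.recent_dose_indicator:
        adjust = adjust + ["recent_dose"]
    # constant adjustment covariates are inestimable in a Cox model;
    # drop them once, globally, so every model sees the same design
    dropped = [c for c in adjust if table[c].nunique() <= 1]
    adjust = [c for c in adjust if c not in dropped]
    arm = ["arm_maintenance"] if config.include_arm else []

    covariate_sets = {
        "1": ["arm_maintenance"] + adjust,
        "2a": arm + ["ce_cfi"] + adjust,
        "2b": arm + ["ce_overall"] + adjust,
        "3a": (ceq_cols["3a"] + adjust
               if not isinstance(ceq_cols["3a"], Exception) else ceq_cols["3a"]),
        "3b": (arm + ceq_cols["3b"] + adjust
               if not isinstance(ceq_cols["3b"], Exception) else ceq_cols["3b"]),
        "4a": arm + ["stce_cfi"] + adjust,
        "4b": arm + ["stce_overall"] + adjust,
        "5": arm + ["tbc"] + adjust,
    }

    models = {}
    selection = None
    weight_est = None
    for mid in config.models:
        rec = ModelRecord(model_id=mid, description=_DESCRIPTIONS[mid], status="ok")
        try:
            if mid == "6":
                selection = select_window(table, hist_overall,
                                          candidate_windows=config.wce_windows,
                                          n_interior_knots=config.wce_n_interior_knots,
                                          constrained=config.wce_constrained,
                                          adjust_covariates=arm + adjust,
                                          ties=config.ties)
                fit, weight_est = selection.fits[selection.best_window]
                rec.note = f"window={selection.best_window:g}d"
                # Grambsch on the selected model's artificial covariates
                work = table.copy()
                from .cox import add_wce_columns
                add_wce_columns(work, hist_overall, weight_est.basis)
                gram_table = work
            else:
                cset = covariate_sets[mid]
                if isinstance(cset, Exception):
                    raise cset
                fit = fit_cox_tv(table, cset, ties=config.ties)
                gram_table = table
            rec.fit = fit
            try:
                rec.grambsch_p = grambsch_global_test(fit, gram_table).p_value
            except (ValueError, np.linalg.LinAlgError) as exc:
                rec.note = (rec.note + "; " if rec.note else "") + f"grambsch failed: {exc}"
        except (ConvergenceError, SingularDesignError, DegenerateRiskSetError,
                ValueError) as exc:
            rec.status = "failed"
            rec.error = f"{type(exc).__name__}: {exc}"
        models[mid] = rec

    n_events = int(table["event"].sum())
    fitted = [m.fit for m in models.values() if m.fit is not None]
    assert all(f.n_events == n_events for f in fitted), \
        "models fitted on differing person-time"
    return ModelSuiteResult(models=models, table=table, cohort=cohort,
                            window_selection=selection, weight_estimate=weight_est,
                            config=config, n_events=n_events, n_rows=len(table),
                            dropped_covariates=dropped)


def sensitivity_suite(patients, doses, updates, outcomes,
                      config: RunConfig = RunConfig()) -> dict:
    """Main suite plus baseline-only-adjustment and recent-dose variants.

    All three suites run on the identical cohort; the returned dict has
    keys 'main', 'baseline_only', 'recent_dose' and 'differences' (a
    per-model, per-term log-HR difference table versus the main suite).
    """
    suites = {
        "main": run_model_suite(patients, doses, updates, outcomes, config),
        "baseline_only": run_model_suite(
            patients, doses, updates, outcomes,
            replace(config, adjustment="baseline_only")),
        "recent_dose": run_model_suite(
            patients, doses, updates, outcomes,
            replace(config, recent_dose_indicator=True)),
    }
    diffs = []
    main = suites["main"]
    for variant in ("baseline_only", "recent_dose"):
        for mid in config.models:
            a, b = main.models[mid], suites[variant].models[mid]
            if a.fit is None or b.fit is None:
                continue
            common = a.fit.params.index.intersection(b.fit.params.index)
            for term in common:
                diffs.append({"variant": variant, "model_id": mid, "term": term,
                              "loghr_main": a.fit.params[term],
                              "loghr_variant": b.fit.params[term],
                              "delta_loghr": b.fit.params[term] - a.fit.params[term]})
    suites["differences"] = pd.DataFrame(diffs)
    return suites


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def render_reports(result: ModelSuiteResult, outdir, seed=None) -> dict:
    """Write comparison CSV/markdown, HR table, weight CSV and run log.

    Output is a deterministic function of (result, seed label): no
    timestamps, so identical runs are byte-identical.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    comp = result.comparison()
    paths["model_comparison"] = out / "model_comparison.csv"
    comp.to_csv(paths["model_comparison"], index=False)

    hr = result.hr_table()
    paths["hr_table"] = out / "hr_table.csv"
    hr.to_csv(paths["hr_table"], index=False)

    if result.weight_estimate is not None:
        w = result.weight_estimate
        band = delta_method_band(w, np.linspace(0.0, w.window, 121))
        paths["weights"] = out / "weights_model6.csv"
        band.to_csv(paths["weights"], index=False)

    paths["long"] = out / "long.csv"
    write_long_csv(result.table, paths["long"])

    md = ["| model | description | k | deviance | AIC | Grambsch p |",
          "|---|---|---|---|---|---|"]
    for _, r in comp.iterrows():
        if r["status"] == "ok":
            md.append(f"| {r['model_id']} | {r['description']} | {int(r['k'])} | "
                      f"{r['deviance']:.1f} | {r['aic']:.1f} | {r['grambsch_p']:.2f} |")
        else:
            md.append(f"| {r['model_id']} | {r['description']} | failed |  |  |  |")
    paths["markdown"] = out / "comparison.md"
    paths["markdown"].write_text("\n".join(md) + "\n")

    cfg = asdict(result.config)
    paths["config"] = out / "config_resolved.yaml"
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))

    log = [f"seed: {seed}", f"n_patients: {result.cohort.n_patients}",
           f"n_events: {result.n_events}", f"n_rows: {result.n_rows}",
           f"exclusions: {result.cohort.exclusions}",
           f"all_converged: {result.all_converged}"]
    if result.window_selection is not None:
        log.append("wce_window_aic: " + ", ".join(
            f"{r.window:g}d={r.aic:.1f}" if r.converged else f"{r.window:g}d=failed"
            for r in result.window_selection.aic_table.itertuples()))
        log.append(f"wce_window_selected: {result.window_selection.best_window:g}d")
    paths["log"] = out / "run.log"
    paths["log"].write_text("\n".join(log) + "\n")
    return paths
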