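"""Trial data model: landmarking and counting-process table construction.

The analysis clock is restarted ("landmarked") at a fixed time after
randomization — by default 182 days, the expected start of the first
chemotherapy-free interval — restricting the cohort to patients still
alive, progression-free, in follow-up and fully observed at that time.
Each remaining patient's follow-up is then cut into counting-process
rows ``(start, stop]`` on which every covariate is constant, the format
consumed by all time-varying Cox fits.

Canonical in-memory containers are pandas DataFrames with the schemas
below; light dataclasses are not used because every operation is
cohort-level and vectorised.

patients : patient_id, arm ('maintenance'|'control'), age_group
    ('<65'|'65-74'|'>=75'), sex ('F'|'M'), primary_resected (bool),
    alk_phos_gt300 (bool), tumor_site ('left'|'right_transverse'|
    'unspecified_colon'|'rectum'), randomization_time (days)
doses : patient_id, time (days), dose (units; 1 unit = one cure = 5 mg/kg)
updates : patient_id, time, who_ps (0/1/2), any_toxicity (bool),
    weight_kg, hemoglobin, bilirubin, blood_pressure
outcomes : patient_id, followup_end (days), event (bool),
    progression_day (float, NaN if none)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "DEFAULT_LANDMARK_DAYS",
    "shift_baseline",
    "build_counting_process",
    "read_trial_csv",
    "write_trial_csv",
    "write_long_csv",
    "read_long_csv",
    "validate_counting_process",
    "TIME_VARYING_COLUMNS",
    "FIXED_DESIGN_COLUMNS",
]

DEFAULT_LANDMARK_DAYS = 182.0

PATIENT_COLUMNS = ["patient_id", "arm", "age_group", "sex", "primary_resected",
                   "alk_phos_gt300", "tumor_site", "randomization_time"]
DOSE_COLUMNS = ["patient_id", "time", "dose"]
UPDATE_COLUMNS = ["patient_id", "time", "who_ps", "any_toxicity", "weight_kg",
                  "hemoglobin", "bilirubin", "blood_pressure"]
OUTCOME_COLUMNS = ["patient_id", "followup_end", "event", "progression_day"]

TIME_VARYING_COLUMNS = ["who_ps", "any_toxicity", "weight_kg", "hemoglobin",
                        "bilirubin", "blood_pressure"]
#: numeric dummy encoding of the fixed baseline covariates (reference
#: categories: control arm, age <65, male sex, left-colon site)
FIXED_DESIGN_COLUMNS = ["arm_maintenance", "age_65_74", "age_ge75", "sex_f",
                        "primary_resected", "alk_phos_gt300",
                        "site_right_transverse", "site_unspecified", "site_rectum"]

_REQUIRED_BASELINE = ["arm", "age_group", "sex", "primary_resected",
                      "alk_phos_gt300", "tumor_site"]


@dataclass
class Cohort:
    """A landmarked cohort: the four record frames plus exclusion counts."""

    patients: pd.DataFrame
    doses: pd.DataFrame
    updates: pd.DataFrame
    outcomes: pd.DataFrame
    exclusions: dict = field(default_factory=dict)
    landmark_days: float = DEFAULT_LANDMARK_DAYS

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def _check_columns(df: pd.DataFrame, required: list, name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing required column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# landmarking
# ---------------------------------------------------------------------------

def shift_baseline(patients: pd.DataFrame, doses: pd.DataFrame,
                   updates: pd.DataFrame, outcomes: pd.DataFrame,
                   landmark_days: float = DEFAULT_LANDMARK_DAYS) -> Cohort:
    """Shift the analysis origin to ``landmark_days`` after randomization.

    Patients who died, progressed, left follow-up, or had incomplete
    baseline covariates before the landmark are excluded (in that order
    of precedence), with per-category counts reported in
    ``Cohort.exclusions``.  All remaining times are re-expressed
    relative to the landmark; dose events received before it are kept
    with negative times (they still contribute to 'overall'-scope
    exposures) — CFI-scope exposures drop them by their negative sign.
    """
    if landmark_days <= 0:
        raise ValueError("landmark_days must be > 0")
    _check_columns(patients, PATIENT_COLUMNS[:-1], "patients")
    _check_columns(outcomes, ["patient_id", "followup_end", "event"], "outcomes")

    out = outcomes.set_index("patient_id")
    if (out["followup_end"] <= 0).any():
        bad = out.index[out["followup_end"] <= 0].tolist()
        raise ValueError(f"outcome at or before randomization for patient(s) {bad}")

    pat = patients.set_index("patient_id")
    missing_ids = set(pat.index) - set(out.index)
    if missing_ids:
        raise ValueError(f"patients without an outcome record: {sorted(missing_ids)}")

    prog = out.get("progression_day", pd.Series(np.nan, index=out.index))
    died_before = out["event"] & (out["followup_end"] <= landmark_days)
    prog_before = ~died_before & (prog <= landmark_days)
    lost_before = ~died_before & ~prog_before & (out["followup_end"] <= landmark_days)
    incomplete = pat[_REQUIRED_BASELINE].isna().any(axis=1).reindex(out.index, fill_value=True)
    missing_cov = ~died_before & ~prog_before & ~lost_before & incomplete

    excluded = died_before | prog_before | lost_before | missing_cov
    exclusions = {
        "died_before_baseline": int(died_before.sum()),
        "progressed_before_baseline": int(prog_before.sum()),
        "lost_before_baseline": int(lost_before.sum()),
        "missing_covariates": int(missing_cov.sum()),
    }
    keep = out.index[~excluded]

    patients2 = patients[patients["patient_id"].isin(keep)].copy()
    outcomes2 = outcomes[outcomes["patient_id"].isin(keep)].copy()
    outcomes2["followup_end"] = outcomes2["followup_end"] - landmark_days
    doses2 = doses[doses["patient_id"].isin(keep)].copy()
    doses2["time"] = doses2["time"] - landmark_days
    doses2["induction_period"] = doses2["time"] < 0
    updates2 = updates[updates["patient_id"].isin(keep)].copy()
    updates2["time"] = updates2["time"] - landmark_days

    return Cohort(patients=patients2.reset_index(drop=True),
                  doses=doses2.reset_index(drop=True),
                  updates=updates2.reset_index(drop=True),
                  outcomes=outcomes2.reset_index(drop=True),
                  exclusions=exclusions, landmark_days=landmark_days)


# ---------------------------------------------------------------------------
# counting-process table
# ---------------------------------------------------------------------------

def _encode_fixed(pat_row: pd.Series) -> dict:
    return {
        "arm_maintenance": float(pat_row["arm"] == "maintenance"),
        "age_65_74": float(pat_row["age_group"] == "65-74"),
        "age_ge75": float(pat_row["age_group"] == ">=75"),
        "sex_f": float(pat_row["sex"] == "F"),
        "primary_resected": float(bool(pat_row["primary_resected"])),
        "alk_phos_gt300": float(bool(pat_row["alk_phos_gt300"])),
        "site_right_transverse": float(pat_row["tumor_site"] == "right_transverse"),
        "site_unspecified": float(pat_row["tumor_site"] == "unspecified_colon"),
        "site_rectum": float(pat_row["tumor_site"] == "rectum"),
    }


def build_counting_process(cohort: Cohort,
                           cut_policy: str = "union_of_change_times") -> pd.DataFrame:
    """Cut each patient's follow-up into ``(start, stop]`` rows.

    cut_policy:
      * ``event_times`` — cut at every distinct cohort death time;
      * ``daily`` — cut at every integer day;
      * ``union_of_change_times`` (default) — cut at cohort death times
        plus the patient's own dose and covariate-update times, so every
        exposure metric evaluated at a row's stop is exact at all event
        times (the only times the partial likelihood reads covariates).

    Time-varying covariates are last-observation-carried-forward: the
    value on a row is the most recent update at or before its start.
    The event indicator is true only on a dying patient's final row.
    """
    if cut_policy not in ("event_times", "daily", "union_of_change_times"):
        raise ValueError(f"unknown cut_policy {cut_policy!r}")
    out = cohort.outcomes
    event_times = np.unique(out.loc[out["event"].astype(bool), "followup_end"].to_numpy(float))

    doses_by_pid = {pid: g["time"].to_numpy(float)
                    for pid, g in cohort.doses.groupby("patient_id", sort=False)}
    upd_by_pid = {pid: g.sort_values("time")
                  for pid, g in cohort.updates.groupby("patient_id", sort=False)}

    frames = []
    pat = cohort.patients.set_index("patient_id")
    for rec in out.itertuples(index=False):
        pid, end, died = rec.patient_id, float(rec.followup_end), bool(rec.event)
        if end <= 0:
            raise ValueError(f"non-positive follow-up for patient {pid}")
        cuts = [event_times[(event_times > 0) & (event_times < end)]]
        if cut_policy == "daily":
            cuts.append(np.arange(1.0, np.ceil(end)))
        elif cut_policy == "union_of_change_times":
            dt = doses_by_pid.get(pid, np.empty(0))
            cuts.append(dt[(dt > 0) & (dt < end)])
            if pid in upd_by_pid:
                ut = upd_by_pid[pid]["time"].to_numpy(float)
                cuts.append(ut[(ut > 0) & (ut < end)])
        edges = np.unique(np.concatenate([[0.0], *cuts, [end]]))
        start, stop = edges[:-1], edges[1:]
        n = start.size
        df = pd.DataFrame({"patient_id": pid, "start": start, "stop": stop,
                           "event": np.r_[np.zeros(n - 1, bool), died]})
        for k, v in _encode_fixed(pat.loc[pid]).items():
            df[k] = v
        df["arm"] = pat.loc[pid, "arm"]

        if pid in upd_by_pid:
            upd = upd_by_pid[pid]
            late = upd["time"] > end
            if late.any():
                warnings.warn(f"dropping {int(late.sum())} covariate update(s) after "
                              f"follow-up end for patient {pid}")
                upd = upd[~late]
            # LOCF: most recent update at or before each row start
            idx = np.searchsorted(upd["time"].to_numpy(float), start, side="right") - 1
            for col in TIME_VARYING_COLUMNS:
                vals = upd[col].to_numpy()
                df[col] = np.where(idx >= 0, vals[np.clip(idx, 0, None)], np.nan)
        else:
            for col in TIME_VARYING_COLUMNS:
                df[col] = np.nan
        frames.append(df)

    table = pd.concat(frames, ignore_index=True)
    table["any_toxicity"] = table["any_toxicity"].astype(float)
    table["who_ps"] = table["who_ps"].astype(float)
    return table


def validate_counting_process(table: pd.DataFrame) -> None:
    """Assert the counting-process invariants; raise ValueError on violation."""
    if (table["start"] >= table["stop"]).any():
        raise ValueError("rows with start >= stop")
    if (table["start"] < 0).any():
        raise ValueError("rows with negative start")
    for pid, g in table.groupby("patient_id", sort=False):
        g = g.sort_values("start")
        if not np.allclose(g["start"].to_numpy()[1:], g["stop"].to_numpy()[:-1]):
            raise ValueError(f"gaps/overlaps in intervals for patient {pid}")
        ev = g["event"].to_numpy(bool)
        if ev[:-1].any():
            raise ValueError(f"event on a non-final row for patient {pid}")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_CSV_SCHEMAS = {
    "patients.csv": PATIENT_COLUMNS,
    "doses.csv": DOSE_COLUMNS,
    "covariates.csv": UPDATE_COLUMNS,
    "outcomes.csv": ["patient_id", "followup_end", "event"],
}
_BOOL_COLS = {"primary_resected", "alk_phos_gt300", "any_toxicity", "event"}


def _read_one(path: Path, required: list, name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (ValueError, pd.errors.ParserError) as exc:  # pragma: no cover - passthrough
        raise ValueError(f"could not parse {name}: {exc}") from exc
    _check_columns(df, required, name)
    for col in df.columns:
        if col in _BOOL_COLS:
            if df[col].dtype == object:
                df[col] = df[col].astype(str).str.lower().map(
                    {"true": True, "false": False, "1": True, "0": False})
                if df[col].isna().any():
                    row = int(df.index[df[col].isna()][0]) + 2  # header + 1-based
                    raise ValueError(f"unparseable boolean in {name} at line {row}, "
                                     f"column {col!r}")
            df[col] = df[col].astype(bool)
    return df


def read_trial_csv(directory) -> tuple:
    """Read (patients, doses, updates, outcomes) from the four trial CSVs."""
    d = Path(directory)
    patients = _read_one(d / "patients.csv", PATIENT_COLUMNS, "patients.csv")
    doses = _read_one(d / "doses.csv", DOSE_COLUMNS, "doses.csv")
    updates = _read_one(d / "covariates.csv", UPDATE_COLUMNS, "covariates.csv")
    outcomes = _read_one(d / "outcomes.csv", _CSV_SCHEMAS["outcomes.csv"], "outcomes.csv")
    if "progression_day" not in outcomes.columns:
        outcomes["progression_day"] = np.nan
    return patients, doses, updates, outcomes


def write_trial_csv(directory, patients: pd.DataFrame, doses: pd.DataFrame,
                    updates: pd.DataFrame, outcomes: pd.DataFrame) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    patients.to_csv(d / "patients.csv", index=False)
    doses[DOSE_COLUMNS].to_csv(d / "doses.csv", index=False)
    updates.to_csv(d / "covariates.csv", index=False)
    outcomes.to_csv(d / "outcomes.csv", index=False)


def write_long_csv(table: pd.DataFrame, path) -> None:
    """Write a counting-process table (UTF-8, header row, stable order)."""
    cols = ["patient_id", "start", "stop", "event"]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False)


def read_long_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["patient_id", "start", "stop", "event"], str(path))
    df["event"] = df["event"].astype(bool)
    return df
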