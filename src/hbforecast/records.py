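"""Hb-anchored feature records from longitudinal dialysis tables.

One record is built per hemoglobin measurement of every included patient:
the anchor is the Hb date *t*, past-history features are aggregated over the
90-day lookback ``(t-90d, t]`` (dose totals, last available labs, session
means), the planned therapy is summed over the lookforward ``(t, t+90d]``
(in a retrospective extract the administered doses are the prescription),
and the regression target is ``delta_hb = Hb(t+3 months) - Hb(t)``, pairing
the anchor with the Hb measurement nearest to ``t + 90d`` within a +/- 15
day tolerance.  No past-history feature may use information after *t*; only
``esa_future``/``iron_future`` look forward, by design.

Inclusion criteria mirror a retrospective ESA-response study design:
prevalent patients (>= 90 days on dialysis) with >= 6 months of follow-up,
at least one IV darbepoetin administration, and no implausible single dose
(> 400 ug darbepoetin or > 300 mg iron).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InclusionReport",
    "apply_inclusion_criteria",
    "aggregate_dose_window",
    "extract_lab_features",
    "extract_session_features",
    "build_records",
    "save_records",
    "load_records",
    "LAB_ANALYTES",
    "RECORD_COLUMNS",
]

LAB_ANALYTES = ("ferritin", "TSAT", "albumin", "phosphate", "CRP")

#: explicit output column order of the records table
RECORD_COLUMNS = [
    "record_id", "patient_id", "anchor_date", "hb_t",
    "age", "sex", "height", "vintage", "diabetes", "modality", "vascular_access",
    "duration", "sessions_per_week", "ektv_mean", "ektv_sd",
    "pre_weight", "post_weight",
    "esa_dose_90d", "iron_dose_90d",
    "ferritin", "tsat", "albumin", "phosphate", "crp",
    "esa_future", "iron_future",
    "target_date", "delta_hb", "valid",
]


@dataclass
class InclusionReport:
    """Patient counts along the inclusion-filter chain, with per-patient reasons."""

    n_initial: int
    n_after_followup_filter: int
    n_after_esa_filter: int
    n_after_dose_filter: int
    excluded: list = field(default_factory=list)   # [{'patient_id':…,'reason':…}]

    def to_json(self) -> str:
        return json.dumps({
            "n_initial": self.n_initial,
            "n_after_followup_filter": self.n_after_followup_filter,
            "n_after_esa_filter": self.n_after_esa_filter,
            "n_after_dose_filter": self.n_after_dose_filter,
            "excluded": self.excluded,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "InclusionReport":
        return cls(**json.loads(text))


def _require_columns(df: pd.DataFrame, columns: list, table: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {table} table")


def apply_inclusion_criteria(profiles: pd.DataFrame, doses: pd.DataFrame,
                             labs: pd.DataFrame | None = None, *,
                             min_vintage_days: float = 90.0,
                             max_darbepoetin_ug: float = 400.0,
                             max_iron_mg: float = 300.0):
    """Apply the study inclusion filters; returns ``(kept_ids, InclusionReport)``.

    Filter chain (each patient is excluded at the *first* violated rule):

    1. time on treatment — follow-up >= 6 calendar months, and prevalent
       (>= ``min_vintage_days`` on dialysis at entry);
    2. therapy — at least one IV darbepoetin administration;
    3. dose plausibility — no single administration above 400 ug darbepoetin
       or 300 mg iron.

    Applying the function twice to its own output changes nothing
    (idempotent).
    """
    _require_columns(profiles, ["patient_id", "vintage", "followup_start", "followup_end"],
                     "profiles")
    _require_columns(doses, ["patient_id", "drug", "amount"], "doses")

    excluded: list[dict] = []
    kept: list[str] = []

    darbe = doses[doses["drug"] == "darbepoetin"]
    darbe_patients = set(darbe.loc[darbe["amount"] > 0, "patient_id"])
    max_by_drug = doses.groupby(["patient_id", "drug"])["amount"].max()

    stage1: list[str] = []
    for row in profiles.itertuples(index=False):
        start = pd.Timestamp(row.followup_start)
        end = pd.Timestamp(row.followup_end)
        if end < start + pd.DateOffset(months=6):
            excluded.append({"patient_id": row.patient_id, "reason": "followup_lt_6_months"})
        elif row.vintage * 365.25 < min_vintage_days:
            excluded.append({"patient_id": row.patient_id, "reason": "not_prevalent"})
        else:
            stage1.append(row.patient_id)

    stage2: list[str] = []
    for pid in stage1:
        if pid not in darbe_patients:
            excluded.append({"patient_id": pid, "reason": "no_iv_darbepoetin"})
        else:
            stage2.append(pid)

    for pid in stage2:
        if max_by_drug.get((pid, "darbepoetin"), 0.0) > max_darbepoetin_ug:
            excluded.append({"patient_id": pid, "reason": "darbepoetin_dose_gt_400ug"})
        elif max_by_drug.get((pid, "iron"), 0.0) > max_iron_mg:
            excluded.append({"patient_id": pid, "reason": "iron_dose_gt_300mg"})
        else:
            kept.append(pid)

    report = InclusionReport(
        n_initial=len(profiles),
        n_after_followup_filter=len(stage1),
        n_after_esa_filter=len(stage2),
        n_after_dose_filter=len(kept),
        excluded=excluded,
    )
    return kept, report


# ---------------------------------------------------------------------------
# window aggregations
# ---------------------------------------------------------------------------

def aggregate_dose_window(doses: pd.DataFrame, patient_id, t,
                          window_start_offset: int, window_end_offset: int,
                          drug: str) -> float:
    """Total dose with date in the half-open window ``(t+start, t+end]``.

    The lookback convention is ``(t-90d, t]`` (anchor-day doses count toward
    history), the lookforward ``(t, t+90d]``; offsets are day counts relative
    to the anchor ``t``.  No doses in the window gives 0.
    """
    if window_start_offset >= window_end_offset:
        raise ValueError("window offsets must define a non-empty interval")
    t = pd.Timestamp(t)
    lo = t + pd.Timedelta(days=window_start_offset)
    hi = t + pd.Timedelta(days=window_end_offset)
    sub = doses[(doses["patient_id"] == patient_id) & (doses["drug"] == drug)]
    dates = pd.to_datetime(sub["date"])
    mask = (dates > lo) & (dates <= hi)
    return float(sub.loc[mask.to_numpy(), "amount"].sum())


def extract_lab_features(labs: pd.DataFrame, patient_id, t, *,
                         analytes: tuple = LAB_ANALYTES,
                         lookback_days: int = 90) -> dict:
    """Last available value per analyte within ``(t-90d, t]``; NaN if absent."""
    t = pd.Timestamp(t)
    lo = t - pd.Timedelta(days=lookback_days)
    sub = labs[labs["patient_id"] == patient_id]
    out = {}
    for analyte in analytes:
        rows = sub[sub["analyte"] == analyte]
        dates = pd.to_datetime(rows["date"])
        mask = ((dates > lo) & (dates <= t)).to_numpy()
        if mask.any():
            idx = dates.to_numpy()[mask].argmax()
            out[analyte] = float(rows.loc[mask, "value"].iloc[idx])
        else:
            out[analyte] = float("nan")
    return out


def extract_session_features(sessions: pd.DataFrame, patient_id, t, *,
                             lookback_days: int = 90) -> dict:
    """Session summaries over ``(t-90d, t]``.

    Means of duration, pre/post weight and eKt/V, the sample sd of eKt/V
    (NaN below two sessions), and the weekly session frequency
    ``7 * n / span`` where the span runs from the first in-window session to
    the anchor day inclusive — so a patient dialyzed thrice weekly scores
    ~3 whether they were present for the whole window or only part of it.
    Zero sessions in the window gives NaN throughout.
    """
    t = pd.Timestamp(t)
    lo = t - pd.Timedelta(days=lookback_days)
    sub = sessions[sessions["patient_id"] == patient_id]
    dates = pd.to_datetime(sub["date"])
    mask = ((dates > lo) & (dates <= t)).to_numpy()
    nan = float("nan")
    if not mask.any():
        return {"ektv_mean": nan, "ektv_sd": nan, "pre_weight": nan,
                "post_weight": nan, "duration": nan, "sessions_per_week": nan}
    win = sub.loc[mask]
    ektv = win["ektv"].to_numpy(dtype=float)
    n = len(win)
    span_days = (t - dates.to_numpy()[mask].min()) / pd.Timedelta(days=1) + 1
    return {
        "ektv_mean": float(ektv.mean()),
        "ektv_sd": float(ektv.std(ddof=1)) if n > 1 else nan,
        "pre_weight": float(win["pre_weight"].mean()),
        "post_weight": float(win["post_weight"].mean()),
        "duration": float(win["duration"].mean()),
        "sessions_per_week": float(7.0 * n / span_days),
    }


# ---------------------------------------------------------------------------
# record assembly
# ---------------------------------------------------------------------------

def _window_sum(day_nums: np.ndarray, cum: np.ndarray, lo: int, hi: int) -> float:
    """Sum of amounts with day in (lo, hi] given sorted days and cumsum."""
    a = np.searchsorted(day_nums, lo, side="right")
    b = np.searchsorted(day_nums, hi, side="right")
    return float(cum[b] - cum[a])


def _day_numbers(dates) -> np.ndarray:
    return pd.to_datetime(dates).to_numpy(dtype="datetime64[D]").astype(np.int64)


class _PatientIndex:
    """Sorted per-patient numpy views for fast repeated window queries."""

    def __init__(self, doses: pd.DataFrame, labs: pd.DataFrame,
                 sessions: pd.DataFrame):
        self.dose: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for drug in ("darbepoetin", "iron"):
            sub = doses[doses["drug"] == drug].sort_values("date") if len(doses) else doses
            if len(sub):
                days = _day_numbers(sub["date"])
                cum = np.concatenate([[0.0], np.cumsum(sub["amount"].to_numpy(dtype=float))])
                self.dose[drug] = (days, cum)
            else:
                self.dose[drug] = (np.empty(0, dtype=np.int64), np.zeros(1))

        self.lab: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for analyte in LAB_ANALYTES:
            sub = labs[labs["analyte"] == analyte].sort_values("date") if len(labs) else labs
            self.lab[analyte] = (_day_numbers(sub["date"]) if len(sub) else np.empty(0, np.int64),
                                 sub["value"].to_numpy(dtype=float) if len(sub) else np.empty(0))

        sess = sessions.sort_values("date") if len(sessions) else sessions
        self.sess_days = _day_numbers(sess["date"]) if len(sess) else np.empty(0, np.int64)
        self.sess = {col: (sess[col].to_numpy(dtype=float) if len(sess) else np.empty(0))
                     for col in ("ektv", "pre_weight", "post_weight", "duration")}

    def dose_sum(self, drug: str, lo: int, hi: int) -> float:
        days, cum = self.dose[drug]
        return _window_sum(days, cum, lo, hi)

    def last_lab(self, analyte: str, lo: int, hi: int) -> float:
        days, values = self.lab[analyte]
        b = np.searchsorted(days, hi, side="right")
        if b == 0 or days[b - 1] <= lo:
            return float("nan")
        return float(values[b - 1])

    def session_block(self, lo: int, hi: int) -> dict:
        a = np.searchsorted(self.sess_days, lo, side="right")
        b = np.searchsorted(self.sess_days, hi, side="right")
        nan = float("nan")
        if b == a:
            return {"ektv_mean": nan, "ektv_sd": nan, "pre_weight": nan,
                    "post_weight": nan, "duration": nan, "sessions_per_week": nan}
        n = b - a
        ektv = self.sess["ektv"][a:b]
        span = hi - self.sess_days[a] + 1
        return {
            "ektv_mean": float(ektv.mean()),
            "ektv_sd": float(ektv.std(ddof=1)) if n > 1 else nan,
            "pre_weight": float(self.sess["pre_weight"][a:b].mean()),
            "post_weight": float(self.sess["post_weight"][a:b].mean()),
            "duration": float(self.sess["duration"][a:b].mean()),
            "sessions_per_week": float(7.0 * n / span),
        }


def build_records(cohort, kept_ids=None, *, lookback_days: int = 90,
                  horizon_days: int = 90, pair_tolerance_days: int = 15) -> pd.DataFrame:
    """One feature record per Hb measurement of every kept patient.

    ``cohort`` is a :class:`~hbforecast.simulate.Cohort` (or any object with
    ``profiles``/``doses``/``labs``/``sessions`` DataFrames in the simulator
    schema).  Records whose anchor has no Hb measurement within
    ``pair_tolerance_days`` of ``t + horizon_days`` are flagged
    ``valid=False`` (no regression target).  Duplicate Hb measurements for
    one patient and date are a data-integrity error.
    """
    profiles, doses = cohort.profiles, cohort.doses
    labs, sessions = cohort.labs, cohort.sessions
    _require_columns(profiles, ["patient_id", "age", "sex", "height", "vintage",
                                "diabetes", "modality", "vascular_access",
                                "followup_start"], "profiles")
    _require_columns(labs, ["patient_id", "date", "analyte", "value"], "labs")

    if kept_ids is None:
        kept_ids = list(profiles["patient_id"])
    kept_set = set(kept_ids)

    rows = []
    dose_g = dict(iter(doses.groupby("patient_id"))) if len(doses) else {}
    lab_g = dict(iter(labs.groupby("patient_id"))) if len(labs) else {}
    sess_g = dict(iter(sessions.groupby("patient_id"))) if len(sessions) else {}
    empty = pd.DataFrame(columns=doses.columns if len(doses) else
                         ["patient_id", "date", "drug", "amount"])

    for prof in profiles.itertuples(index=False):
        pid = prof.patient_id
        if pid not in kept_set:
            continue
        plabs = lab_g.get(pid)
        if plabs is None:
            continue
        hb = plabs[plabs["analyte"] == "Hb"].sort_values("date")
        if len(hb) == 0:
            continue
        hb_days = _day_numbers(hb["date"])
        if len(np.unique(hb_days)) != len(hb_days):
            raise ValueError(f"duplicate Hb measurements for patient {pid}")
        hb_values = hb["value"].to_numpy(dtype=float)
        hb_dates = pd.to_datetime(hb["date"]).to_numpy()

        index = _PatientIndex(dose_g.get(pid, empty), plabs,
                              sess_g.get(pid, pd.DataFrame(columns=sessions.columns)))
        start_day = _day_numbers([prof.followup_start])[0]

        for i in range(len(hb_days)):
            t_day = int(hb_days[i])
            t = pd.Timestamp(hb_dates[i])
            # target: Hb nearest to t + horizon within the tolerance
            target = t_day + horizon_days
            j = np.searchsorted(hb_days, target)
            best, best_gap = -1, pair_tolerance_days + 1
            for cand in (j - 1, j):
                if 0 <= cand < len(hb_days) and cand != i:
                    gap = abs(int(hb_days[cand]) - target)
                    if gap < best_gap:
                        best, best_gap = cand, gap
            valid = best >= 0
            delta_hb = float(hb_values[best] - hb_values[i]) if valid else float("nan")
            target_date = pd.Timestamp(hb_dates[best]) if valid else pd.NaT

            sess = index.session_block(t_day - lookback_days, t_day)
            rows.append({
                "record_id": f"{pid}:{t.strftime('%Y-%m-%d')}",
                "patient_id": pid,
                "anchor_date": t,
                "hb_t": float(hb_values[i]),
                "age": float(prof.age),
                "sex": prof.sex,
                "height": float(prof.height),
                "vintage": float(prof.vintage) + (t_day - start_day) / 365.25,
                "diabetes": int(prof.diabetes),
                "modality": prof.modality,
                "vascular_access": prof.vascular_access,
                "duration": sess["duration"],
                "sessions_per_week": sess["sessions_per_week"],
                "ektv_mean": sess["ektv_mean"],
                "ektv_sd": sess["ektv_sd"],
                "pre_weight": sess["pre_weight"],
                "post_weight": sess["post_weight"],
                "esa_dose_90d": index.dose_sum("darbepoetin", t_day - lookback_days, t_day),
                "iron_dose_90d": index.dose_sum("iron", t_day - lookback_days, t_day),
                "ferritin": index.last_lab("ferritin", t_day - lookback_days, t_day),
                "tsat": index.last_lab("TSAT", t_day - lookback_days, t_day),
                "albumin": index.last_lab("albumin", t_day - lookback_days, t_day),
                "phosphate": index.last_lab("phosphate", t_day - lookback_days, t_day),
                "crp": index.last_lab("CRP", t_day - lookback_days, t_day),
                "esa_future": index.dose_sum("darbepoetin", t_day, t_day + horizon_days),
                "iron_future": index.dose_sum("iron", t_day, t_day + horizon_days),
                "target_date": target_date,
                "delta_hb": delta_hb,
                "valid": valid,
            })

    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def save_records(records: pd.DataFrame, path) -> None:
    """Write the records table as CSV: ISO dates, empty fields for missing."""
    df = records.copy()
    for col in ("anchor_date", "target_date"):
        df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def load_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("anchor_date", "target_date"):
        df[col] = pd.to_datetime(df[col])
    df["valid"] = df["valid"].astype(bool)
    return df[RECORD_COLUMNS]
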