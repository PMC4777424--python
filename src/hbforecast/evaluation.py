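"""Agreement, error and Hb-cycling analyses for the 3-month Hb predictor.

The error convention, fixed once and used everywhere, is

    ``error = observed - predicted``  (Hb at t+3 months, g/dL)

so a positive error means the model under-predicted.  Because a
squared-loss regressor shrinks extreme predictions toward the cohort mean,
the Bland-Altman regression of (observed - predicted) on the pair mean has a
positive slope and the extreme observed-Hb quartiles show opposite-signed
mean errors; both signatures are what the evaluation is designed to surface.
``signed_error_by_quartile`` accepts the opposite convention
(``pred_minus_obs``) since the published sign pattern of this diagnostic
depends on which difference is reported.

Hb-cycling uses the Ebben scheme relative to a closed target band
(default [10, 13] g/dL): each run of 6 consecutive monthly Hb values is
classified as constantly low / in / high, low-amplitude fluctuation crossing
the lower (LAL) or upper (LAH) bound, or high-amplitude fluctuation crossing
both (HA).

Large prediction errors (|error| > 1.5 g/dL) are attributed to adverse
events dated inside the prediction interval (anchor, target]; a record may
count toward several event types, and flagged records without any event are
counted "unexplained".
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model import TrainedModel, predict

__all__ = [
    "error_metrics",
    "bland_altman",
    "signed_error_by_quartile",
    "per_patient_bins",
    "ebben_classify",
    "ebben_counts",
    "attribute_large_errors",
    "evaluate",
    "save_report",
    "load_report",
]

EBBEN_CATEGORIES = ("constantly_low", "constantly_in", "constantly_high",
                    "LAL", "LAH", "HA")
PER_PATIENT_BIN_EDGES = (0.0, 0.5, 1.0, 1.5)
HISTOGRAM_BIN_WIDTH = 0.25


def error_metrics(observed, predicted) -> dict:
    """Error summary block: MAE, quartiles, range, fraction within +/-1.5 g/dL.

    Quartiles use linear interpolation; the +/-1.5 band is strict
    (|error| < 1.5).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size == 0:
        raise ValueError("error_metrics needs at least one pair")
    err = obs - pred
    abs_err = np.abs(err)
    q1, q2, q3 = np.percentile(err, [25, 50, 75])
    a1, a2, a3 = np.percentile(abs_err, [25, 50, 75])
    return {
        "n": int(obs.size),
        "mae": float(abs_err.mean()),
        "median_error": float(q2),
        "error_quartiles": [float(q1), float(q2), float(q3)],
        "abs_error_quartiles": [float(a1), float(a2), float(a3)],
        "error_range": [float(err.min()), float(err.max())],
        "frac_within_1p5": float(np.mean(abs_err < 1.5)),
    }


def bland_altman(observed, predicted) -> dict:
    """OLS of the pairwise difference on the pairwise mean.

    diff = observed - predicted is regressed on mean = (observed +
    predicted)/2; the slope p-value is the two-sided t-test.  A positive
    slope is the shrinkage (regression-to-the-mean) signature.  Identical
    pair means (zero variance) leave the slope undefined and raise.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 3:
        raise ValueError("bland_altman needs at least 3 pairs")
    mean = (obs + pred) / 2.0
    diff = obs - pred
    if np.ptp(mean) == 0:
        raise ValueError("undefined slope: pair means have zero variance")
    fit = stats.linregress(mean, diff)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "slope_p": float(fit.pvalue),
        "mean": mean,
        "diff": diff,
    }


def signed_error_by_quartile(observed, predicted,
                             convention: str = "obs_minus_pred") -> np.ndarray:
    """Mean signed error within the four quartile groups of observed Hb(t+3).

    Records are ranked by observed value (stable order) and cut into four
    equal-as-possible groups, so boundary ties fall in the lower quartile
    and degenerate inputs (all values identical) still yield four equal
    means.  ``convention`` selects ``obs_minus_pred`` (default) or
    ``pred_minus_obs``.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = obs.size
    if n < 4:
        raise ValueError("need at least 4 records for quartile analysis")
    if convention == "obs_minus_pred":
        err = obs - pred
    elif convention == "pred_minus_obs":
        err = pred - obs
    else:
        raise ValueError(f"unknown convention {convention!r}")
    order = np.argsort(obs, kind="stable")
    bounds = [n * i // 4 for i in range(5)]
    return np.array([err[order[bounds[i]:bounds[i + 1]]].mean() for i in range(4)])


def per_patient_bins(patient_ids, observed, predicted) -> dict:
    """Per-patient MAE binned into [0,0.5), [0.5,1), [1,1.5), [1.5,inf) g/dL."""
    df = pd.DataFrame({
        "patient_id": np.asarray(patient_ids),
        "abs_err": np.abs(np.asarray(observed, dtype=float)
                          - np.asarray(predicted, dtype=float)),
    })
    per_patient = df.groupby("patient_id", sort=True)["abs_err"].mean()
    edges = [*PER_PATIENT_BIN_EDGES, np.inf]
    counts = [int(((per_patient >= lo) & (per_patient < hi)).sum())
              for lo, hi in zip(edges[:-1], edges[1:])]
    return {
        "bin_edges": list(PER_PATIENT_BIN_EDGES),
        "counts": counts,
        "n_patients": int(len(per_patient)),
        "per_patient_mae": {str(k): float(v) for k, v in per_patient.items()},
    }


def ebben_classify(hb_sequence, band_low: float = 10.0, band_high: float = 13.0) -> str:
    """Hb-cycling category of one 6-month monthly Hb sequence.

    The band is closed: a value equal to a bound is in-band.  The six
    categories partition all positive sequences: which of {below, in, above}
    the values visit determines the class (both extremes visited, with or
    without in-band values, is high-amplitude HA).
    """
    seq = np.asarray(hb_sequence, dtype=float)
    if seq.shape != (6,):
        raise ValueError(f"Ebben classification needs exactly 6 values, got {seq.shape}")
    if not np.all(seq > 0):
        raise ValueError("Hb values must be positive")
    below = bool(np.any(seq < band_low))
    above = bool(np.any(seq > band_high))
    inside = bool(np.any((seq >= band_low) & (seq <= band_high)))
    if below and above:
        return "HA"
    if below:
        return "LAL" if inside else "constantly_low"
    if above:
        return "LAH" if inside else "constantly_high"
    return "constantly_in"


def ebben_counts(hb_monthly: pd.DataFrame, band_low: float = 10.0,
                 band_high: float = 13.0) -> dict:
    """Category counts over all 6-month sliding windows of consecutive months.

    ``hb_monthly`` needs ``patient_id``, ``date``, ``value`` columns (one Hb
    per patient-month); a missing month breaks the window chain.
    """
    counts = {cat: 0 for cat in EBBEN_CATEGORIES}
    n_sequences = 0
    for _, sub in hb_monthly.groupby("patient_id"):
        sub = sub.sort_values("date")
        dates = pd.to_datetime(sub["date"])
        month_no = (dates.dt.year * 12 + dates.dt.month).to_numpy()
        values = sub["value"].to_numpy(dtype=float)
        # split into runs of consecutive months
        run_start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or month_no[i] != month_no[i - 1] + 1:
                run = values[run_start:i]
                for j in range(len(run) - 5):
                    counts[ebben_classify(run[j:j + 6], band_low, band_high)] += 1
                    n_sequences += 1
                run_start = i
    counts["n_sequences"] = n_sequences
    return counts


def attribute_large_errors(records: pd.DataFrame, predictions: pd.DataFrame,
                           events: pd.DataFrame, threshold: float = 1.5):
    """Attribute large prediction errors to adverse events in their window.

    A record is flagged when |observed - predicted| Hb(t+3) is strictly
    above ``threshold``.  Every event type with an event dated in
    ``(anchor_date, target_date]`` is credited (a record may count toward
    several types); flagged records with no event count as ``unexplained``.
    Returns ``(counts, flags)`` where flags has one row per evaluated record.
    """
    merged = records.merge(predictions[["record_id", "delta_hb_pred"]], on="record_id")
    merged = merged[merged["valid"].astype(bool)]
    err = merged["delta_hb"].to_numpy(dtype=float) - merged["delta_hb_pred"].to_numpy(dtype=float)

    ev_by_patient: dict = {}
    if events is not None and len(events):
        for pid, sub in events.groupby("patient_id"):
            ev_by_patient[pid] = (pd.to_datetime(sub["date"]).to_numpy(),
                                  sub["etype"].to_numpy())

    etypes = sorted(set(events["etype"])) if events is not None and len(events) else []
    counts = {etype: 0 for etype in etypes}
    counts["unexplained"] = 0
    flag_rows = []
    for i, row in enumerate(merged.itertuples(index=False)):
        flagged = bool(abs(err[i]) > threshold)
        hit_types: list[str] = []
        if flagged:
            dates, kinds = ev_by_patient.get(row.patient_id, (None, None))
            if dates is not None:
                t0 = np.datetime64(pd.Timestamp(row.anchor_date))
                t1 = np.datetime64(pd.Timestamp(row.target_date))
                in_window = (dates > t0) & (dates <= t1)
                hit_types = sorted(set(kinds[in_window]))
            for etype in hit_types:
                counts[etype] = counts.get(etype, 0) + 1
            if not hit_types:
                counts["unexplained"] += 1
        flag_rows.append({"record_id": row.record_id, "error": float(err[i]),
                          "flagged": flagged, "event_types": hit_types})
    return counts, pd.DataFrame(flag_rows)


def _histogram(err: np.ndarray) -> dict:
    lo = np.floor(err.min() / HISTOGRAM_BIN_WIDTH) * HISTOGRAM_BIN_WIDTH
    hi = np.ceil(err.max() / HISTOGRAM_BIN_WIDTH) * HISTOGRAM_BIN_WIDTH
    if hi <= lo:
        hi = lo + HISTOGRAM_BIN_WIDTH
    edges = np.round(np.arange(lo, hi + HISTOGRAM_BIN_WIDTH / 2, HISTOGRAM_BIN_WIDTH), 10)
    counts, _ = np.histogram(err, bins=edges)
    return {"bin_edges": edges.tolist(), "counts": counts.tolist()}


def _split_block(sub: pd.DataFrame, events: pd.DataFrame,
                 predictions: pd.DataFrame) -> dict:
    merged = sub.merge(predictions[["record_id", "hb_pred"]], on="record_id")
    obs = merged["hb_t"].to_numpy(dtype=float) + merged["delta_hb"].to_numpy(dtype=float)
    pred = merged["hb_pred"].to_numpy(dtype=float)
    ba = bland_altman(obs, pred)
    counts, _ = attribute_large_errors(sub, predictions, events)
    return {
        "metrics": error_metrics(obs, pred),
        "bland_altman": {k: ba[k] for k in ("slope", "intercept", "slope_p")},
        "signed_error_by_quartile": signed_error_by_quartile(obs, pred).tolist(),
        "per_patient_bins": per_patient_bins(merged["patient_id"], obs, pred),
        "attribution": counts,
        "error_histogram": _histogram(obs - pred),
    }


def evaluate(model: TrainedModel, records: pd.DataFrame,
             events: pd.DataFrame | None = None, split=None) -> dict:
    """Full evaluation report (train and test blocks) for a trained model.

    Each block carries the error summary, Bland-Altman fit, quartile-wise
    signed errors, per-patient MAE bins, adverse-event attribution of large
    errors and 0.25 g/dL error-histogram data; the cohort-level Ebben
    cycling census of the anchor Hb series is reported once.  Deterministic:
    no randomness enters after training.
    """
    if split is None:
        train_ids, test_ids = model.train_ids, model.test_ids
    else:
        train_ids, test_ids = split
    valid = records[records["valid"].astype(bool)].set_index("record_id", drop=False)
    events = events if events is not None else pd.DataFrame(
        columns=["patient_id", "date", "etype", "hb_effect"])

    report: dict = {"schema": "hbforecast-report-v1"}
    hb_series = records.rename(columns={"anchor_date": "date", "hb_t": "value"})
    report["ebben"] = ebben_counts(hb_series[["patient_id", "date", "value"]])

    for name, ids in (("train", train_ids), ("test", test_ids)):
        sub = valid.loc[[i for i in ids if i in valid.index]].reset_index(drop=True)
        preds = predict(model, sub)
        report[name] = _split_block(sub, events, preds)
    report["n_records"] = int(len(valid))
    return report


def save_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def load_report(path) -> dict:
    return json.loads(Path(path).read_text())
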