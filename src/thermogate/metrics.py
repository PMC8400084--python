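"""Evaluation metrics for respiratory-rate traces and breath peaks.

Rate-trace agreement (after nearest-timestamp alignment):

* **MAE** — mean absolute rate difference in breaths/min;
* **Pearson** — product-moment correlation of the aligned traces;
* **coverage** — fraction of estimates within +/-3 bpm of the reference
  (inclusive bound: an error of exactly 3 bpm counts as covered).

Breath-peak agreement: each reference peak owns an acceptance interval
running from the midpoint with its predecessor to the midpoint with its
successor (the signal's start/end stand in for missing neighbors).  A
reference peak is validly matched iff *exactly one* predicted peak falls in
its interval; precision = valid / predicted peaks, recall = valid /
reference peaks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .rates import PeakList, RateTrace

__all__ = [
    "MetricsReport",
    "align_traces",
    "mae",
    "pearson",
    "coverage",
    "match_peaks",
    "precision_recall",
    "evaluate_rate_traces",
    "evaluate_peaks",
]

#: Coverage tolerance in breaths per minute.
DEFAULT_TOL_BPM = 3.0


@dataclass
class MetricsReport:
    """The five benchmark statistics plus their underlying counts."""

    mae: float
    pearson: float
    coverage: float
    precision: float
    recall: float
    n_rates: int
    n_within: int
    np_pre: int
    np_ref: int
    np_valid: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def align_traces(
    pred: RateTrace,
    ref: RateTrace,
    max_offset_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-timestamp join of two rate traces.

    For every predicted sample the nearest reference timestamp is found;
    pairs farther apart than ``max_offset_s`` (default: half the prediction
    step, or 0.5 s) and pairs with a NaN rate are dropped.
    """
    if max_offset_s is None:
        max_offset_s = 0.5 * pred.step_s if pred.step_s else 0.5
    if len(pred) == 0 or len(ref) == 0:
        return np.empty(0), np.empty(0)
    pos = np.searchsorted(ref.times, pred.times)
    left = np.clip(pos - 1, 0, len(ref) - 1)
    right = np.clip(pos, 0, len(ref) - 1)
    nearest = np.where(
        np.abs(ref.times[left] - pred.times) <= np.abs(ref.times[right] - pred.times),
        left,
        right,
    )
    keep = np.abs(ref.times[nearest] - pred.times) <= max_offset_s
    p, r = pred.rates[keep], ref.rates[nearest[keep]]
    ok = np.isfinite(p) & np.isfinite(r)
    return p[ok], r[ok]


def mae(pred: np.ndarray, ref: np.ndarray) -> float:
    """Mean absolute error of aligned rate samples, in breaths/min."""
    pred, ref = np.asarray(pred, float), np.asarray(ref, float)
    if pred.size == 0:
        raise ValueError("empty overlap between traces")
    return float(np.mean(np.abs(pred - ref)))


def pearson(pred: np.ndarray, ref: np.ndarray) -> float:
    """Product-moment correlation of aligned rate samples."""
    pred, ref = np.asarray(pred, float), np.asarray(ref, float)
    if pred.size < 2:
        raise ValueError("need at least 2 samples for a correlation")
    if pred.std() == 0 or ref.std() == 0:
        raise ValueError("zero-variance trace: correlation undefined")
    dp, dr = pred - pred.mean(), ref - ref.mean()
    return float(np.sum(dp * dr) / np.sqrt(np.sum(dp**2) * np.sum(dr**2)))


def coverage(pred: np.ndarray, ref: np.ndarray, tol: float = DEFAULT_TOL_BPM) -> float:
    """Fraction of samples with |pred - ref| <= tol (inclusive bound)."""
    pred, ref = np.asarray(pred, float), np.asarray(ref, float)
    if pred.size == 0:
        raise ValueError("empty overlap between traces")
    return float(np.mean(np.abs(pred - ref) <= tol))


def match_peaks(pred: PeakList, ref: PeakList) -> tuple[int, int, int]:
    """Count validly matched reference peaks.

    Returns ``(np_valid, np_pre, np_ref)``.  Acceptance intervals are
    half-open ``[lo, hi)`` so a predicted peak sitting exactly on a midpoint
    belongs to exactly one interval.  For the first/last reference peak the
    interval is bounded by the signal start/end when known, otherwise it is
    unbounded on that side.
    """
    p = pred.peak_times
    r = ref.peak_times
    np_pre, np_ref = p.size, r.size
    if np_ref == 0 or np_pre == 0:
        return 0, np_pre, np_ref
    t_start = ref.t_start if ref.t_start is not None else -np.inf
    t_end = ref.t_end if ref.t_end is not None else np.inf
    np_valid = 0
    for i in range(np_ref):
        lo = t_start if i == 0 else 0.5 * (r[i - 1] + r[i])
        hi = t_end if i == np_ref - 1 else 0.5 * (r[i] + r[i + 1])
        count = int(np.count_nonzero((p >= lo) & (p < hi)))
        if count == 1:  # "only one" rule: 0 or >1 predicted peaks both fail
            np_valid += 1
    return np_valid, np_pre, np_ref


def precision_recall(np_valid: int, np_pre: int, np_ref: int) -> tuple[float, float]:
    """Precision = valid/predicted, recall = valid/reference (NaN if empty)."""
    prec = np_valid / np_pre if np_pre >= 1 else float("nan")
    rec = np_valid / np_ref if np_ref >= 1 else float("nan")
    return prec, rec


def evaluate_rate_traces(
    pred: RateTrace,
    ref: RateTrace,
    tol: float = DEFAULT_TOL_BPM,
    max_offset_s: float | None = None,
) -> dict:
    """MAE / Pearson / coverage of two rate traces after alignment."""
    p, r = align_traces(pred, ref, max_offset_s)
    n = int(p.size)
    n_within = int(np.count_nonzero(np.abs(p - r) <= tol)) if n else 0
    out = {"n_rates": n, "n_within": n_within}
    out["mae"] = mae(p, r) if n else float("nan")
    out["coverage"] = coverage(p, r, tol) if n else float("nan")
    try:
        out["pearson"] = pearson(p, r)
    except ValueError:
        out["pearson"] = float("nan")
    return out


def evaluate_peaks(pred: PeakList, ref: PeakList) -> dict:
    """Precision / recall of predicted breath peaks against reference peaks."""
    np_valid, np_pre, np_ref = match_peaks(pred, ref)
    prec, rec = precision_recall(np_valid, np_pre, np_ref)
    return {
        "np_valid": np_valid,
        "np_pre": np_pre,
        "np_ref": np_ref,
        "precision": prec,
        "recall": rec,
    }


def evaluate(
    pred_rate: RateTrace,
    ref_rate: RateTrace,
    pred_peaks: PeakList,
    ref_peaks: PeakList,
    tol: float = DEFAULT_TOL_BPM,
    max_offset_s: float | None = None,
) -> MetricsReport:
    """Full benchmark report: rate-trace and peak statistics combined."""
    r = evaluate_rate_traces(pred_rate, ref_rate, tol, max_offset_s)
    pk = evaluate_peaks(pred_peaks, ref_peaks)
    return MetricsReport(
        mae=r["mae"],
        pearson=r["pearson"],
        coverage=r["coverage"],
        precision=pk["precision"],
        recall=pk["recall"],
        n_rates=r["n_rates"],
        n_within=r["n_within"],
        np_pre=pk["np_pre"],
        np_ref=pk["np_ref"],
        np_valid=pk["np_valid"],
    )
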