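"""Sliding-window orchestration shared by all extraction methods.

Every method processes the video in short analysis windows (5-30 s): the
segmentation (for Seg methods) and the alpha gain (for FVP-Alpha) are local
to each window, each window's trace is band-pass filtered to the respiratory
band (0.167-0.833 Hz), and the filtered pieces are overlap-added into one
full-length respiratory signal.

Overlap-add uses a strictly positive sine-squared taper with weight
normalization, so wherever the contributing segments agree the
reconstruction is exact — including single-coverage regions and disjoint
spans.  The band-pass is a zero-phase (forward-backward) 4th-order
Butterworth, which preserves breath-peak timing for the inter-breath-interval
evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import METHOD_LABELS, RespiratorySignal, ThermalVideo
from .fvp import DegenerateSignalError, fvp_alpha, fvp_avg, fvp_var
from .segmentation import (
    DegenerateSegmentationError,
    dc_features,
    kmeans_foreground,
    pixel_snr,
    seg_ac,
    seg_avg,
    seg_snr,
)

__all__ = ["WindowPlan", "plan_windows", "bandpass", "overlap_add", "extract_signal"]

log = logging.getLogger(__name__)

#: Respiratory band in Hz (10-50 breaths/min).
DEFAULT_BAND_HZ = (0.167, 0.833)


@dataclass
class WindowPlan:
    """Extraction-window configuration.

    ``length_s`` is the analysis-window length (the processing latency a
    subject experiences at the gate; benchmarked at 5/10/20/30 s), ``step_s``
    the hop between consecutive windows (default 1 s, giving 80-97% overlap),
    and ``band`` the respiratory pass band in Hz.
    """

    length_s: float = 10.0
    step_s: float = 1.0
    band: tuple[float, float] = DEFAULT_BAND_HZ

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.length_s:
            raise ValueError(f"need 0 < step_s <= length_s, got {self.step_s}, {self.length_s}")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError(f"invalid band {self.band}")


def plan_windows(t: int, fps: float, plan: WindowPlan) -> list[tuple[int, int]]:
    """Half-open frame spans of the sliding extraction window.

    A trailing partial span shorter than the window length is dropped.
    """
    length = int(round(plan.length_s * fps))
    step = max(1, int(round(plan.step_s * fps)))
    if t < length:
        raise ValueError(f"video of {t} frames shorter than one {length}-frame window")
    return [(s, s + length) for s in range(0, t - length + 1, step)]


def bandpass(
    signal: RespiratorySignal,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    order: int = 4,
) -> RespiratorySignal:
    """Zero-phase Butterworth band-pass restricted to the respiratory band.

    Applied forward and backward (``sosfiltfilt``), so the effective
    attenuation is the squared magnitude response and the group delay is
    zero.  DC is rejected entirely.
    """
    nyquist = signal.fps / 2.0
    if not band[1] < nyquist:
        raise ValueError(f"band {band} infeasible at fps {signal.fps}")
    sos = butter(order, band, btype="bandpass", fs=signal.fps, output="sos")
    n = signal.values.size
    # pad with at least one period of the low cutoff: edge transients of the
    # odd-extension padding otherwise bias the spectral peak near the band edge
    padlen = min(n - 1, max(3 * (2 * sos.shape[0] + 1), int(round(signal.fps / band[0]))))
    filtered = sosfiltfilt(sos, signal.values, padlen=padlen)
    return signal.with_values(filtered)


def _coa_taper(m: int) -> np.ndarray:
    # sin^2(pi (k + 1/2) / m): strictly positive, constant-overlap-add at hop m/2
    k = np.arange(m)
    return np.sin(np.pi * (k + 0.5) / m) ** 2


def overlap_add(
    segments: list[np.ndarray | RespiratorySignal],
    spans: list[tuple[int, int]],
    t: int,
    eps: float = 1e-12,
) -> np.ndarray:
    """Assemble per-window traces into one length-``t`` signal.

    Each segment is mean-centered, multiplied by a strictly positive
    sine-squared taper, and accumulated; the accumulator is divided by the
    accumulated taper weights (floored at ``eps``).  Deterministic; exact
    wherever overlapping segments agree.
    """
    if len(segments) != len(spans):
        raise ValueError("segments and spans differ in length")
    acc = np.zeros(t)
    weights = np.zeros(t)
    for seg, (start, end) in zip(segments, spans):
        values = seg.values if isinstance(seg, RespiratorySignal) else np.asarray(seg, float)
        if values.size != end - start:
            raise ValueError(f"segment of {values.size} samples does not fit span ({start}, {end})")
        taper = _coa_taper(values.size)
        acc[start:end] += (values - values.mean()) * taper
        weights[start:end] += taper
    return acc / np.maximum(weights, eps)


def _extract_window(
    video: ThermalVideo,
    extended: ThermalVideo,
    method: str,
    snr_percentile: float,
) -> RespiratorySignal:
    """Run one extraction method on a single analysis window.

    ``video`` is the nominal analysis window: the foreground mask, the
    per-pixel quality maps and any window-local statistics are computed on
    it.  ``extended`` is the same window plus a margin of real frames on
    each side; the returned trace covers the extended span so the band-pass
    filter can be cropped back to the nominal span free of edge transients.
    """
    if method == "FVP-AVG":
        return fvp_avg(extended)
    if method == "FVP-VAR":
        return fvp_var(extended)
    if method == "FVP-Alpha":
        try:
            return fvp_alpha(fvp_avg(extended), fvp_var(extended))
        except DegenerateSignalError:
            log.warning("FVP-Alpha degenerate (flat VAR); falling back to FVP-AVG")
            return fvp_avg(extended)
    # Seg family: segment the nominal window on its DC features
    try:
        mask = kmeans_foreground(dc_features(video))
    except DegenerateSegmentationError:
        log.warning("%s: degenerate DC map; falling back to FVP-AVG", method)
        return fvp_avg(extended)
    if method == "Seg-AVG":
        return seg_avg(extended, mask)
    quality = pixel_snr(video, mask)
    if method == "Seg-SNR":
        return seg_snr(extended, mask, quality, percentile=snr_percentile)
    if method == "Seg-AC":
        return seg_ac(extended, mask, quality)
    raise ValueError(f"unknown method {method!r}; expected one of {METHOD_LABELS}")


def extract_signal(
    video: ThermalVideo,
    method: str,
    plan: WindowPlan | None = None,
    snr_percentile: float = 75.0,
) -> RespiratorySignal:
    """Full pipeline: windowed extraction, band-pass, overlap-add.

    For Seg methods the foreground mask (and, where applicable, the
    per-pixel quality maps) are recomputed for every analysis window, so the
    segmentation tracks the subject over time.  The returned signal has the
    same length and frame rate as the video and zero mean.
    """
    if method not in METHOD_LABELS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHOD_LABELS}")
    if plan is None:
        plan = WindowPlan()
    spans = plan_windows(video.n_frames, video.fps, plan)
    # filter over a margin of real frames (one low-cutoff period each side)
    # and crop back: avoids band-edge transients from synthetic padding
    margin = int(round(video.fps / plan.band[0]))
    segments = []
    for start, end in spans:
        lo = max(0, start - margin)
        hi = min(video.n_frames, end + margin)
        window = video.slice(start, end)
        raw = _extract_window(window, video.slice(lo, hi), method, snr_percentile)
        filtered = bandpass(raw, plan.band).values
        segments.append(filtered[start - lo : start - lo + (end - start)])
    values = overlap_add(segments, spans, video.n_frames)
    return RespiratorySignal(
        values, video.fps, method=method, window_length_s=plan.length_s, t0=video.t0
    )
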