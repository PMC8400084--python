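"""Segmentation-based (Seg) extractors.

At 8x8 pixels no facial landmarks exist, but the subject is reliably warmer
than the background.  Pixels are therefore clustered into foreground and
background on their *DC temperature* — the per-pixel temporal mean over the
analysis window — with a deterministic two-cluster K-means (initial centroids
at the maximum and minimum DC value, squared-Euclidean distance, Lloyd
iterations until the assignment stops changing).  The warmer cluster is the
foreground.  Three signals are then derived from the foreground:

* ``seg_avg`` — spatial mean over all foreground pixels;
* ``seg_snr`` — mean over the foreground pixels whose in-band/out-of-band
  spectral energy ratio is highest (respiratory-quality selection);
* ``seg_ac``  — the single foreground pixel with the largest temporal
  standard deviation in the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .core import RespiratorySignal, ThermalVideo
from .fvp import fvp_avg

__all__ = [
    "ForegroundMask",
    "PixelQuality",
    "DegenerateSegmentationError",
    "dc_features",
    "kmeans_foreground",
    "seg_avg",
    "pixel_snr",
    "seg_snr",
    "seg_ac",
]

#: Respiratory band used for the per-pixel SNR quality metric, in breaths/min.
DEFAULT_INBAND_BPM = (10.0, 50.0)


class DegenerateSegmentationError(ValueError):
    """All DC features identical: two-cluster segmentation is undefined."""


@dataclass
class ForegroundMask:
    """Foreground/background split of one analysis window.

    ``centroids`` holds (foreground mean, background mean) in degrees Celsius;
    the foreground is by construction the warmer cluster.
    """

    mask: np.ndarray
    centroids: tuple[float, float]
    window_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("foreground mask has no pixels")
        if self.centroids[0] < self.centroids[1]:
            raise ValueError("foreground centroid must be the warmer one")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass
class PixelQuality:
    """Per-pixel quality maps over one analysis window.

    ``snr`` is the linear ratio of in-band to out-of-band spectral energy
    (dimensionless, >= 0); ``ac`` is the temporal standard deviation in
    degrees Celsius.
    """

    snr: np.ndarray
    ac: np.ndarray


def dc_features(video: ThermalVideo, window_span: tuple[int, int] | None = None) -> np.ndarray:
    """Per-pixel temporal mean temperature over a half-open frame span."""
    if window_span is None:
        window_span = (0, video.n_frames)
    start, end = window_span
    if not (0 <= start < end <= video.n_frames):
        raise ValueError(f"empty or invalid span {window_span} for T={video.n_frames}")
    return video.frames[start:end].mean(axis=0)


def kmeans_foreground(dc: np.ndarray, max_iter: int | None = None) -> ForegroundMask:
    """Deterministic two-cluster K-means on scalar DC-temperature features.

    Initial centroids are the maximum and minimum DC value; assignment uses
    squared Euclidean distance; Lloyd updates run until the assignment is
    unchanged (at most ``H*W`` iterations, which always suffices in 1-D).
    """
    dc = np.asarray(dc, dtype=float)
    vals = dc.ravel()
    if vals.size < 2 or np.ptp(vals) == 0:
        raise DegenerateSegmentationError("all DC features identical")
    centroids = np.array([vals.max(), vals.min()])
    if max_iter is None:
        max_iter = vals.size + 1
    labels = None
    for _ in range(max_iter):
        dist = (vals[:, None] - centroids[None, :]) ** 2
        new_labels = np.argmin(dist, axis=1)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in (0, 1):
            members = vals[labels == j]
            if members.size:  # empty cluster keeps its previous centroid
                centroids[j] = members.mean()
    fg_cluster = int(np.argmax(centroids))
    mask = (labels == fg_cluster).reshape(dc.shape)
    fg_mean = float(centroids[fg_cluster])
    bg_mean = float(centroids[1 - fg_cluster])
    return ForegroundMask(mask, (fg_mean, bg_mean))


def seg_avg(video: ThermalVideo, mask: ForegroundMask) -> RespiratorySignal:
    """Spatial mean over foreground pixels, per frame.

    With an all-true mask this reduces exactly to :func:`~thermogate.fvp.fvp_avg`.
    """
    if mask.mask.shape != video.shape:
        raise ValueError(f"mask shape {mask.mask.shape} != frame shape {video.shape}")
    values = video.frames[:, mask.mask].mean(axis=1)
    return RespiratorySignal(values, video.fps, method="Seg-AVG", t0=video.t0)


def pixel_snr(
    video: ThermalVideo,
    mask: ForegroundMask | None = None,
    inband_bpm: tuple[float, float] = DEFAULT_INBAND_BPM,
    eps: float = 1e-15,
) -> PixelQuality:
    """Per-pixel respiratory SNR and temporal standard deviation.

    Each pixel trace is mean-removed, Hann-tapered (leakage control in the
    short 5-30 s windows) and transformed; the SNR is the ratio of spectral
    power inside ``inband_bpm`` to power outside it.  The DC bin is excluded
    from both bands and the out-of-band power is floored at ``eps``.  Being
    a ratio, the SNR is invariant to offsets and to rescaling of the trace.

    Pixels outside the foreground mask (if given) are reported as NaN in the
    ``snr`` map; the ``ac`` map is computed everywhere.
    """
    t, h, w = video.frames.shape
    traces = video.frames.reshape(t, h * w)
    ac = traces.std(axis=0).reshape(h, w)

    x = traces - traces.mean(axis=0, keepdims=True)
    taper = get_window("hann", t)[:, None]
    spec = np.abs(np.fft.rfft(x * taper, axis=0)) ** 2
    freqs = np.fft.rfftfreq(t, d=1.0 / video.fps)
    f_lo, f_hi = inband_bpm[0] / 60.0, inband_bpm[1] / 60.0
    inband = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    outband = (freqs > 0) & ~inband
    p_in = spec[inband].sum(axis=0)
    p_out = spec[outband].sum(axis=0)
    snr = (p_in / np.maximum(p_out, eps)).reshape(h, w)
    if mask is not None:
        snr = np.where(mask.mask, snr, np.nan)
    return PixelQuality(snr=snr, ac=ac)


def seg_snr(
    video: ThermalVideo,
    mask: ForegroundMask,
    quality: PixelQuality,
    percentile: float = 75.0,
) -> RespiratorySignal:
    """Mean over the foreground pixels with the strongest respiratory SNR.

    Selection keeps foreground pixels at or above the given percentile of
    the foreground SNR distribution (default 75th), never fewer than one.
    ``percentile=0`` reduces to :func:`seg_avg`.
    """
    fg_snr = quality.snr[mask.mask]
    if np.isnan(fg_snr).any():
        raise ValueError("quality map has NaN SNR inside the foreground")
    threshold = np.percentile(fg_snr, percentile)
    selected = mask.mask & (np.nan_to_num(quality.snr, nan=-np.inf) >= threshold)
    if not selected.any():  # guard: keep at least the best pixel
        best = np.nanargmax(np.where(mask.mask, quality.snr, np.nan))
        selected = np.zeros_like(mask.mask)
        selected.ravel()[best] = True
    values = video.frames[:, selected].mean(axis=1)
    return RespiratorySignal(values, video.fps, method="Seg-SNR", t0=video.t0)


def seg_ac(
    video: ThermalVideo,
    mask: ForegroundMask,
    quality: PixelQuality,
) -> RespiratorySignal:
    """Trace of the foreground pixel with maximal temporal standard deviation.

    Ties break deterministically to the first pixel in row-major order.
    """
    scores = np.where(mask.mask, quality.ac, -np.inf)
    idx = int(np.argmax(scores))  # first max in row-major order
    r, c = divmod(idx, video.shape[1])
    values = video.frames[:, r, c]
    return RespiratorySignal(values, video.fps, method="Seg-AC", t0=video.t0)


def full_frame_mask(video: ThermalVideo) -> ForegroundMask:
    """All-pixels mask (fallback when segmentation is degenerate)."""
    mean = float(video.frames.mean())
    return ForegroundMask(np.ones(video.shape, dtype=bool), (mean, mean))
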