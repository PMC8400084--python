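"""Respiratory-rate calculators.

Two complementary estimators operate on an extracted respiratory signal:

* **averaged rate** — frequency-domain: a 10 s window slides in 0.1 s steps;
  in each window the mean-removed, Hann-tapered signal is zero-padded to at
  least 4096 points and the magnitude-spectrum argmax inside the [10, 50]
  breaths/min band is taken.  The zero-padding yields a ~0.15 bpm frequency
  grid at 10 fps — the native 10 s window alone would only resolve 6 bpm.
* **instantaneous rate** — time-domain: inhale/exhale peaks are detected and
  each inter-breath interval is inverted (60 / interval), timestamping the
  rate at the interval midpoint.  More responsive to breath-to-breath
  changes, but more sensitive to jitter in short windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, get_window

from .core import RespiratorySignal

__all__ = [
    "RateTrace",
    "PeakList",
    "averaged_rate",
    "detect_peaks",
    "instantaneous_rate",
]

#: Respiratory search band in breaths per minute.
DEFAULT_BAND_BPM = (10.0, 50.0)


@dataclass
class RateTrace:
    """Time-stamped respiratory-rate series in breaths per minute.

    ``rates`` may contain NaN where a window had no usable signal; such
    samples are excluded pairwise from metric computation.
    """

    times: np.ndarray
    rates: np.ndarray
    kind: str = "averaged"
    step_s: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.rates = np.asarray(self.rates, dtype=float).ravel()
        if self.times.size != self.rates.size:
            raise ValueError("times and rates differ in length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class PeakList:
    """Detected breath-peak timestamps in seconds, strictly increasing.

    ``t_start`` / ``t_end`` record the span of the signal the peaks came
    from; they bound the first and last acceptance intervals during peak
    matching.
    """

    peak_times: np.ndarray
    t_start: float | None = None
    t_end: float | None = None

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float).ravel()
        if self.peak_times.size > 1 and not np.all(np.diff(self.peak_times) > 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return self.peak_times.size


def averaged_rate(
    signal: RespiratorySignal,
    window_s: float = 10.0,
    step_s: float = 0.1,
    band_bpm: tuple[float, float] = DEFAULT_BAND_BPM,
    nfft_min: int = 4096,
) -> RateTrace:
    """Sliding-window FFT-argmax respiratory rate.

    Each window is mean-removed, Hann-tapered and zero-padded to at least
    ``nfft_min`` points; the reported rate is the frequency of the largest
    magnitude-spectrum bin inside ``band_bpm``, converted to breaths/min,
    timestamped at the window center.  All-zero windows yield NaN.

    The estimate is invariant to scaling and sign of the signal (argmax of a
    magnitude spectrum) and is hard-limited to the search band.
    """
    n = int(round(window_s * signal.fps))
    if signal.values.size < n:
        raise ValueError(f"signal of {signal.values.size} samples shorter than one "
                         f"{n}-sample rate window")
    step = max(1, int(round(step_s * signal.fps)))
    starts = np.arange(0, signal.values.size - n + 1, step)

    windows = np.stack([signal.values[s:s + n] for s in starts])
    windows = windows - windows.mean(axis=1, keepdims=True)
    taper = get_window("hann", n)
    nfft = max(nfft_min, n)
    spec = np.abs(np.fft.rfft(windows * taper, n=nfft, axis=1))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / signal.fps)
    band = (freqs >= band_bpm[0] / 60.0) & (freqs <= band_bpm[1] / 60.0)
    band_freqs = freqs[band]
    band_spec = spec[:, band]

    rates = 60.0 * band_freqs[np.argmax(band_spec, axis=1)]
    silent = band_spec.max(axis=1) <= 0
    rates[silent] = np.nan
    times = signal.t0 + (starts + (n - 1) / 2.0) / signal.fps
    return RateTrace(times, rates, kind="averaged", step_s=step / signal.fps)


def detect_peaks(
    signal: RespiratorySignal,
    prominence_factor: float = 0.3,
    min_separation_s: float = 60.0 / DEFAULT_BAND_BPM[1],
) -> PeakList:
    """Detect breath peaks in a band-passed respiratory signal.

    Local maxima with prominence of at least ``prominence_factor`` times the
    signal standard deviation, separated by at least ``min_separation_s``
    (1.2 s by default — the period of the 50 bpm band ceiling).  A flat
    signal yields an empty list.
    """
    t_start = signal.t0
    t_end = signal.t0 + (signal.values.size - 1) / signal.fps
    sd = signal.values.std()
    if sd == 0:
        return PeakList(np.empty(0), t_start, t_end)
    distance = max(1, int(round(min_separation_s * signal.fps)))
    idx, _ = find_peaks(signal.values, prominence=prominence_factor * sd, distance=distance)
    return PeakList(signal.t0 + idx / signal.fps, t_start, t_end)


def instantaneous_rate(peaks: PeakList) -> RateTrace:
    """Inter-breath-interval rate: 60 / interval, at interval midpoints."""
    t = peaks.peak_times
    if t.size < 2:
        return RateTrace(np.empty(0), np.empty(0), kind="instantaneous")
    intervals = np.diff(t)
    rates = 60.0 / intervals
    times = t[:-1] + intervals / 2.0
    return RateTrace(times, rates, kind="instantaneous")
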