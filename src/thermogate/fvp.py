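"""Full-video-processing (FVP) extractors.

Each thermal frame is reduced to a single scalar, and the scalars are
concatenated over time into a respiratory trace:

* ``fvp_avg`` — spatial mean of the frame; tracks the warm respiratory area
  directly when it occupies a large part of the image (mask, short distance).
* ``fvp_var`` — signed cube root of the third central spatial moment.  Like a
  spatial contrast statistic, but odd-order so that inhale/exhale polarity is
  preserved (an even-order statistic folds both phases onto positive values).
* ``fvp_alpha`` — additive combination of the two, with a variance-ratio gain
  that equalizes their amplitudes; the respiratory components of AVG and VAR
  move in phase (exhaling warms the region and raises the contrast), so the
  sum boosts the shared breathing component.
"""

from __future__ import annotations

import numpy as np

from .core import RespiratorySignal, ThermalVideo

__all__ = ["fvp_avg", "fvp_var", "fvp_std", "fvp_alpha", "DegenerateSignalError"]


class DegenerateSignalError(ValueError):
    """A combination step received a flat input it cannot normalize."""


def fvp_avg(video: ThermalVideo) -> RespiratorySignal:
    """Spatial mean of each frame, concatenated over time."""
    values = video.frames.mean(axis=(1, 2))
    return RespiratorySignal(values, video.fps, method="FVP-AVG", t0=video.t0)


def fvp_var(video: ThermalVideo) -> RespiratorySignal:
    """Signed cube root of the third central spatial moment of each frame.

    For frame ``t`` with spatial mean ``mu_t``::

        m3(t) = mean( (I(x, y, t) - mu_t) ** 3 )
        VAR(t) = sign(m3) * |m3| ** (1/3)

    The odd moment is antisymmetric: reflecting every pixel about the frame
    mean flips the sign of the output exactly.
    """
    mu = video.frames.mean(axis=(1, 2), keepdims=True)
    m3 = ((video.frames - mu) ** 3).mean(axis=(1, 2))
    values = np.cbrt(m3)
    return RespiratorySignal(values, video.fps, method="FVP-VAR", t0=video.t0)


def fvp_std(video: ThermalVideo) -> RespiratorySignal:
    """Spatial standard deviation per frame (2nd-order contrast).

    Comparison utility only: the even order discards breathing polarity, so
    it is not one of the benchmarked methods.
    """
    values = video.frames.std(axis=(1, 2))
    return RespiratorySignal(values, video.fps, method="FVP-STD", t0=video.t0)


def fvp_alpha(
    avg_sig: RespiratorySignal,
    var_sig: RespiratorySignal,
    eps: float = 1e-12,
) -> RespiratorySignal:
    """Alpha-tuned combination ``AVG + (sigma(AVG)/sigma(VAR)) * VAR``.

    Both inputs are mean-centered over the combination window first, so the
    output is zero-mean.  The gain is computed per call, i.e. per extraction
    window, which tracks non-stationary amplitude.

    Raises
    ------
    DegenerateSignalError
        If the VAR input is flat (``sigma(VAR)`` numerically zero); callers
        may fall back to the AVG signal alone.
    """
    a = np.asarray(avg_sig.values, float)
    v = np.asarray(var_sig.values, float)
    if a.size != v.size:
        raise ValueError(f"length mismatch: {a.size} vs {v.size}")
    a = a - a.mean()
    v = v - v.mean()
    sd_v = v.std()
    if sd_v < eps:
        raise DegenerateSignalError("flat VAR signal: alpha gain undefined")
    gain = a.std() / sd_v
    return RespiratorySignal(
        a + gain * v, avg_sig.fps, method="FVP-Alpha", t0=avg_sig.t0
    )
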