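"""Data model and container I/O for low-resolution thermal video.

A thermopile array delivers a stream of tiny absolute-temperature images
(canonically 8x8 pixels at 10 fps).  :class:`ThermalVideo` is the in-memory
container used throughout the package; :class:`RespiratorySignal` holds the
one-dimensional temperature-derived trace produced by the extraction methods.

Conventions (fixed across the package):

* frames are stored row-major as a ``T x H x W`` float array, pixel ``(x, y)``
  meaning ``(row, column)`` with 0-based indices;
* temperatures are degrees Celsius;
* the timestamp of frame ``k`` is ``t0 + k / fps`` seconds.

Supported on-disk containers: HDF5 (dataset ``frames``, attributes ``fps``
and ``t0``), NPZ, and a human-inspectable CSV dialect with one frame per row
(``H*W`` columns, header comment carrying shape, frame rate and start time).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "ThermalVideo",
    "RespiratorySignal",
    "read_video",
    "write_video",
    "moving_mean_denoise",
    "read_signal_csv",
    "write_signal_csv",
]

#: Extraction-method labels accepted everywhere a ``method`` argument appears.
METHOD_LABELS = ("FVP-AVG", "FVP-VAR", "FVP-Alpha", "Seg-AVG", "Seg-SNR", "Seg-AC")


class FormatError(ValueError):
    """A video container is missing metadata or does not match its layout."""


@dataclass
class ThermalVideo:
    """A sequence of absolute-temperature frames with a fixed frame rate.

    Parameters
    ----------
    frames
        ``T x H x W`` array of temperatures in degrees Celsius.
    fps
        Frame rate in Hz, strictly positive.
    t0
        Timestamp of the first frame in seconds (default 0).
    """

    frames: np.ndarray
    fps: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        t, h, w = self.frames.shape
        if t < 1 or h < 1 or w < 1:
            raise ValueError(f"empty video: shape {self.frames.shape}")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite temperature values in frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        """Per-frame timestamps in seconds."""
        return self.t0 + np.arange(self.n_frames) / self.fps

    def slice(self, start: int, end: int) -> "ThermalVideo":
        """Sub-video over the half-open frame span ``[start, end)``."""
        if not (0 <= start < end <= self.n_frames):
            raise ValueError(f"invalid span ({start}, {end}) for T={self.n_frames}")
        return ThermalVideo(self.frames[start:end], self.fps, self.t0 + start / self.fps)


@dataclass
class RespiratorySignal:
    """One-dimensional respiratory trace derived from a thermal video."""

    values: np.ndarray
    fps: float
    method: str = "unknown"
    window_length_s: float | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError("empty signal")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in respiratory signal")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fps

    def with_values(self, values: np.ndarray) -> "RespiratorySignal":
        return replace(self, values=np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

_CSV_HEADER_RE = re.compile(
    r"#\s*thermogate-video\s+T=(\d+)\s+H=(\d+)\s+W=(\d+)\s+fps=([0-9.eE+-]+)\s+t0=([0-9.eE+-]+)"
)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix == ".npz":
        return "npz"
    if suffix == ".csv":
        return "csv"
    raise FormatError(f"cannot infer container format from {path.name!r}")


def read_video(path: str | Path, format: str | None = None) -> ThermalVideo:
    """Load a :class:`ThermalVideo` from an HDF5/NPZ/CSV container."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "frames" not in f:
                raise FormatError(f"{path}: missing 'frames' dataset")
            frames = np.asarray(f["frames"])
            try:
                fps = float(f["frames"].attrs["fps"])
            except KeyError as exc:
                raise FormatError(f"{path}: missing 'fps' attribute") from exc
            t0 = float(f["frames"].attrs.get("t0", 0.0))
    elif fmt == "npz":
        with np.load(path) as data:
            try:
                frames = data["frames"]
                fps = float(data["fps"])
            except KeyError as exc:
                raise FormatError(f"{path}: missing 'frames' or 'fps' entry") from exc
            t0 = float(data["t0"]) if "t0" in data else 0.0
    elif fmt == "csv":
        with open(path) as f:
            header = f.readline()
        m = _CSV_HEADER_RE.match(header)
        if m is None:
            raise FormatError(f"{path}: malformed CSV video header: {header.strip()!r}")
        t, h, w = (int(m.group(i)) for i in (1, 2, 3))
        fps, t0 = float(m.group(4)), float(m.group(5))
        flat = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
        if flat.shape != (t, h * w):
            raise FormatError(
                f"{path}: expected {t} rows of {h * w} columns, got {flat.shape}"
            )
        frames = flat.reshape(t, h, w)  # row-major per documented layout
    else:
        raise FormatError(f"unknown container format {fmt!r}")
    return ThermalVideo(frames, fps, t0)


def write_video(
    video: ThermalVideo,
    path: str | Path,
    format: str | None = None,
    csv_decimals: int = 3,
) -> Path:
    """Write a video container readable by :func:`read_video`.

    HDF5/NPZ preserve frames bit-identically; CSV rounds to ``csv_decimals``
    decimal places.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("frames", data=video.frames)
            ds.attrs["fps"] = video.fps
            ds.attrs["t0"] = video.t0
    elif fmt == "npz":
        np.savez(path, frames=video.frames, fps=video.fps, t0=video.t0)
    elif fmt == "csv":
        t, h, w = video.frames.shape
        header = f"# thermogate-video T={t} H={h} W={w} fps={video.fps!r} t0={video.t0!r}\n"
        with open(path, "w") as f:
            f.write(header)
            np.savetxt(f, video.frames.reshape(t, h * w), delimiter=",",
                       fmt=f"%.{csv_decimals}f")
    else:
        raise FormatError(f"unknown container format {fmt!r}")
    return path


def write_signal_csv(times: np.ndarray, values: np.ndarray, path: str | Path) -> Path:
    """Export a (time_s, value) series as two-column CSV."""
    path = Path(path)
    arr = np.column_stack([np.asarray(times, float), np.asarray(values, float)])
    np.savetxt(path, arr, delimiter=",", header="time_s,value", comments="")
    return path


def read_signal_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return arr[:, 0], arr[:, 1]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def moving_mean_denoise(video: ThermalVideo, window_s: float = 1.0) -> ThermalVideo:
    """Temporal moving-mean filter reducing per-pixel quantization noise.

    Each pixel trace is replaced by its mean over a centered window of
    ``round(window_s * fps)`` frames.  Near the edges the window shrinks to
    the available frames, so no temperatures are invented at the boundaries
    and a constant video passes through unchanged.  The centered alignment
    introduces no group delay, keeping breath-peak timing intact.
    """
    k = int(round(window_s * video.fps))
    if k < 1:
        raise ValueError(f"window {window_s} s is shorter than one frame at {video.fps} fps")
    t = video.n_frames
    if k > t:
        raise ValueError(f"window of {k} frames longer than video ({t} frames)")
    left, right = (k - 1) // 2, k // 2
    idx = np.arange(t)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, t - 1)
    csum = np.concatenate(
        [np.zeros((1,) + video.shape), np.cumsum(video.frames, axis=0)], axis=0
    )
    counts = (hi - lo + 1).astype(float)[:, None, None]
    out = (csum[hi + 1] - csum[lo]) / counts
    return ThermalVideo(out, video.fps, video.t0)
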