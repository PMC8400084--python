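"""Synthetic thermopile scenes with respiratory ground truth.

The study recordings behind this benchmark are not publicly deposited, so
this module renders the equivalent scenes from first principles: a warm
block of body pixels over a cooler background on a tiny grid (8x8 by
default), with a respiration region whose temperature is modulated by a
guided sinusoidal breathing waveform.  Exhaling warms the region, inhaling
cools it.

Physical realism is intentionally minimal — block regions, inverse-square
geometric scaling with distance, Gaussian sensor noise, uniform temperature
quantization and optional body sway.  No radiometry, thermal diffusion or
human-shape rendering is attempted.  The point is a controllable scene in
which every pipeline stage has exact ground truth: the breathing waveform,
the breath-peak times (analytic, from the phase), and the programmed rate
profile.

The canonical guided-breathing protocol is four one-minute segments at
20, 10, 30 and 20 breaths/min.  Scenario grids mirror the two study
conditions: five mask/no-mask scenarios at short distances ("dataset A")
and a 10-150 cm distance sweep in 10 cm steps ("dataset B").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import RespiratorySignal, ThermalVideo, write_video
from .rates import PeakList, RateTrace, averaged_rate

__all__ = [
    "ProtocolConfig",
    "SceneConfig",
    "GroundTruth",
    "RoiLayout",
    "breathing_waveform",
    "roi_geometry",
    "render_video",
    "make_dataset",
    "dataset_a_scenarios",
    "dataset_b_scenarios",
    "load_manifest",
    "load_scenario",
]

#: Guided-breathing protocol: (duration_s, rate_bpm) per segment.
DATASET_A_PROTOCOL = ((60.0, 20.0), (60.0, 10.0), (60.0, 30.0), (60.0, 20.0))

#: Region sizes (pixels) at the 10 cm reference distance.
ROI_ANCHOR_PIXELS = {"mask": 12, "nostril": 2}
BODY_ANCHOR_PIXELS = 48
REFERENCE_DISTANCE_CM = 10.0


@dataclass
class ProtocolConfig:
    """Piecewise-constant guided-breathing protocol."""

    segments: tuple[tuple[float, float], ...] = DATASET_A_PROTOCOL

    def __post_init__(self) -> None:
        self.segments = tuple((float(d), float(r)) for d, r in self.segments)
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for d, r in self.segments:
            if d <= 0:
                raise ValueError(f"segment duration must be positive, got {d}")
            if not 10.0 <= r <= 50.0:
                raise ValueError(f"rate {r} bpm outside the respiratory band [10, 50]")

    @property
    def duration_s(self) -> float:
        return sum(d for d, _ in self.segments)

    def rate_at(self, times: np.ndarray) -> np.ndarray:
        """Programmed rate (bpm) at each timestamp, piecewise constant."""
        times = np.asarray(times, dtype=float)
        edges = np.cumsum([d for d, _ in self.segments])
        seg = np.searchsorted(edges, times, side="right")
        seg = np.clip(seg, 0, len(self.segments) - 1)
        rates = np.array([r for _, r in self.segments])
        return rates[seg]


@dataclass
class SceneConfig:
    """Everything that defines one rendered thermopile scene.

    Defaults describe a masked subject at 30 cm in a 21 degC room: body at
    31 degC, breathing modulation of 0.5 degC peak on the mask region,
    0.1 degC Gaussian sensor noise and 0.25 degC quantization.  ``sway_prob``
    is the per-second probability of a +/-1 pixel shift of the subject
    (default 0: guided breathing, standing still; enable it to study motion
    robustness).
    """

    grid: tuple[int, int] = (8, 8)
    fps: float = 10.0
    background_temp: float = 21.0
    body_temp: float = 31.0
    roi_kind: str = "mask"
    distance_cm: float = 30.0
    breath_amp: float | None = None
    noise_sd: float = 0.1
    quant_step: float = 0.25
    drift_per_min: float = 0.0
    sway_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_kind not in ROI_ANCHOR_PIXELS:
            raise ValueError(f"roi_kind must be one of {tuple(ROI_ANCHOR_PIXELS)}")
        if self.breath_amp is None:
            self.breath_amp = 0.5 if self.roi_kind == "mask" else 0.3
        if self.body_temp <= self.background_temp:
            raise ValueError("body must be warmer than the background")
        if self.breath_amp <= 0 or self.fps <= 0:
            raise ValueError("breath_amp and fps must be positive")
        if self.distance_cm < 5:
            raise ValueError("distance below the 5 cm minimum")


@dataclass
class GroundTruth:
    """Reference respiratory truth for one rendered scene."""

    waveform: RespiratorySignal
    ref_peaks: PeakList
    protocol: ProtocolConfig

    _ref_rate: RateTrace | None = field(default=None, repr=False)

    @property
    def ref_rate(self) -> RateTrace:
        """Reference rate trace: the clean waveform run through the same
        sliding-FFT estimator as the predictions (default 10 s / 0.1 s)."""
        if self._ref_rate is None:
            self._ref_rate = self.reference_rate()
        return self._ref_rate

    def reference_rate(self, window_s: float = 10.0, step_s: float = 0.1) -> RateTrace:
        return averaged_rate(self.waveform, window_s=window_s, step_s=step_s)

    def programmed_rate(self, times: np.ndarray) -> np.ndarray:
        return self.protocol.rate_at(np.asarray(times) - self.waveform.t0)


def breathing_waveform(
    protocol: ProtocolConfig,
    fps: float,
    t0: float = 0.0,
) -> GroundTruth:
    """Phase-continuous sinusoidal breathing waveform with analytic peaks.

    The instantaneous frequency is piecewise constant per protocol segment;
    the phase integrates the frequency, so there is no discontinuity at
    segment boundaries.  The waveform is ``sin(phase)`` and the ground-truth
    (exhale) peaks sit exactly at ``phase = pi/2 + 2*pi*k``, solved in
    closed form segment by segment.
    """
    n = int(round(protocol.duration_s * fps))
    times = np.arange(n) / fps

    # piecewise-linear phase, exact at every sample
    phase = np.zeros(n)
    peak_times: list[float] = []
    seg_start_t = 0.0
    seg_start_phase = 0.0
    for duration, rate_bpm in protocol.segments:
        f = rate_bpm / 60.0
        in_seg = (times >= seg_start_t) & (times < seg_start_t + duration)
        phase[in_seg] = seg_start_phase + 2 * np.pi * f * (times[in_seg] - seg_start_t)
        seg_end_phase = seg_start_phase + 2 * np.pi * f * duration
        # peaks: phase = pi/2 + 2 pi k inside [seg_start_phase, seg_end_phase)
        k = np.ceil((seg_start_phase - np.pi / 2) / (2 * np.pi))
        while True:
            target = np.pi / 2 + 2 * np.pi * k
            if target >= seg_end_phase - 1e-12:
                break
            if target >= seg_start_phase - 1e-12:
                peak_times.append(seg_start_t + (target - seg_start_phase) / (2 * np.pi * f))
            k += 1
        seg_start_t += duration
        seg_start_phase = seg_end_phase

    waveform = RespiratorySignal(np.sin(phase), fps, method="reference", t0=t0)
    peaks = PeakList(t0 + np.asarray(peak_times), t_start=t0, t_end=t0 + (n - 1) / fps)
    return GroundTruth(waveform=waveform, ref_peaks=peaks, protocol=protocol)


@dataclass
class RoiLayout:
    """Pixel geometry of one scene at a given distance.

    ``amp_scale`` is 1 for a resolved region and drops below 1 once the
    region would occupy less than one pixel: the breathing modulation is
    then mixed into a single pixel at proportionally reduced amplitude.
    """

    roi_pixels: np.ndarray  # (n, 2) row/col indices
    body_pixels: np.ndarray
    amp_scale: float


def _nearest_pixels(center: tuple[float, float], grid: tuple[int, int], n: int) -> np.ndarray:
    h, w = grid
    rr, cc = np.mgrid[0:h, 0:w]
    coords = np.column_stack([rr.ravel(), cc.ravel()])
    d2 = (coords[:, 0] - center[0]) ** 2 + (coords[:, 1] - center[1]) ** 2
    order = np.lexsort((coords[:, 1], coords[:, 0], d2))  # distance, then row-major
    return coords[order[:n]]


def roi_geometry(
    roi_kind: str,
    distance_cm: float,
    grid: tuple[int, int] = (8, 8),
) -> RoiLayout:
    """Inverse-square scaling of region sizes with subject distance.

    Region pixel counts are anchored at 10 cm (mask ~12 px, nostril ~2 px,
    body ~48 px) and scale as ``(10 / distance)**2``.  A sub-pixel region
    degenerates to one pixel carrying the breathing signal at reduced
    amplitude — the geometric reason nostril breathing becomes unmeasurable
    beyond short distances.
    """
    if roi_kind not in ROI_ANCHOR_PIXELS:
        raise ValueError(f"roi_kind must be one of {tuple(ROI_ANCHOR_PIXELS)}")
    if distance_cm < 5:
        raise ValueError("distance below the 5 cm minimum")
    h, w = grid
    n_pix = h * w
    scale = (REFERENCE_DISTANCE_CM / distance_cm) ** 2

    roi_frac = ROI_ANCHOR_PIXELS[roi_kind] * scale
    n_roi = int(np.floor(roi_frac))
    amp_scale = 1.0 if n_roi >= 1 else roi_frac
    n_roi = min(max(n_roi, 1), n_pix)

    n_body = int(np.floor(BODY_ANCHOR_PIXELS * scale))
    n_body = min(max(n_body, n_roi), n_pix)

    body_center = ((h - 1) / 2.0, (w - 1) / 2.0)
    body = _nearest_pixels(body_center, grid, n_body)

    # respiration region sits in the lower-center of the body (nostril/mask
    # area of a frontal face); pick the n_roi body pixels nearest that point
    roi_center = (min(h - 1, body_center[0] + h / 4.0), body_center[1])
    d2 = (body[:, 0] - roi_center[0]) ** 2 + (body[:, 1] - roi_center[1]) ** 2
    order = np.lexsort((body[:, 1], body[:, 0], d2))
    roi = body[order[:n_roi]]
    return RoiLayout(roi_pixels=roi, body_pixels=body, amp_scale=amp_scale)


def render_video(
    scene: SceneConfig,
    protocol: ProtocolConfig | None = None,
) -> tuple[ThermalVideo, GroundTruth]:
    """Render a thermopile video of a breathing subject, with ground truth.

    Background pixels sit at ``background_temp`` plus ambient drift, body
    pixels at ``body_temp``, and the respiration region is additionally
    modulated by ``breath_amp * amp_scale * waveform`` (positive at exhale).
    Optional sway shifts the subject by whole pixels, then Gaussian noise
    and quantization are applied.  Deterministic given ``scene.seed``.
    """
    if protocol is None:
        protocol = ProtocolConfig()
    gt = breathing_waveform(protocol, scene.fps)
    layout = roi_geometry(scene.roi_kind, scene.distance_cm, scene.grid)
    h, w = scene.grid
    n = gt.waveform.values.size
    rng = np.random.default_rng(scene.seed)

    times = np.arange(n) / scene.fps
    drift = scene.drift_per_min * times / 60.0
    frames = np.broadcast_to(drift[:, None, None], (n, h, w)).copy()
    frames += scene.background_temp

    # per-second sway: random-walk offset of the whole subject, in pixels
    n_seconds = int(np.ceil(n / scene.fps))
    offsets = np.zeros((n_seconds, 2), dtype=int)
    steps = rng.random(n_seconds)
    direction = rng.integers(0, 4, size=n_seconds)  # up/down/left/right
    dr = np.array([-1, 1, 0, 0])
    dc = np.array([0, 0, -1, 1])
    off = np.zeros(2, dtype=int)
    for s in range(n_seconds):
        if s > 0 and steps[s] < scene.sway_prob:
            off = off + np.array([dr[direction[s]], dc[direction[s]]])
        offsets[s] = off

    amp = scene.breath_amp * layout.amp_scale
    sec_index = np.minimum(np.arange(n) // int(round(scene.fps)), n_seconds - 1)
    for s in range(n_seconds):
        frame_sel = np.nonzero(sec_index == s)[0]
        if frame_sel.size == 0:
            continue
        body = np.clip(layout.body_pixels + offsets[s], [0, 0], [h - 1, w - 1])
        roi = np.clip(layout.roi_pixels + offsets[s], [0, 0], [h - 1, w - 1])
        frames[frame_sel[:, None], body[:, 0][None, :], body[:, 1][None, :]] = (
            scene.body_temp + drift[frame_sel][:, None]
        )
        frames[frame_sel[:, None], roi[:, 0][None, :], roi[:, 1][None, :]] += (
            amp * gt.waveform.values[frame_sel][:, None]
        )

    if scene.noise_sd > 0:
        frames += rng.normal(0.0, scene.noise_sd, size=frames.shape)
    if scene.quant_step > 0:
        frames = np.round(frames / scene.quant_step) * scene.quant_step
    return ThermalVideo(frames, scene.fps), gt


# ---------------------------------------------------------------------------
# scenario grids and dataset writing
# ---------------------------------------------------------------------------


def dataset_a_scenarios(seed: int = 0, **overrides) -> list[tuple[str, SceneConfig, ProtocolConfig]]:
    """Five short-distance scenarios: mask at 10/30/50 cm, nostril at 5/10 cm."""
    protocol = ProtocolConfig()
    out = []
    specs = [("M-10cm", "mask", 10), ("M-30cm", "mask", 30), ("M-50cm", "mask", 50),
             ("N-5cm", "nostril", 5), ("N-10cm", "nostril", 10)]
    for i, (name, kind, dist) in enumerate(specs):
        scene = SceneConfig(roi_kind=kind, distance_cm=dist, seed=seed + i, **overrides)
        out.append((name, scene, protocol))
    return out


def dataset_b_scenarios(seed: int = 0, **overrides) -> list[tuple[str, SceneConfig, ProtocolConfig]]:
    """Masked-subject distance sweep: 10 to 150 cm in 10 cm steps."""
    protocol = ProtocolConfig()
    out = []
    for i, dist in enumerate(range(10, 151, 10)):
        scene = SceneConfig(roi_kind="mask", distance_cm=dist, seed=seed + i, **overrides)
        out.append((f"D-{dist}cm", scene, protocol))
    return out


def make_dataset(
    scenarios: list[tuple[str, SceneConfig, ProtocolConfig]],
    out_dir: str | Path,
) -> Path:
    """Render scenarios to disk: video (NPZ), ground truth (CSV), manifest (JSON).

    Returns the manifest path.
    """
    if not scenarios:
        raise ValueError("empty scenario list")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, scene, protocol in scenarios:
        video, gt = render_video(scene, protocol)
        video_path = out_dir / f"{name}.npz"
        write_video(video, video_path)
        wf_path = out_dir / f"{name}_waveform.csv"
        np.savetxt(wf_path, np.column_stack([gt.waveform.times, gt.waveform.values]),
                   delimiter=",", header="time_s,value", comments="")
        pk_path = out_dir / f"{name}_peaks.csv"
        np.savetxt(pk_path, gt.ref_peaks.peak_times[:, None],
                   delimiter=",", header="peak_time_s", comments="")
        entries.append({
            "name": name,
            "video": video_path.name,
            "waveform": wf_path.name,
            "peaks": pk_path.name,
            "roi_kind": scene.roi_kind,
            "distance_cm": scene.distance_cm,
            "seed": scene.seed,
            "fps": scene.fps,
            "segments": list(map(list, protocol.segments)),
        })
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps({"scenarios": entries}, indent=2))
    return manifest_path


def load_manifest(manifest_path: str | Path) -> list[dict]:
    return json.loads(Path(manifest_path).read_text())["scenarios"]


def load_scenario(entry: dict, base_dir: str | Path) -> tuple[ThermalVideo, GroundTruth]:
    """Reload one rendered scenario (video + ground truth) from disk."""
    from .core import read_video

    base = Path(base_dir)
    video = read_video(base / entry["video"])
    wf = np.loadtxt(base / entry["waveform"], delimiter=",", skiprows=1, ndmin=2)
    peaks = np.loadtxt(base / entry["peaks"], delimiter=",", skiprows=1, ndmin=2)
    waveform = RespiratorySignal(wf[:, 1], entry["fps"], method="reference", t0=wf[0, 0])
    t_end = wf[-1, 0]
    peak_list = PeakList(peaks[:, 0] if peaks.size else np.empty(0),
                         t_start=wf[0, 0], t_end=t_end)
    protocol = ProtocolConfig(tuple(map(tuple, entry["segments"])))
    return video, GroundTruth(waveform=waveform, ref_peaks=peak_list, protocol=protocol)
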