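# Methods

`thermogate` implements a benchmark system for contactless respiratory-rate
(RR) screening with a thermopile array: a grid of thermocouple elements that
reports an absolute-temperature image at very low spatial resolution
(canonically 8×8 pixels at 10 fps). Exhaled air warms the region around the
nostrils — or, far more visibly, the outer surface of a face mask — by a few
tenths of a degree Celsius, so the breathing rhythm is present in the video
as a small periodic temperature modulation. The package covers the full
chain from raw video to evaluation statistics, plus a scene simulator that
provides exact ground truth.

## Signal model and extraction methods

Let `I(x, y, t)` be the temperature of pixel `(x, y)` in frame `t` of an
`H×W` video. Raw frames may first be denoised with a 1 s temporal moving
mean (centered window, shrinking at the edges; centering adds no group
delay, so breath-peak timing is preserved — the alignment and edge policy
are this package's choices, flagged for sensitivity analysis).

Three whole-frame (FVP) statistics turn each frame into one sample:

- **FVP-AVG** `AVG(t) = (1/HW) Σ_x Σ_y I(x, y, t)` — the spatial mean.
  Effective when the respiration region fills a large part of the frame.
- **FVP-VAR** `VAR(t) = sign(m3) |m3|^{1/3}` with
  `m3 = (1/HW) Σ (I − μ_t)^3` — a signed third-order contrast statistic.
  The odd order preserves inhale/exhale polarity (a standard deviation
  would fold both phases onto positive values); the signed real cube root
  of the mean cubed deviation is used, negative when `m3 < 0`.
- **FVP-Alpha** `Alpha(t) = AVG(t) + (σ(AVG)/σ(VAR)) · VAR(t)`, both inputs
  mean-centered first. Exhaling raises both the mean and the contrast, so
  the two components are in phase and add coherently. The gain `σ(AVG)/σ(VAR)`
  is computed per extraction window (the processing is windowed anyway, and
  a local gain tracks non-stationary amplitude); a flat VAR input raises an
  error and the pipeline falls back to AVG.

Three segmentation (Seg) methods first split each analysis window's pixels
into foreground and background by two-cluster K-means on the per-pixel
*DC temperature* (temporal mean over the window). The clustering is the
deterministic scalar variant: initial centroids at the maximum and minimum
DC value, squared-Euclidean assignment, Lloyd updates until the assignment
stops changing; the warmer cluster is the foreground (the subject is
assumed warmer than the background). From the foreground:

- **Seg-AVG** — spatial mean over all foreground pixels;
- **Seg-SNR** — mean over foreground pixels whose respiratory SNR (linear
  ratio of spectral energy inside [10, 50] bpm to energy outside it, DC bin
  excluded, Hann-tapered window) is at or above the 75th percentile of the
  foreground distribution, never fewer than one pixel. The keep-count is
  unspecified in the underlying method description; the percentile rule
  keeps a handful of pixels for noise averaging and is exposed as a
  parameter (`percentile=0` reduces to Seg-AVG);
- **Seg-AC** — the single foreground pixel with the largest temporal
  standard deviation, ties broken to the first pixel in row-major order.

A note on the K-means variant: a Lloyd fixed point on scalar features is
always a threshold partition of the sorted values, and on two-level maps
(warm body over cooler background — every map this pipeline produces) it
coincides with the exhaustive-search optimum; on structureless inputs it can
be a local optimum, which is a property of the prescribed algorithm and is
documented by the tests.

## Windowed processing

All methods run in a sliding analysis window (5/10/20/30 s benchmarked;
hop 1 s, this package's default — the hop is not prescribed by the method
description). Per window: (Seg only) recompute DC features, mask and
quality maps; extract the trace; band-pass to 0.167–0.833 Hz with a
zero-phase (forward–backward) 4th-order Butterworth; overlap-add the
filtered pieces into a full-length signal.

Numerical choices:

- *Filter edges.* `filtfilt`-style filtering is sensitive at the low band
  edge (a 10 bpm tone sits exactly at the 0.167 Hz cutoff). The pad length
  is one full low-cutoff period, and each window is filtered over a span
  extended by one such period of real neighboring frames, then cropped
  back. Masks and quality maps still come from the nominal window.
- *Overlap-add.* Each segment is mean-centered, weighted by a strictly
  positive shifted sine-squared taper and accumulated; the accumulator is
  divided by the accumulated weights (floored at 1e−12). Wherever the
  contributing segments agree the reconstruction is exact, including
  single-coverage and disjoint spans.

## Rate calculators

- **Averaged rate** (frequency domain): 10 s window sliding in 0.1 s steps;
  mean-removed, Hann-tapered, zero-padded to ≥ 4096 points; argmax of the
  magnitude spectrum restricted to [10, 50] bpm, timestamped at the window
  center. The native 10 s window resolves only 6 bpm; zero-padding gives a
  ~0.15 bpm grid at 10 fps, which is what makes sub-bpm MAE meaningful.
  All-zero windows yield NaN and are excluded pairwise from metrics.
- **Instantaneous rate** (time domain): breath peaks are local maxima with
  prominence ≥ 0.3 × signal standard deviation and separation ≥ 1.2 s (the
  period of the 50 bpm band ceiling); the detector parameters are not
  prescribed by the method description and are exposed as arguments. Each
  inter-breath interval maps to `60/interval` bpm at the interval midpoint.

## Evaluation metrics

After nearest-timestamp alignment (maximum offset half the rate step):
MAE = `Σ|RR_pre − RR_ref|/N`; the Pearson product-moment correlation;
coverage = `C/N` with `C` counting `|RR_pre − RR_ref| ≤ 3` bpm (the bound
is inclusive: an error of exactly 3 bpm counts as covered).

Peak matching: reference peak `i` owns the interval from the midpoint with
its predecessor to the midpoint with its successor; the signal's start/end
bound the first/last intervals, and membership is half-open `[lo, hi)` so a
prediction on a midpoint belongs to exactly one interval. A reference peak
is valid iff exactly one predicted peak falls in its interval;
precision = `NP_valid/NP_pre`, recall = `NP_valid/NP_ref`.

## The scene simulator

The simulator emulates the two study conditions — guided breathing at short
distances with/without a face mask, and a masked-subject distance sweep
from 10 to 150 cm in 10 cm steps — since the original recordings are not
publicly available. It renders block regions only:

- background at 21 °C, body block at 31 °C (warm-over-cool ordering is the
  premise the segmentation relies on), optional linear ambient drift;
- a respiration region inside the body block whose temperature is modulated
  by `breath_amp · waveform`, positive at exhale (0.5 °C peak for a mask
  region, 0.3 °C for a nostril region);
- the guided waveform is a phase-continuous sinusoid whose instantaneous
  frequency is piecewise constant per protocol segment (default protocol:
  four one-minute segments at 20/10/30/20 bpm); breath-peak times are
  solved analytically from the phase;
- geometry scales with distance as `(10 cm / d)²`, anchored at 12 mask
  pixels / 2 nostril pixels / 48 body pixels at 10 cm. A sub-pixel region
  collapses to one pixel with proportionally diluted amplitude — the
  geometric reason nostril breathing becomes unmeasurable beyond ~10 cm;
- per-pixel Gaussian sensor noise (default σ = 0.1 °C), uniform temperature
  quantization (default step 0.25 °C, sensor-class resolution), and
  optional body sway as a per-second ±1 pixel random-walk shift of the
  subject (default probability 0: guided breathing, standing still; enable
  for motion-robustness experiments). All randomness flows from one seed;
  renders are bit-identical for identical configurations.

The reference rate trace used in the evaluation is the clean waveform run
through the same sliding-FFT estimator as the predictions — i.e. the
reference RR is *extracted from the reference respiratory signal*, so
prediction and reference see segment boundaries the same way. The piecewise
programmed rate remains available separately.

What the simulator deliberately omits: radiometric physics (emissivity,
atmospheric attenuation), thermal diffusion, realistic human shape, head
pose, breathing irregularity and apnea. Passing tests therefore demonstrate
correctness of the processing chain and its qualitative behavior (mask vs
nostril, distance degradation, Seg vs FVP ordering), not clinical
performance on human subjects.

## Problem sizes in tests and reproduction runs

The reproduction script uses the full 4-minute protocol for the noisy
masked-subject run and 60 s single-segment renders for the clean rate
checks. The distance-degradation property is tested on a scaled-down 90 s
protocol (45 s at 20 bpm + 45 s at 10 bpm) with a 1 s rate step over
10 seeds × 15 distances — enough to resolve the monotone trend while
keeping the suite quick. These sizes are the package's own defaults for its
test conditions.

## Known limitations

- At 8×8 resolution the segmentation separates subject from background
  only; facial parts cannot be distinguished, so beyond ~60 cm all methods
  degrade substantially (mirrored by the simulator's geometry).
- The peak detector's prominence threshold trades precision against recall;
  short windows with low-frequency residue can produce spurious peaks.
- The instantaneous-rate evaluation assumes reasonably regular breathing;
  apnea or highly irregular patterns are out of scope.
- The Alpha combination assumes the AVG and VAR respiratory components are
  in phase; scenes where they decorrelate (e.g. strong sway) can make the
  combination worse than either input.
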