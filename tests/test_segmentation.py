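import numpy as np
import pytest

import thermogate as tg
from thermogate.segmentation import DegenerateSegmentationError


def exhaustive_two_means(vals):
    """Exhaustive threshold-partition 2-means: the 1-D optimum is always a
    threshold partition of the sorted values."""
    vals = np.asarray(vals, float).ravel()
    order = np.argsort(vals, kind="stable")
    s = vals[order]
    best_split, best_wcss = None, np.inf
    for k in range(1, s.size):
        lo, hi = s[:k], s[k:]
        w = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if w < best_wcss - 1e-15:
            best_wcss, best_split = w, k
    labels = np.zeros(vals.size, dtype=bool)
    labels[order[best_split:]] = True  # upper (warmer) cluster
    return labels, best_wcss


def wcss_of(vals, fg):
    a, b = vals[fg], vals[~fg]
    out = ((a - a.mean()) ** 2).sum()
    if b.size:
        out += ((b - b.mean()) ** 2).sum()
    return out


def structured_dc_map(rng, shape=(3, 3), n_fg=None):
    """Random DC map with genuine two-level structure: a warm subject over a
    cooler background, both with sensor-scale scatter."""
    n = shape[0] * shape[1]
    if n_fg is None:
        n_fg = int(rng.integers(1, max(2, n // 3 + 1)))
    vals = np.concatenate(
        [rng.normal(31.0, 0.3, n_fg), rng.normal(21.0, 0.3, n - n_fg)]
    )
    rng.shuffle(vals)
    return vals.reshape(shape)


class TestDcFeatures:
    def test_constant_video_and_two_frame_mean(self):
        video = tg.ThermalVideo(np.full((10, 4, 4), 23.0), 10.0)
        assert np.allclose(tg.dc_features(video), 23.0)
        two = tg.ThermalVideo(np.array([[[20.0]], [[22.0]]]), 10.0)
        assert tg.dc_features(two)[0, 0] == pytest.approx(21.0)

    def test_matches_loop_oracle_on_span(self, random_video):
        span = (5, 25)
        dc = tg.dc_features(random_video, span)
        h, w = random_video.shape
        for x in range(h):
            for y in range(w):
                assert dc[x, y] == pytest.approx(
                    random_video.frames[span[0]:span[1], x, y].mean(), rel=1e-14
                )

    def test_empty_span_rejected(self, random_video):
        with pytest.raises(ValueError):
            tg.dc_features(random_video, (10, 10))


class TestKmeansForeground:
    def test_bimodal_map_recovers_warm_pixels(self, rng):
        dc = np.full((8, 8), 21.0)
        warm = rng.choice(64, size=12, replace=False)
        dc.ravel()[warm] = 33.0
        mask = tg.kmeans_foreground(dc)
        assert set(np.flatnonzero(mask.mask.ravel())) == set(warm)
        assert mask.centroids[0] == pytest.approx(33.0)
        assert mask.centroids[1] == pytest.approx(21.0)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_exhaustive_partition_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        shape = (3, 3) if trial % 2 else (4, 4)
        dc = structured_dc_map(rng, shape)
        mask = tg.kmeans_foreground(dc)
        oracle_labels, oracle_wcss = exhaustive_two_means(dc)
        assert np.array_equal(mask.mask.ravel(), oracle_labels)
        assert wcss_of(dc.ravel(), mask.mask.ravel()) == pytest.approx(oracle_wcss)

    def test_result_is_threshold_partition(self, rng):
        # any Lloyd fixed point in 1-D splits the sorted values at a threshold
        for _ in range(20):
            dc = rng.uniform(20, 33, size=(4, 4))
            mask = tg.kmeans_foreground(dc)
            fg_min = dc[mask.mask].min()
            bg_max = dc[~mask.mask].max()
            assert fg_min > bg_max

    def test_translation_invariance(self, rng):
        dc = structured_dc_map(rng, (4, 4))
        base = tg.kmeans_foreground(dc)
        shifted = tg.kmeans_foreground(dc + 7.5)
        assert np.array_equal(base.mask, shifted.mask)

    def test_foreground_is_warmer_cluster(self, rng):
        dc = structured_dc_map(rng, (8, 8), n_fg=10)
        mask = tg.kmeans_foreground(dc)
        assert dc[mask.mask].mean() >= dc[~mask.mask].mean()

    def test_degenerate_map_raises(self):
        with pytest.raises(DegenerateSegmentationError):
            tg.kmeans_foreground(np.full((8, 8), 25.0))


class TestSegAvg:
    def test_full_mask_reduces_to_fvp_avg(self, random_video):
        mask = tg.ForegroundMask(np.ones((8, 8), bool), (25.0, 25.0))
        assert np.allclose(
            tg.seg_avg(random_video, mask).values,
            tg.fvp_avg(random_video).values,
            rtol=0, atol=1e-12,
        )

    def test_single_pixel_mask_returns_that_trace(self, random_video):
        m = np.zeros((8, 8), bool)
        m[3, 5] = True
        mask = tg.ForegroundMask(m, (30.0, 21.0))
        assert np.array_equal(
            tg.seg_avg(random_video, mask).values, random_video.frames[:, 3, 5]
        )

    def test_matches_loop_oracle(self, random_video, rng):
        m = rng.random((8, 8)) < 0.3
        m[0, 0] = True
        mask = tg.ForegroundMask(m, (30.0, 21.0))
        out = tg.seg_avg(random_video, mask).values
        expected = np.array(
            [random_video.frames[t][m].mean() for t in range(random_video.n_frames)]
        )
        assert np.allclose(out, expected, rtol=1e-14)


class TestPixelSnr:
    def make_video(self, trace, n_pix=4):
        frames = np.tile(trace[:, None, None], (1, 2, 2))
        return tg.ThermalVideo(frames, 10.0)

    def test_inband_sinusoid_has_high_snr(self):
        t = np.arange(300) / 10.0
        video = self.make_video(25.0 + np.sin(2 * np.pi * t / 3))  # 20 bpm
        q = tg.pixel_snr(video)
        assert np.all(q.snr >= 100)

    def test_outband_sinusoid_has_low_snr(self):
        t = np.arange(300) / 10.0
        video = self.make_video(25.0 + np.sin(2 * np.pi * 1.5 * t))  # 90 bpm
        q = tg.pixel_snr(video)
        assert np.all(q.snr <= 0.05)

    def test_white_noise_snr_near_band_ratio(self, rng):
        # flat spectrum: SNR ~ inband width / outband width
        n = 3000
        traces = rng.normal(size=(n, 1, 1))
        video = tg.ThermalVideo(25 + traces, 10.0)
        q = tg.pixel_snr(video)
        expected = (50 - 10) / 60.0 / (5.0 - (50 - 10) / 60.0)  # ~0.154
        assert q.snr[0, 0] == pytest.approx(expected, rel=0.5)

    def test_offset_and_scale_invariance(self, rng):
        trace = rng.normal(size=200)
        v1 = self.make_video(trace + 25.0)
        v2 = self.make_video(3.0 * trace + 40.0)
        q1, q2 = tg.pixel_snr(v1), tg.pixel_snr(v2)
        assert np.allclose(q1.snr, q2.snr, rtol=1e-9)

    def test_ac_is_temporal_std(self, random_video):
        q = tg.pixel_snr(random_video)
        assert np.allclose(q.ac, random_video.frames.std(axis=0))


class TestSegSnrSegAc:
    def breathing_pixel_video(self, rng):
        t = np.arange(300) / 10.0
        frames = 21.0 + 0.05 * rng.normal(size=(300, 8, 8))
        frames[:, 2:6, 2:6] += 10.0  # warm body block
        frames[:, 4, 4] += 1.0 * np.sin(2 * np.pi * t / 3)
        return tg.ThermalVideo(frames, 10.0)

    def test_snr_selection_keeps_the_breathing_pixel(self, rng):
        video = self.breathing_pixel_video(rng)
        mask = tg.kmeans_foreground(tg.dc_features(video))
        quality = tg.pixel_snr(video, mask)
        assert mask.mask[4, 4]
        sel_best = np.nanargmax(np.where(mask.mask, quality.snr, np.nan))
        assert sel_best == 4 * 8 + 4

    def test_identical_foreground_pixels_reduce_to_seg_avg(self):
        t = np.arange(100) / 10.0
        frames = np.full((100, 4, 4), 21.0)
        frames[:, :2, :2] = 31.0 + np.sin(2 * np.pi * t / 3)[:, None, None]
        video = tg.ThermalVideo(frames, 10.0)
        mask = tg.kmeans_foreground(tg.dc_features(video))
        quality = tg.pixel_snr(video, mask)
        out = tg.seg_snr(video, mask, quality)
        assert np.allclose(out.values, tg.seg_avg(video, mask).values)

    def test_percentile_zero_reduces_to_seg_avg(self, rng):
        video = self.breathing_pixel_video(rng)
        mask = tg.kmeans_foreground(tg.dc_features(video))
        quality = tg.pixel_snr(video, mask)
        out = tg.seg_snr(video, mask, quality, percentile=0.0)
        assert np.allclose(out.values, tg.seg_avg(video, mask).values)

    def test_seg_ac_selects_highest_std_pixel(self, rng):
        video = self.breathing_pixel_video(rng)
        mask = tg.kmeans_foreground(tg.dc_features(video))
        quality = tg.pixel_snr(video, mask)
        out = tg.seg_ac(video, mask, quality)
        assert np.array_equal(out.values, video.frames[:, 4, 4])

    def test_seg_ac_tie_breaks_row_major(self):
        frames = np.full((50, 4, 4), 21.0)
        wave = np.sin(2 * np.pi * np.arange(50) / 25)
        frames[:, 1, 1] = 31.0 + wave
        frames[:, 2, 3] = 31.0 + wave  # identical std, later in row-major order
        video = tg.ThermalVideo(frames, 10.0)
        mask = tg.kmeans_foreground(tg.dc_features(video))
        quality = tg.pixel_snr(video, mask)
        out = tg.seg_ac(video, mask, quality)
        assert np.array_equal(out.values, video.frames[:, 1, 1])

    def test_seg_ac_matches_argmax_oracle(self, random_video):
        mask = tg.ForegroundMask(np.ones((8, 8), bool), (25.0, 25.0))
        quality = tg.pixel_snr(random_video, mask)
        out = tg.seg_ac(random_video, mask, quality)
        stds = random_video.frames.std(axis=0)
        r, c = np.unravel_index(np.argmax(stds), stds.shape)
        assert np.array_equal(out.values, random_video.frames[:, r, c])
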