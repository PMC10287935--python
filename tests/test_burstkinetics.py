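import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clusterscope.burstkinetics import (BinaryTrace, TSTrace, _apply_burst_rules,
                                        _runs, binarize_trace,
                                        bootstrap_asl_test, burst_statistics,
                                        correct_xy_drift,
                                        estimate_background_sd,
                                        fit_lorentzian_scale, gamma_to_sd,
                                        gaussian_mask_photometry,
                                        track_transcription_sites)
from clusterscope.segmentation import LabelMask
from clusterscope.synth import (SceneSpec, TelegraphParams, render_ts_movie,
                                simulate_ts_movie)


def make_trace(intensity, bg_sd=1.0, interval=15.0):
    intensity = np.asarray(intensity, dtype=float)
    return TSTrace(cell_label=1, times=np.arange(intensity.size) * interval,
                   intensity=intensity, bg_sd=bg_sd)


def brute_force_rules(raw):
    """Direct application of the two clean-up rules on a 0/1 list."""
    s = list(raw)
    n = len(s)
    # merge on-runs separated by exactly one off frame
    out = s[:]
    for i in range(1, n - 1):
        if s[i] == 0 and s[i - 1] == 1 and s[i + 1] == 1:
            out[i] = 1
    s = out[:]
    # remove remaining on-runs of length 1
    i = 0
    while i < n:
        if s[i] == 1:
            j = i
            while j < n and s[j] == 1:
                j += 1
            if j - i == 1:
                out[i] = 0
            i = j
        else:
            i += 1
    return out


class TestBinarize:
    def test_single_frame_burst_removed(self):
        bt = binarize_trace(make_trace([0, 0, 10, 0, 0]), k=6)
        assert np.all(bt.states == 0)

    def test_single_frame_gap_merged(self):
        bt = binarize_trace(make_trace([10, 0, 10]), k=6)
        assert np.all(bt.states == 1)

    def test_gaps_bridged_before_burst_removal(self):
        # (1,0,1,0,1): both gaps merged into one 5-frame burst, so the
        # single-frame runs survive as part of it
        bt = binarize_trace(make_trace([10, 0, 10, 0, 10]), k=6)
        assert np.all(bt.states == 1)

    def test_isolated_single_frame_still_removed(self):
        bt = binarize_trace(make_trace([0, 10, 0, 0, 10, 10, 0]), k=6)
        assert bt.states.tolist() == [0, 0, 0, 0, 1, 1, 0]

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=30))
    def test_invariants_and_brute_force_agreement(self, raw):
        cleaned = _apply_burst_rules(np.array(raw))
        assert cleaned.tolist() == brute_force_rules(raw)
        BinaryTrace(states=cleaned, threshold=1.0)  # invariant check in ctor

    def test_missing_bg_sd_rejected(self):
        with pytest.raises(ValueError):
            binarize_trace(make_trace([1, 2, 3], bg_sd=float("nan")))

    def test_telegraph_states_recovered_noiselessly(self):
        p = TelegraphParams(k_on=1 / 200, k_off=1 / 200, initiation_rate=0.5,
                            dwell_time=60.0, noise_sd=0.0)
        out = simulate_ts_movie(p, 10, 3600.0, seed=3)
        for intensity, state in zip(out["intensity"], out["state"]):
            bt = binarize_trace(make_trace(intensity, bg_sd=1.0), k=6)
            truth = _apply_burst_rules(state)
            # dwell smears the off transition by <= dwell_time frames
            on_err = np.mean(bt.states != truth)
            assert on_err < 0.25


class TestBurstStatistics:
    def test_worked_example(self):
        raw = [0, 0, 1, 1, 1, 0, 0, 1, 1]
        bt = BinaryTrace(np.array(raw), threshold=6.0)
        tt = make_trace(np.array(raw, dtype=float) * 10)
        bs = burst_statistics([bt], [tt], frame_interval=15.0, n_boot=10)
        assert sorted(bs.burst_durations.tolist()) == [30.0, 45.0]
        assert bs.inter_burst_times.tolist() == [30.0]
        assert bs.induction_times.tolist() == [30.0]
        assert bs.burst_intensities.tolist() == [10.0]

    def test_all_off_counts_in_denominator(self):
        on = BinaryTrace(np.array([0, 1, 1, 0]), threshold=1.0)
        off = BinaryTrace(np.array([0, 0, 0, 0]), threshold=1.0)
        tt = make_trace([0, 5, 5, 0])
        bs = burst_statistics([on, off], [tt, make_trace([0, 0, 0, 0])],
                              n_boot=10)
        assert bs.n_cells == 2 and bs.n_active == 1
        assert bs.active_fraction == 0.5
        assert bs.active_fraction_err == pytest.approx(np.sqrt(1) / 2)

    def test_on_off_frames_partition_trace(self):
        raw = np.array([0, 1, 1, 0, 0, 1, 1, 1])
        bt = BinaryTrace(raw, threshold=1.0)
        runs = _runs(bt.states)
        assert sum(length for _, length, _ in runs) == raw.size

    def test_right_censored_excluded_when_requested(self):
        raw = [0, 1, 1, 0, 0, 1, 1]  # final run touches the end
        bt = BinaryTrace(np.array(raw), threshold=1.0)
        tt = make_trace(np.array(raw, float) * 10)
        bs = burst_statistics([bt], [tt], n_boot=10, drop_right_censored=True)
        assert bs.burst_durations.tolist() == [30.0]


class TestDriftCorrection:
    def _drifting_movie(self, rate=0.2, n=20):
        # drift applied analytically so the ground truth is exact
        rng = np.random.default_rng(0)
        pts = rng.uniform(12, 52, (6, 2))
        yy, xx = np.mgrid[0:64, 0:64]

        def frame(d):
            img = np.zeros((64, 64))
            for y, x in pts:
                img += 1000 * np.exp(-((yy - y - d) ** 2 + (xx - x - d) ** 2)
                                     / (2 * 2.0**2))
            return img

        return np.array([frame(rate * t) for t in range(n)])

    def test_linear_drift_removed(self):
        movie = self._drifting_movie()
        corrected, shifts, _ = correct_xy_drift(movie)
        # applied shifts track the drift to subpixel accuracy
        expected = -0.2 * np.arange(20)
        assert np.abs(shifts[:, 0] - expected).max() < 0.05

    def test_static_movie_identity(self):
        movie = np.tile(self._drifting_movie(rate=0.0, n=1), (5, 1, 1))
        _, shifts, _ = correct_xy_drift(movie)
        assert np.abs(shifts).max() < 1e-3

    def test_round_trip(self):
        from scipy import ndimage
        base = self._drifting_movie(rate=0.0, n=1)[0]
        shifted = ndimage.shift(base, (1.0, -2.0), order=1)
        movie = np.stack([base, shifted])
        corrected, _, _ = correct_xy_drift(movie)
        inner = (slice(8, -8), slice(8, -8))
        assert np.abs(corrected[1][inner] - base[inner]).max() < \
            0.05 * base.max()

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            correct_xy_drift(np.zeros((1, 8, 8)))


@pytest.fixture(scope="module")
def constant_ts_movie():
    traces = dict(intensity=np.full((1, 30), 800.0),
                  state=np.ones((1, 30), int))
    scene = SceneSpec(shape=(5, 48, 48), seed=0)
    movie, pos = render_ts_movie(traces, scene)
    labels = np.ones((48, 48), dtype=np.int32)
    return movie, pos, labels


class TestTracking:
    def test_constant_ts_intensity_recovered(self, constant_ts_movie):
        movie, pos, labels = constant_ts_movie
        out = track_transcription_sites(movie, LabelMask(labels))
        tr = out[0]
        # photometry estimates the 2D-integrated intensity of the projected
        # spot: peak 800 x 2 pi sigma_xy^2
        expect = 800.0 * 2 * np.pi * 1.66**2
        assert np.all(np.abs(tr.intensity - expect) / expect < 0.02)
        assert not tr.excluded

    def test_empty_cell_inactive(self):
        scene = SceneSpec(shape=(5, 48, 48), seed=1, noise_model="gaussian",
                          noise_sd=2.0)
        movie, _ = render_ts_movie(
            dict(intensity=np.zeros((1, 10))), scene)
        labels = np.ones((48, 48), dtype=np.int32)
        out = track_transcription_sites(movie, LabelMask(labels))
        assert out[0].excluded
        assert np.abs(out[0].intensity).max() < 50

    def test_blinking_gap_positional_hold(self):
        intensity = np.full((1, 12), 900.0)
        intensity[0, 5:8] = 0.0  # TS off for 3 frames
        scene = SceneSpec(shape=(5, 48, 48), seed=2)
        movie, pos = render_ts_movie(dict(intensity=intensity), scene)
        out = track_transcription_sites(movie, LabelMask(
            np.ones((48, 48), dtype=np.int32)))
        tr = out[0]
        # positions held during the gap at the last detected location
        assert np.allclose(tr.position[5:8], tr.position[4], atol=0.5)
        assert np.abs(tr.intensity[5:8]).max() < 0.1 * tr.intensity[4]


class TestBackgroundSD:
    def test_gaussian_background_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 5.0, 3000)
        _, gamma = fit_lorentzian_scale(x)
        assert gamma_to_sd(gamma) == pytest.approx(5.0, rel=0.15)

    def test_cauchy_scale_recovered(self):
        from scipy import stats
        x = stats.cauchy.rvs(loc=10, scale=3.0, size=3000,
                             random_state=np.random.default_rng(1))
        _, gamma = fit_lorentzian_scale(x)
        assert gamma == pytest.approx(3.0, rel=0.15)

    def test_zero_noise_movie_sd_near_zero(self):
        scene = SceneSpec(shape=(5, 48, 48), seed=3)
        movie, pos = render_ts_movie(
            dict(intensity=np.full((1, 30), 800.0)), scene)
        out = track_transcription_sites(movie, LabelMask(
            np.ones((48, 48), dtype=np.int32)))
        sd = estimate_background_sd(movie, out[0])
        expect = 800.0 * 2 * np.pi * 1.66**2
        assert sd < 0.01 * expect

    def test_noisy_movie_sd_within_range(self):
        scene = SceneSpec(shape=(5, 48, 48), seed=4, noise_model="gaussian",
                          noise_sd=10.0)
        movie, pos = render_ts_movie(
            dict(intensity=np.full((1, 40), 2000.0)), scene)
        out = track_transcription_sites(movie, LabelMask(
            np.ones((48, 48), dtype=np.int32)))
        sd = estimate_background_sd(movie, out[0])
        assert 0 < sd < 2000.0 * 2 * np.pi * 1.66**2 * 0.2

    def test_few_samples_fallback(self):
        tr = make_trace(np.arange(5.0))
        tr.position = None
        sd = estimate_background_sd(np.zeros((5, 1, 16, 16)), tr)
        assert np.isfinite(sd)


class TestASL:
    def test_identical_samples_asl_near_one(self):
        v = np.arange(30.0)
        assert bootstrap_asl_test(v, v, n_rep=500, seed=0) > 0.9

    def test_separated_samples_asl_small(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 100)
        b = rng.normal(3, 1, 100)
        assert bootstrap_asl_test(a, b, n_rep=1000, seed=2) < 0.01

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 40), rng.normal(0.2, 1, 40)
        r1 = bootstrap_asl_test(a, b, seed=7)
        r2 = bootstrap_asl_test(a, b, seed=7)
        assert r1 == r2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_asl_test([], [1.0])
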