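import numpy as np
import pytest

from clusterscope.spotfit import (DetectionConfig, SpotFit, SpotModelParams,
                                  detect_candidates, estimate_edge_background,
                                  filter_spots, goodness_of_fit, kept,
                                  peak_intensity, refine_spot,
                                  threshold_from_sd)
from clusterscope.synth import (GroundTruthSpot, SceneSpec,
                                gaussian_spot_value, render_spot_stack)

from conftest import random_spot

CFG = DetectionConfig()
TWO_PI_32 = (2 * np.pi) ** 1.5


class TestDetectCandidates:
    def test_single_spot_single_candidate(self, single_spot_stack):
        stack, truth = single_spot_stack
        cfg = DetectionConfig(abs_threshold=threshold_from_sd(stack, CFG, 5))
        cands = detect_candidates(stack, cfg)
        assert len(cands) == 1
        assert np.all(np.abs(cands[0] - [truth.z0, truth.y0, truth.x0]) <= 1)

    def test_constant_stack_no_candidates(self):
        cfg = DetectionConfig(abs_threshold=0.0)
        assert len(detect_candidates(np.full((7, 20, 20), 5.0), cfg)) == 0

    def test_two_spots_two_candidates(self):
        spots = [GroundTruthSpot(15, 20, 7, 1.7, 1.1, 5000, (100, 0, 0, 0)),
                 GroundTruthSpot(35, 20, 7, 1.7, 1.1, 5000)]
        stack, _ = render_spot_stack(spots, SceneSpec(shape=(15, 40, 50)))
        cfg = DetectionConfig(abs_threshold=threshold_from_sd(stack, CFG, 5))
        assert len(detect_candidates(stack, cfg)) == 2


class TestEdgeBackground:
    def test_exact_plane_recovered(self):
        zz, yy, xx = np.meshgrid(np.arange(7), np.arange(11), np.arange(11),
                                 indexing="ij")
        roi = 5.0 + 0.2 * xx - 0.1 * yy + 0.3 * zz
        b, bx, by, bz = estimate_edge_background(roi)
        assert np.allclose([b, bx, by, bz], [5.0, 0.2, -0.1, 0.3], atol=1e-9)

    def test_constant_roi(self):
        assert estimate_edge_background(np.full((5, 5, 5), 3.0)) == (3.0, 0, 0, 0)

    def test_plane_with_centered_peak(self):
        zz, yy, xx = np.meshgrid(np.arange(7), np.arange(11), np.arange(11),
                                 indexing="ij")
        roi = 5.0 + 0.2 * xx - 0.1 * yy + 0.3 * zz
        # narrow peak whose mass never reaches the ROI faces
        roi += 500 * np.exp(-((xx - 5) ** 2 + (yy - 5) ** 2) / (2 * 0.8**2)
                            - (zz - 3) ** 2 / (2 * 0.6**2))
        b, bx, by, bz = estimate_edge_background(roi)
        assert np.allclose([b, bx, by, bz], [5.0, 0.2, -0.1, 0.3], atol=0.01)

    def test_too_small_roi_rejected(self):
        with pytest.raises(ValueError):
            estimate_edge_background(np.zeros((2, 5, 5)))


class TestRefineSpot:
    def test_noiseless_parameters_within_one_percent(self, single_spot_stack):
        stack, truth = single_spot_stack
        fit = refine_spot(stack, (round(truth.z0), round(truth.y0),
                                  round(truth.x0)), CFG)
        p = fit.params
        got = [p.I, p.x0, p.y0, p.z0, p.sigma_xy, p.sigma_z,
               p.b, p.bx, p.by, p.bz]
        want = [truth.total_intensity, truth.x0, truth.y0, truth.z0,
                truth.sigma_xy, truth.sigma_z, *truth.background]
        assert np.allclose(got, want, rtol=0.01)

    def test_bright_neighbor_does_not_steal_fit(self):
        dim = GroundTruthSpot(20, 20, 7, 1.7, 1.1, 3000, (100, 0, 0, 0))
        bright = GroundTruthSpot(28, 20, 7, 1.7, 1.1, 9000)
        stack, _ = render_spot_stack([dim, bright],
                                     SceneSpec(shape=(15, 40, 48)))
        fit = refine_spot(stack, (7, 20, 20), CFG)
        assert np.linalg.norm(fit.position - np.array([20, 20, 7])) <= 3.0

    def test_sigma_independent_of_intensity(self):
        # sigma constant across a 10x intensity span while I_p scales
        sigmas, ips = [], []
        for scale in (1, 2, 4, 7, 10):
            truth = GroundTruthSpot(20, 20, 7, 1.7, 1.1, 1000.0 * scale,
                                    (100, 0, 0, 0))
            stack, _ = render_spot_stack([truth], SceneSpec(shape=(15, 40, 40)))
            fit = refine_spot(stack, (7, 20, 20), CFG)
            sigmas.append(fit.params.sigma_xy)
            ips.append(fit.peak_intensity)
        sigmas, ips = np.array(sigmas), np.array(ips)
        assert sigmas.std() / sigmas.mean() < 0.05
        assert ips[-1] / ips[0] == pytest.approx(10.0, rel=0.05)

    def test_all_nonpositive_roi_marked_failed(self):
        fit = refine_spot(np.full((15, 40, 40), -5.0), (7, 20, 20), CFG)
        assert fit.failed

    def test_candidate_outside_stack_rejected(self):
        with pytest.raises(ValueError):
            refine_spot(np.zeros((5, 10, 10)), (9, 5, 5), CFG)


class TestPeakIntensity:
    def test_zero_intensity(self):
        p = SpotModelParams(I=0.0, x0=0, y0=0, z0=0, sigma_xy=1.0, sigma_z=1.0)
        assert peak_intensity(p) == 0.0

    def test_unit_denominator(self):
        s = (2 * np.pi) ** -0.5
        p = SpotModelParams(I=1.0, x0=0, y0=0, z0=0, sigma_xy=s, sigma_z=s)
        assert peak_intensity(p) == pytest.approx(1.0, rel=1e-12)

    def test_equals_model_height_above_background(self):
        # oracle: evaluate G at the center and subtract the plane there
        p = SpotModelParams(I=4321.0, x0=12.3, y0=9.9, z0=5.1, sigma_xy=1.6,
                            sigma_z=1.2, b=80.0, bx=0.3, by=-0.2, bz=0.1)
        spot = GroundTruthSpot(p.x0, p.y0, p.z0, p.sigma_xy, p.sigma_z, p.I,
                               (p.b, p.bx, p.by, p.bz))
        height = (gaussian_spot_value(spot, p.x0, p.y0, p.z0)
                  - (p.b + p.bx * p.x0 + p.by * p.y0 + p.bz * p.z0))
        assert peak_intensity(p) == pytest.approx(float(height), rel=1e-9)

    def test_recomputable_from_params(self, single_spot_stack):
        stack, truth = single_spot_stack
        fit = refine_spot(stack, (7, 18, 20), CFG)
        p = fit.params
        recomputed = p.I / (TWO_PI_32 * p.sigma_xy**2 * p.sigma_z)
        assert fit.peak_intensity == pytest.approx(recomputed, rel=1e-12)

    def test_nonpositive_sigma_rejected(self):
        p = SpotModelParams(I=1.0, x0=0, y0=0, z0=0, sigma_xy=1.0, sigma_z=1.0)
        p.sigma_z = 0.0
        with pytest.raises(ValueError):
            peak_intensity(p)


class TestGoodnessOfFit:
    def test_noiseless_model_r2_one(self, single_spot_stack):
        stack, truth = single_spot_stack
        fit = refine_spot(stack, (7, 18, 20), CFG)
        assert fit.r2_total == pytest.approx(1.0, abs=1e-6)

    def test_small_noise_high_r2(self, single_spot_stack):
        stack, truth = single_spot_stack
        rng = np.random.default_rng(5)
        peak = 5000 / (TWO_PI_32 * 1.7**2 * 1.1)
        noisy = stack + rng.normal(0, 0.01 * peak, stack.shape)
        fit = refine_spot(noisy, (7, 18, 20), CFG)
        assert fit.r2_total > 0.9

    def test_pure_noise_peak_r2_can_be_negative(self):
        # adjusted R^2 is not bounded below
        rng = np.random.default_rng(8)
        roi = np.abs(rng.normal(100, 5, (7, 11, 11)))
        p = SpotModelParams(I=1.0, x0=5, y0=5, z0=3, sigma_xy=1.5, sigma_z=1.0,
                            b=0.0)
        _, r2_peak, _ = goodness_of_fit(roi, p)
        assert r2_peak < 0

    def test_too_few_voxels_undefined(self):
        p = SpotModelParams(I=10.0, x0=1, y0=1, z0=1, sigma_xy=1.0, sigma_z=1.0)
        r2_total, _, _ = goodness_of_fit(np.ones((1, 3, 3)), p)
        assert np.isnan(r2_total)


def _fit_at(x, y, z, cand=None, r2_peak=0.5, I=1000.0):
    p = SpotModelParams(I=I, x0=x, y0=y, z0=z, sigma_xy=1.6, sigma_z=1.1)
    cand = cand or (x, y, z)
    return SpotFit(params=p, peak_intensity=peak_intensity(p), r2_total=0.9,
                   r2_peak=r2_peak, r2_background=0.5, candidate_xyz=cand,
                   n_iterations=3, converged=True)


class TestFilterSpots:
    def test_displaced_fit_removed(self):
        fits = filter_spots([_fit_at(10, 10, 5, cand=(14, 10, 5))])
        assert fits[0].reject_reason == "moved_from_candidate"

    def test_duplicates_keep_first(self):
        a, b = _fit_at(10, 10, 5), _fit_at(10.01, 10, 5)
        out = filter_spots([a, b])
        assert out[0].reject_reason == ""
        assert out[1].reject_reason == "duplicate"

    def test_r2_peak_threshold(self):
        out = filter_spots([_fit_at(10, 10, 5, r2_peak=-2.0),
                            _fit_at(20, 10, 5, r2_peak=-0.5)])
        assert out[0].reject_reason == "poor_peak_fit"
        assert out[1].reject_reason == ""

    def test_outside_cell_mask_removed(self):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[5:15, 5:15] = 2
        out = filter_spots([_fit_at(10, 10, 5), _fit_at(25, 25, 5)],
                           cells=labels)
        assert out[0].reject_reason == "" and out[0].cell_label == 2
        assert out[1].reject_reason == "outside_cells"

    def test_idempotent(self):
        fits = [_fit_at(10, 10, 5), _fit_at(10.01, 10, 5),
                _fit_at(20, 20, 5, r2_peak=-3)]
        once = filter_spots(fits)
        twice = filter_spots(once)
        assert [f.reject_reason for f in once] == [f.reject_reason for f in twice]
        assert [tuple(f.position) for f in kept(once)] == \
               [tuple(f.position) for f in kept(twice)]


class TestRecoveryUnderNoise:
    def test_median_errors_with_poisson_noise(self):
        # peak SNR >= 10: median sigma error < 5%, median centroid error < 0.15 vx
        rng = np.random.default_rng(42)
        sig_errs, cen_errs = [], []
        for i in range(60):
            truth = random_spot(rng)
            scene = SceneSpec(shape=(15, 40, 40), noise_model="poisson",
                              gain=1.0, noise_sd=0.0, seed=1000 + i)
            stack, _ = render_spot_stack([truth], scene)
            fit = refine_spot(stack, (round(truth.z0), round(truth.y0),
                                      round(truth.x0)), CFG)
            if fit.failed:
                continue
            sig_errs.append(abs(fit.params.sigma_xy - truth.sigma_xy)
                            / truth.sigma_xy)
            cen_errs.append(np.linalg.norm(
                fit.position - [truth.x0, truth.y0, truth.z0]))
        assert np.median(sig_errs) < 0.05
        assert np.median(cen_errs) < 0.15

    def test_false_positive_rate_on_pure_background(self):
        # threshold at 5x noise SD on spotless stacks
        n_spots = 0
        for i in range(10):
            scene = SceneSpec(shape=(15, 64, 64), noise_model="gaussian",
                              noise_sd=10.0, seed=2000 + i)
            stack, _ = render_spot_stack(
                [], SceneSpec(shape=(15, 64, 64)))
            rng = np.random.default_rng(2000 + i)
            stack = 100.0 + rng.normal(0, 10.0, stack.shape)
            cfg = DetectionConfig(abs_threshold=threshold_from_sd(stack, CFG, 5))
            cands = detect_candidates(stack, cfg)
            fits = kept(filter_spots(
                [refine_spot(stack, c, CFG) for c in cands], cfg=CFG))
            n_spots += len(fits)
        assert n_spots / 10 < 1.0
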