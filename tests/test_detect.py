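"""The gradient-coil-noise detector: unit, oracle and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coilqc.detect import (
    DetectionParams,
    SliceIntensityMatrix,
    compute_background_intensity,
    default_threshold_grid,
    detect,
    detect_slice,
    evaluate_against_truth,
    suggest_threshold,
    threshold_sweep,
)
from coilqc.io import BackgroundMask, Scan4D
from coilqc.phantom import NoiseGroundTruth

from conftest import brute_force_detect_slice


class TestBackgroundIntensity:
    def test_uniform_background(self):
        vox = np.full((4, 4, 2, 3), 10.0)
        mask = BackgroundMask(np.ones((4, 4, 2), bool))
        I = compute_background_intensity(Scan4D(vox, 2.5), mask)
        np.testing.assert_array_equal(I.I, np.full((2, 3), 10.0))

    def test_mean_of_two_voxels(self):
        vox = np.zeros((2, 1, 1, 1))
        vox[0, 0, 0, 0] = 8.0
        vox[1, 0, 0, 0] = 12.0
        mask = BackgroundMask(np.ones((2, 1, 1), bool))
        I = compute_background_intensity(Scan4D(vox, 2.5), mask)
        assert I.I[0, 0] == pytest.approx(10.0)

    def test_empty_slice_names_the_slice(self):
        vox = np.zeros((2, 2, 3, 2))
        mask = np.ones((2, 2, 3), bool)
        mask[:, :, 1] = False
        with pytest.raises(ValueError, match="slice 1"):
            compute_background_intensity(Scan4D(vox, 2.5),
                                         BackgroundMask(mask))

    def test_recovers_injected_increment(self, small_phantom, small_spec):
        scan, mask, truth = small_phantom
        I = compute_background_intensity(scan, mask)
        m, n = np.argwhere(truth.noisy)[0]
        clean_baseline = I.I[m][~truth.noisy[m]].mean()
        n_bg = mask.voxels[:, :, m].sum()
        tol = 6 * small_spec.background_sd / np.sqrt(n_bg)
        assert I.I[m, n] == pytest.approx(clean_baseline + 15.0, abs=tol)


class TestDetectSlice:
    def test_hand_traced_jump_series(self):
        I = np.array([10.0, 10.1, 9.9, 10.0, 25.0, 25.1,
                      10.0, 10.1, 25.0, 10.0])
        state, flags = detect_slice(I, DetectionParams(3))
        np.testing.assert_array_equal(state.jump_volumes, [4, 8])
        assert state.min_noise == pytest.approx(25.0)
        assert state.i_bg == pytest.approx(10.0)
        np.testing.assert_array_equal(np.flatnonzero(flags), [4, 5, 8])

    def test_constant_series_is_clean(self):
        state, flags = detect_slice(np.full(8, 10.0), DetectionParams(3))
        assert state.jump_volumes.size == 0
        assert state.i_bg == pytest.approx(10.0)
        assert not flags.any()

    def test_noise_from_volume_zero_decaying(self):
        # only a negative jump: n_p empty, median fallback still flags
        # the initial noisy volumes
        I = np.array([25.0, 25, 25, 10, 10, 10, 10])
        state, flags = detect_slice(I, DetectionParams(3))
        assert state.jump_volumes.size == 0
        assert state.i_bg == pytest.approx(10.0)
        np.testing.assert_array_equal(np.flatnonzero(flags), [0, 1, 2])

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_slice(np.array([1.0]), DetectionParams(3))

    @given(st.lists(st.floats(min_value=0, max_value=100,
                              allow_nan=False, allow_infinity=False),
                    min_size=2, max_size=50),
           st.floats(min_value=0.1, max_value=20))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, series, thr):
        _, flags = detect_slice(np.array(series), DetectionParams(thr))
        assert list(flags) == brute_force_detect_slice(series, thr)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_clean_series_never_flagged(self, seed):
        # fluctuation range below thr/2 and no injections -> no flags
        rng = np.random.default_rng(seed)
        thr = 3.0
        base = rng.uniform(5, 50)
        series = base + rng.uniform(-thr / 4, thr / 4, size=30)
        _, flags = detect_slice(series, DetectionParams(thr))
        assert not flags.any()


class TestDetect:
    def test_all_clean_censors_nothing(self):
        I = SliceIntensityMatrix(np.full((3, 10), 7.0))
        res = detect(I, 3.0)
        assert not res.censor.flags.any()

    def test_any_rule_over_slices(self):
        M = np.full((4, 12), 10.0)
        M[2, 7] = 30.0  # one noisy slice at volume 7
        res = detect(SliceIntensityMatrix(M), 3.0)
        np.testing.assert_array_equal(np.flatnonzero(res.censor.flags), [7])
        assert res.censor.reasons == {7: "noise"}

    def test_phantom_recovery_exact(self, small_phantom):
        scan, mask, truth = small_phantom
        I = compute_background_intensity(scan, mask)
        res = detect(I, 3.0)
        np.testing.assert_array_equal(res.noisy, truth.noisy)

    def test_ibg_recovery(self, small_phantom, small_spec):
        scan, mask, truth = small_phantom
        I = compute_background_intensity(scan, mask)
        res = detect(I, 3.0)
        for m, state in enumerate(res.per_slice):
            clean = I.I[m][~truth.noisy[m]]
            if clean.size < I.n_volumes / 2:
                continue
            n_bg = mask.voxels[:, :, m].sum()
            tol = 3 * small_spec.background_sd / np.sqrt(n_bg)
            assert abs(state.i_bg - np.median(clean)) < tol


class TestThresholdSweep:
    def test_single_threshold_consistent_with_detect(self, small_phantom):
        scan, mask, _ = small_phantom
        I = compute_background_intensity(scan, mask)
        sw = threshold_sweep(I, [3.0])
        assert sw.counts[0] == detect(I, 3.0).censor.n_censored

    def test_noisy_phantom_plateaus_at_injected_count(self, small_phantom):
        scan, mask, truth = small_phantom
        I = compute_background_intensity(scan, mask)
        sw = threshold_sweep(I, default_threshold_grid())
        n_inj = int(truth.noisy_volumes.sum())
        # over the separation range (well above fluctuation, well below
        # the 15-unit increment) the count sits exactly at the injections
        sep = (sw.thresholds >= 2.0) & (sw.thresholds <= 10.0)
        assert np.all(sw.counts[sep] == n_inj)

    def test_unsorted_thresholds_rejected(self):
        I = SliceIntensityMatrix(np.zeros((2, 5)))
        with pytest.raises(ValueError):
            threshold_sweep(I, [3.0, 1.0])

    def test_default_grid_matches_sweep_range(self):
        grid = default_threshold_grid()
        assert grid[0] == pytest.approx(0.1)
        assert grid[-1] == pytest.approx(10.0)
        assert len(grid) == 100


class TestSuggestThreshold:
    def test_plateau_after_sharp_drop(self):
        from coilqc.detect import SweepResult
        sw = SweepResult(np.array([0.5, 1, 2, 3, 4, 5, 6]),
                         np.array([193, 193, 5, 0, 0, 0, 0]))
        thr, found = suggest_threshold(sw)
        assert found and thr == pytest.approx(3.0)

    def test_already_flat_returns_first(self):
        from coilqc.detect import SweepResult
        sw = SweepResult(np.array([1.0, 2, 3, 4]),
                         np.array([40, 40, 40, 40]))
        thr, found = suggest_threshold(sw)
        assert found and thr == pytest.approx(1.0)

    def test_no_plateau_falls_back_to_max(self):
        from coilqc.detect import SweepResult
        sw = SweepResult(np.array([1.0, 2, 3, 4, 5]),
                         np.array([50, 40, 30, 20, 10]))
        with pytest.warns(UserWarning, match="plateau"):
            thr, found = suggest_threshold(sw)
        assert not found and thr == pytest.approx(5.0)


class TestEvaluateAgainstTruth:
    def test_perfect_detection(self, small_phantom):
        scan, mask, truth = small_phantom
        I = compute_background_intensity(scan, mask)
        res = detect(I, 3.0)
        ev = evaluate_against_truth(res, truth)
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0

    def test_blind_detector_has_zero_sensitivity(self, small_phantom):
        scan, mask, truth = small_phantom
        I = compute_background_intensity(scan, mask)
        res = detect(I, 3.0)
        res.noisy[:] = False
        ev = evaluate_against_truth(res, truth)
        assert ev.sensitivity == 0.0

    def test_all_clean_truth_has_undefined_sensitivity(self):
        I = SliceIntensityMatrix(np.full((2, 6), 5.0))
        res = detect(I, 3.0)
        truth = NoiseGroundTruth(np.zeros((2, 6), bool), 0.0)
        ev = evaluate_against_truth(res, truth)
        assert ev.sensitivity is None
        assert ev.specificity == 1.0

    def test_separation_regime_auc_is_one(self, small_phantom):
        scan, mask, truth = small_phantom
        I = compute_background_intensity(scan, mask)
        sw = threshold_sweep(I, default_threshold_grid())
        res = detect(I, 3.0)
        ev = evaluate_against_truth(res, truth, sw)
        assert ev.auc == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        I = SliceIntensityMatrix(np.zeros((2, 6)))
        res = detect(I, 3.0)
        truth = NoiseGroundTruth(np.zeros((3, 6), bool), 0.0)
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_against_truth(res, truth)
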