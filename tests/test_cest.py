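"""Unit tests for the dynamic CEST quantification chain."""

import numpy as np
import pytest

from glucoflow import (
    CESTGroundTruth,
    CESTSeries,
    SaturationSchedule,
    UptakeCurve,
    center_kspace_saturation,
    compute_mtr,
    delta_mtr,
    drift_correct,
    phase_aucs,
    roi_timecourse,
    simulate_cest_session,
    uptake_auc,
)


def _uniform_curve(values, t0=0.0, t1=60.0):
    values = np.asarray(values, dtype=float)
    t = np.linspace(t0, t1, len(values))
    return UptakeCurve(values=values, times=t, offset=2.9, baseline_window=(-20.0, 0.0))


# ---------------------------------------------------------------------------
# schedule


class TestSchedule:
    def test_default_schedule_yields_48_samples_per_offset(self, schedule):
        assert schedule.samples_per_offset() == 48
        _, offsets, _ = schedule.frame_table()
        for off in schedule.offsets:
            assert np.isclose(offsets, off).sum() == 48

    def test_each_segment_bracketed_by_references(self, schedule):
        times, offsets, segs = schedule.frame_table()
        is_ref = np.isclose(offsets, schedule.reference_offset)
        for k in range(schedule.n_segments):
            seg_ref = is_ref[segs == k]
            assert seg_ref[0] and seg_ref[-1]
            assert seg_ref.sum() == 2

    def test_sample_times_strictly_increasing(self, schedule):
        times, _, _ = schedule.frame_table()
        assert np.all(np.diff(times) > 0)

    def test_baseline_precedes_injection(self, schedule):
        times, _, segs = schedule.frame_table()
        assert np.all(times[segs == 0] < 0)
        assert np.all(times[segs > 0] > 0)

    @pytest.mark.parametrize(
        "kwargs", [{"n_segments": 0}, {"offsets": ()}, {"segment_duration": -1.0}]
    )
    def test_invalid_schedule_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SaturationSchedule(**kwargs)

    def test_center_kspace_saturation_matches_hand_value(self, schedule):
        # 490 ms per line, 64-line matrix, center after 32 lines
        assert center_kspace_saturation(schedule) == pytest.approx(15.68)


# ---------------------------------------------------------------------------
# drift correction


class TestDriftCorrect:
    def test_constant_references_normalize_constant_signal(self, schedule):
        times, offsets, segs = schedule.frame_table()
        is_ref = np.isclose(offsets, schedule.reference_offset)
        r, s = 2.0, 1.5
        data = np.where(is_ref, r, s)[None, None, :] * np.ones((2, 2, 1))
        series = CESTSeries(data, times, offsets, segs, schedule)
        out = drift_correct(series)
        assert np.allclose(out.data, s / r)
        assert not out.is_reference().any()

    def test_linear_multiplicative_drift_removed_exactly(self, schedule):
        times, offsets, segs = schedule.frame_table()
        is_ref = np.isclose(offsets, schedule.reference_offset)
        drift = 1.0 + 0.004 * times
        c = 0.93
        data = (np.where(is_ref, drift, c * drift))[None, None, :].copy()
        series = CESTSeries(data, times, offsets, segs, schedule)
        out = drift_correct(series)
        assert np.max(np.abs(out.data - c)) < 1e-12

    def test_piecewise_linear_drift_distinct_slopes_removed(self, schedule):
        times, offsets, segs = schedule.frame_table()
        is_ref = np.isclose(offsets, schedule.reference_offset)
        slopes = [0.002, -0.003, 0.001, -0.0005]
        drift = np.empty_like(times)
        for k, b in enumerate(slopes):
            sel = segs == k
            drift[sel] = 1.0 + b * (times[sel] - times[sel][0])
        data = np.where(is_ref, drift, 0.9 * drift)[None, None, :].copy()
        out = drift_correct(CESTSeries(data, times, offsets, segs, schedule))
        for k in range(4):
            seg_vals = out.data[0, 0, out.frame_segments == k]
            assert np.max(np.abs(seg_vals - 0.9)) < 1e-12

    def test_missing_reference_frame_raises(self, schedule):
        times, offsets, segs = schedule.frame_table()
        offsets = offsets.copy()
        is_ref = np.isclose(offsets, schedule.reference_offset)
        offsets[np.flatnonzero(is_ref)[0]] = schedule.offsets[0]  # destroy one ref
        series = CESTSeries(np.ones((1, 1, len(times))), times, offsets, segs, schedule)
        with pytest.raises(ValueError, match="reference"):
            drift_correct(series)

    def test_nonpositive_reference_flags_voxel_invalid(self, schedule):
        times, offsets, segs = schedule.frame_table()
        is_ref = np.isclose(offsets, schedule.reference_offset)
        data = np.ones((2, 1, len(times)))
        data[1, 0, is_ref] = -1.0  # broken voxel
        out = drift_correct(CESTSeries(data, times, offsets, segs, schedule))
        assert out.valid_mask[0, 0] and not out.valid_mask[1, 0]


# ---------------------------------------------------------------------------
# MTR and delta-MTR


class TestMTR:
    @pytest.mark.parametrize("norm_value,expected", [(1.0, 0.0), (0.8, 0.2)])
    def test_mtr_definition(self, schedule, norm_value, expected):
        times, offsets, segs = schedule.frame_table()
        keep = ~np.isclose(offsets, schedule.reference_offset)
        series = CESTSeries(
            np.full((1, 1, keep.sum()), norm_value),
            times[keep], offsets[keep], segs[keep], schedule,
        )
        mtr = compute_mtr(series)
        for off in schedule.offsets:
            assert np.allclose(mtr.data[off], expected)

    def test_baseline_mtr_recovered_from_simulator(self):
        truth = CESTGroundTruth(noise_sd=0.0, baseline_mtr=0.05, uptake_amplitude=0.0)
        series, _ = simulate_cest_session(truth=truth, seed=0, grid_shape=(3, 3))
        mtr = compute_mtr(drift_correct(series))
        for off in series.schedule.offsets:
            assert np.allclose(mtr.data[off], 0.05)

    def test_constant_mtr_gives_zero_curve(self, clean_cest_session):
        series, truth = clean_cest_session
        # amplitude > 0 only post-injection; check baseline samples are 0-mean
        curve = delta_mtr(compute_mtr(drift_correct(series)))
        base = curve.values[..., curve.times < 0]
        assert np.allclose(base.mean(axis=-1), 0.0, atol=1e-14)

    def test_step_change_in_mtr_maps_to_delta(self, schedule):
        times, offsets, segs = schedule.frame_table()
        keep = ~np.isclose(offsets, schedule.reference_offset)
        t = times[keep]
        norm = np.where(t < 0, 1 - 0.05, 1 - 0.06)[None, None, :] * np.ones((1, 1, 1))
        series = CESTSeries(norm, t, offsets[keep], segs[keep], schedule)
        curve = delta_mtr(compute_mtr(series))
        assert np.allclose(curve.values[0, 0, curve.times > 0], 0.01)

    def test_empty_baseline_window_rejected(self, clean_cest_session):
        series, _ = clean_cest_session
        mtr = compute_mtr(drift_correct(series))
        with pytest.raises(ValueError):
            delta_mtr(mtr, baseline_window=(-0.01, 0.0))

    def test_offset_independence(self, clean_cest_session):
        """Processing at 2.9 ppm ignores values at the other offsets."""
        series, _ = clean_cest_session
        perturbed = CESTSeries(
            series.data.copy(), series.frame_times, series.frame_offsets,
            series.frame_segments, series.schedule,
        )
        other = np.isclose(perturbed.frame_offsets, 1.2) | np.isclose(
            perturbed.frame_offsets, 2.0
        )
        perturbed.data[..., other] *= 5.0
        c0 = delta_mtr(compute_mtr(drift_correct(series)), offset=2.9)
        c1 = delta_mtr(compute_mtr(drift_correct(perturbed)), offset=2.9)
        assert np.array_equal(c0.values, c1.values)


# ---------------------------------------------------------------------------
# AUCs


class TestAUC:
    def test_constant_curve_hand_value(self):
        curve = _uniform_curve(np.full(61, 0.01))
        assert uptake_auc(curve, (0, 60)) == pytest.approx(0.6, abs=1e-15)

    def test_zero_curve_zero_auc(self):
        curve = _uniform_curve(np.zeros(61))
        assert uptake_auc(curve, (0, 60)) == 0.0

    def test_triangular_curve_hand_trapezoid(self):
        t = np.linspace(0, 60, 61)
        vals = np.where(t <= 30, 0.02 * t / 30, 0.02 * (60 - t) / 30)
        curve = _uniform_curve(vals)
        assert uptake_auc(curve, (0, 60)) == pytest.approx(0.6, rel=1e-12)

    def test_window_outside_range_rejected(self):
        curve = _uniform_curve(np.ones(61))
        with pytest.raises(ValueError):
            uptake_auc(curve, (0, 120), snap_to_samples=False)

    def test_constant_curve_equal_phases(self):
        curve = _uniform_curve(np.full(61, 0.03))
        s = phase_aucs(curve)
        assert s.auc_initial == pytest.approx(s.auc_total / 3)
        assert s.auc_peak == pytest.approx(s.auc_total / 3)
        assert s.auc_washout == pytest.approx(s.auc_total / 3)

    def test_phases_partition_total_on_simulator_grid(self):
        truth = CESTGroundTruth(noise_sd=0.01)
        series, _ = simulate_cest_session(truth=truth, seed=5, grid_shape=(2, 2))
        curve = delta_mtr(compute_mtr(drift_correct(series)))
        c = UptakeCurve(
            values=curve.values[0, 0], times=curve.times, offset=2.9,
            baseline_window=curve.baseline_window,
        )
        s = phase_aucs(c)
        assert s.auc_total == pytest.approx(
            s.auc_initial + s.auc_peak + s.auc_washout, abs=1e-12
        )

    def test_gamma_variate_peaking_mid_hour_has_largest_peak_phase(self):
        # defaults place the uptake peak near 25 min post-injection
        truth = CESTGroundTruth(noise_sd=0.0)
        series, gt = simulate_cest_session(truth=truth, seed=0, grid_shape=(2, 2))
        curve = delta_mtr(compute_mtr(drift_correct(series)))
        c = UptakeCurve(
            values=curve.values[0, 0], times=curve.times, offset=2.9,
            baseline_window=curve.baseline_window,
        )
        s = phase_aucs(c)
        assert s.auc_peak > s.auc_initial and s.auc_peak > s.auc_washout

    def test_noise_free_recovery_matches_generating_curve_trapezoid(self):
        """Quantified AUC equals the trapezoid of the generating curve."""
        truth = CESTGroundTruth(noise_sd=0.0, drift_slope=-0.001)
        series, gt = simulate_cest_session(truth=truth, seed=0, grid_shape=(2, 2))
        curve = delta_mtr(compute_mtr(drift_correct(series)))
        t = curve.times
        auc = uptake_auc(
            UptakeCurve(curve.values[0, 0], t, 2.9, curve.baseline_window), (0, 60)
        )
        lo = t[np.argmin(np.abs(t - 0))]
        hi = t[np.argmin(np.abs(t - 60))]
        sel = (t >= lo) & (t <= hi)
        oracle = np.trapezoid(gt.delta_mtr_true(t[sel]), t[sel])
        assert auc == pytest.approx(oracle, abs=1e-14)

    def test_noisy_roi_curve_tracks_generating_curve(self):
        """ROI-averaged noisy curve within 3 propagated SEs of truth."""
        truth = CESTGroundTruth(noise_sd=0.005)
        series, gt = simulate_cest_session(truth=truth, seed=11, grid_shape=(16, 16))
        curve = delta_mtr(compute_mtr(drift_correct(series)))
        mean, sem = roi_timecourse(curve.values, np.ones((16, 16), bool))
        expected = gt.delta_mtr_true(curve.times)
        # SEM of a noisy ratio is approximately the sample SEM; allow 5 SEs
        # at any single point but require 3 SEs on 95% of points
        z = np.abs(mean - expected) / np.maximum(sem, 1e-12)
        assert np.mean(z < 3) > 0.9


# ---------------------------------------------------------------------------
# ROI statistics


class TestROITimecourse:
    def test_single_voxel_sem_zero(self):
        vals = np.arange(12.0).reshape(1, 1, 12)
        mask = np.ones((1, 1), bool)
        mean, sem = roi_timecourse(vals, mask)
        assert np.array_equal(mean, vals[0, 0])
        assert np.all(sem == 0)

    def test_uniform_image_sem_zero(self):
        vals = np.ones((4, 4, 5)) * 2.5
        mean, sem = roi_timecourse(vals, np.ones((4, 4), bool))
        assert np.allclose(mean, 2.5) and np.allclose(sem, 0.0)

    def test_two_voxel_hand_computation(self):
        vals = np.zeros((1, 2, 1))
        a, b = 1.0, 4.0
        vals[0, 0, 0], vals[0, 1, 0] = a, b
        mean, sem = roi_timecourse(vals, np.ones((1, 2), bool))
        assert mean[0] == pytest.approx((a + b) / 2)
        assert sem[0] == pytest.approx(abs(a - b) / 2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            roi_timecourse(np.ones((2, 2, 3)), np.zeros((2, 2), bool))

    def test_invalid_voxels_excluded(self):
        vals = np.ones((1, 2, 3))
        vals[0, 1] = 100.0
        valid = np.array([[True, False]])
        mean, _ = roi_timecourse(vals, np.ones((1, 2), bool), valid)
        assert np.allclose(mean, 1.0)
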