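import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flexitorque import (
    CalibrationCoverageError,
    OutOfRangeError,
    ParameterError,
    ProtocolError,
    ProtocolConfig,
    RectificationError,
    SegmentationError,
    TrialRecording,
    calibrate_connatural,
    compute_strain,
    connatural_circumference,
    extract_strain,
    flexion_end_circumference,
    normalize_strain,
    rectify_circumference,
    segment_flexions,
    select_flexion,
    simulate_isokinetic_trial,
    simulate_passive_trial,
    strain_profile,
)
from flexitorque.preprocess import ConnaturalProfile

from conftest import make_quiet


class TestCalibrate:
    def test_noiseless_round_trip(self, quiet_subject, quiet_profile):
        theta = np.linspace(30, 120, 181)
        assert np.allclose(quiet_profile(theta),
                           connatural_circumference(quiet_subject, theta),
                           atol=1e-9)

    def test_two_identical_trials_same_as_one(self, quiet_subject, passive_protocol):
        trial = simulate_passive_trial(quiet_subject, passive_protocol)
        one = calibrate_connatural([trial])
        two = calibrate_connatural([trial, trial])
        assert np.allclose(one.angle, two.angle, rtol=1e-13)
        assert np.allclose(one.c0, two.c0, rtol=1e-13)

    def test_bin_error_shrinks_like_sqrt_n(self, subject):
        # Monte-Carlo: averaging 9x more passive sweeps cuts the profile
        # error by about 3x
        def profile_rmse(n_trials, seed0):
            trials = [simulate_passive_trial(
                subject, ProtocolConfig("passive", velocity=90.0, n_cycles=2,
                                        seed=seed0 + i))
                for i in range(n_trials)]
            prof = calibrate_connatural(trials)
            theta = np.linspace(31, 119, 89)
            err = prof(theta) - connatural_circumference(subject, theta)
            return np.sqrt(np.mean(err ** 2))

        r1 = np.mean([profile_rmse(1, 100 * k) for k in range(8)])
        r9 = np.mean([profile_rmse(9, 100 * k + 1000) for k in range(8)])
        assert 1.8 < r1 / r9 < 4.5

    def test_coverage_gap_detected(self, subject):
        proto = ProtocolConfig("passive", velocity=90.0, seed=1)
        t = np.arange(200) / 100.0
        angle = np.clip(30 + 45 * t, 30, 80)  # never reaches the upper ROM
        trial = TrialRecording(t, angle, np.zeros(200),
                              np.full(200, 280.0), proto)
        with pytest.raises(CalibrationCoverageError):
            calibrate_connatural([trial])

    def test_non_passive_rejected(self, subject, isokinetic_protocol):
        trial = simulate_isokinetic_trial(subject, isokinetic_protocol)
        with pytest.raises(ProtocolError):
            calibrate_connatural([trial])

    def test_profile_invariants(self, quiet_profile):
        assert np.all(np.diff(quiet_profile.angle) > 0)
        assert np.all(quiet_profile.c0 > 0)
        with pytest.raises(OutOfRangeError):
            quiet_profile(125.0)


class TestSegmentation:
    def test_four_cycles_give_four_flexions(self, subject, isokinetic_protocol):
        trial = simulate_isokinetic_trial(subject, isokinetic_protocol)
        assert len(segment_flexions(trial)) == 4

    def test_extension_only_fails(self, subject):
        proto = ProtocolConfig("passive", velocity=90.0, seed=1)
        t = np.arange(101) / 100.0
        angle = 120.0 - 90.0 * t  # single monotone extension
        trial = TrialRecording(t, angle, np.zeros(101), np.full(101, 280.0), proto)
        with pytest.raises(SegmentationError):
            segment_flexions(trial)

    def test_boundaries_match_extrema_oracle(self, quiet_trial):
        # noiseless triangular wave at 90 deg/s, 100 Hz: vertices every 100
        # samples, flexion k spans [200k, 200k + 100]
        segments = segment_flexions(quiet_trial)
        expected = [(200 * k, 200 * k + 101) for k in range(4)]
        assert [(s.start, s.stop) for s in segments] == expected
        for seg in segments:
            assert quiet_trial.angle[seg.start] == 30.0
            assert quiet_trial.angle[seg.stop - 1] == 120.0

    def test_select_second_by_default(self, quiet_trial):
        segments = segment_flexions(quiet_trial)
        assert select_flexion(segments).cycle == 2
        assert select_flexion(segments, 4).cycle == 4

    def test_select_too_many(self, quiet_trial):
        segments = segment_flexions(quiet_trial)
        with pytest.raises(SegmentationError):
            select_flexion(segments, 5)

    def test_noisy_segmentation_close_to_oracle(self, subject, isokinetic_protocol):
        trial = simulate_isokinetic_trial(subject, isokinetic_protocol)
        segments = segment_flexions(trial)
        for seg, start in zip(segments, (0, 200, 400, 600)):
            assert abs(seg.start - start) <= 5
            assert abs(seg.stop - (start + 101)) <= 5


class TestRectification:
    def test_endpoint_identities_exact(self, quiet_trial, quiet_profile):
        segments = segment_flexions(quiet_trial)
        seg = select_flexion(segments, 2)
        cbar = flexion_end_circumference(segments, window_deg=0.0)
        rect = rectify_circumference(seg, quiet_profile, cbar120=cbar,
                                     window_deg=0.0)
        c0_30 = quiet_profile(30.0)
        assert rect[0] == c0_30            # exact endpoint identity
        assert rect[-1] == cbar            # exact endpoint identity

    def test_additive_offset_invariance_bitwise(self, quiet_subject,
                                                quiet_trial, quiet_profile):
        # circumference values lie in [256, 512) mm, so adding the dyadic 5.0
        # is exact in float64 and the offset cancels bit-for-bit
        segments = segment_flexions(quiet_trial)
        seg = select_flexion(segments, 2)
        cbar = flexion_end_circumference(segments, window_deg=0.0)
        rect = rectify_circumference(seg, quiet_profile, cbar120=cbar,
                                     window_deg=0.0)
        shifted = TrialRecording(quiet_trial.time, quiet_trial.angle,
                                 quiet_trial.torque,
                                 quiet_trial.circumference + 5.0,
                                 quiet_trial.protocol)
        seg2 = select_flexion(segment_flexions(shifted), 2)
        rect2 = rectify_circumference(seg2, quiet_profile, cbar120=cbar,
                                      window_deg=0.0)
        assert np.array_equal(rect, rect2)

    @given(offset=st.floats(-20, 20, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_additive_offset_invariance_property(self, offset):
        subject = make_quiet(3)
        trial = simulate_isokinetic_trial(
            subject, ProtocolConfig("isokinetic", velocity=90.0, seed=5))
        profile = calibrate_connatural([simulate_passive_trial(
            subject, ProtocolConfig("passive", velocity=90.0, n_cycles=2, seed=6))])
        segments = segment_flexions(trial)
        cbar = flexion_end_circumference(segments)
        rect = rectify_circumference(select_flexion(segments, 2), profile,
                                     cbar120=cbar)
        shifted = TrialRecording(trial.time, trial.angle, trial.torque,
                                 trial.circumference + offset, trial.protocol)
        rect2 = rectify_circumference(select_flexion(segment_flexions(shifted), 2),
                                      profile, cbar120=cbar)
        assert np.allclose(rect, rect2, atol=1e-8)

    def test_flat_signal_rejected(self, quiet_profile, isokinetic_protocol):
        t = np.arange(401) / 100.0
        phase = np.mod(t, 2.0)
        angle = np.where(phase <= 1.0, 30 + 90 * phase, 120 - 90 * (phase - 1.0))
        trial = TrialRecording(t, angle, np.zeros(401), np.full(401, 280.0),
                               isokinetic_protocol)
        seg = select_flexion(segment_flexions(trial), 2)
        with pytest.raises(RectificationError):
            rectify_circumference(seg, quiet_profile)

    def test_drift_removed_within_tolerance(self):
        base = make_quiet(9)
        drifting = make_quiet(9, drift_amp=1.0, drift_tau=60.0)
        proto = ProtocolConfig("isokinetic", velocity=90.0, seed=7)
        rects = []
        for sub in (base, drifting):
            trial = simulate_isokinetic_trial(sub, proto)
            profile = calibrate_connatural([simulate_passive_trial(
                sub, ProtocolConfig("passive", velocity=90.0, n_cycles=2, seed=8))])
            segments = segment_flexions(trial)
            rects.append(rectify_circumference(select_flexion(segments, 2),
                                               profile, segments=segments))
        # residual is bounded by the drift spread across the trial's
        # flexion-to-extension turnarounds, a small fraction of the raw drift
        assert np.max(np.abs(rects[0] - rects[1])) < 0.25


class TestStrain:
    def test_zero_when_rectified_equals_profile(self, quiet_profile):
        theta = np.linspace(30, 120, 91)
        series = compute_strain(theta, quiet_profile(theta), quiet_profile)
        assert np.allclose(series.strain, 0.0)

    def test_ten_percent_case(self, quiet_profile):
        theta = np.array([60.0, 75.0])
        series = compute_strain(theta, 1.1 * quiet_profile(theta), quiet_profile)
        assert np.allclose(series.strain, 0.1, rtol=1e-12)

    def test_out_of_range_rejected(self, quiet_profile):
        with pytest.raises(OutOfRangeError):
            compute_strain(np.array([125.0]), np.array([300.0]), quiet_profile)

    def test_noiseless_round_trip_recovers_ground_truth(
            self, quiet_subject, quiet_trial, quiet_profile):
        segments = segment_flexions(quiet_trial)
        seg = select_flexion(segments, 2)
        series = extract_strain(quiet_trial, quiet_profile, window_deg=0.0)
        truth = quiet_trial.ground_truth["strain"][seg.indices]
        assert np.allclose(series.strain, truth, atol=1e-9)

    def test_recovery_error_vanishes_with_noise(self):
        # strain recovery error goes to zero with the noise and drift scales
        errs = []
        for scale in (1.0, 0.25, 0.0):
            sub = make_quiet(13, noise_torque_sd=0.3 * scale,
                             noise_circ_sd=0.15 * scale, drift_amp=1.0 * scale)
            trial = simulate_isokinetic_trial(
                sub, ProtocolConfig("isokinetic", velocity=90.0, seed=17))
            profile = calibrate_connatural([simulate_passive_trial(
                sub, ProtocolConfig("passive", velocity=90.0, n_cycles=2, seed=18))])
            segments = segment_flexions(trial)
            seg = select_flexion(segments, 2)
            series = extract_strain(trial, profile, segments=segments)
            truth = trial.ground_truth["strain"][seg.indices]
            errs.append(np.sqrt(np.mean((series.strain - truth) ** 2)))
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 1e-3

    def test_passive_strain_zero_mean(self, subject, passive_protocol):
        trial = simulate_passive_trial(subject, passive_protocol)
        profile = calibrate_connatural([trial])
        series = extract_strain(trial, profile, flexion_index=1)
        assert abs(np.mean(series.strain)) < 5e-4


class TestNormalizeStrain:
    def test_beta_one_at_s_max(self, quiet_profile):
        theta = np.linspace(40, 110, 20)
        series = compute_strain(theta, 1.05 * quiet_profile(theta), quiet_profile)
        series.strain[:] = 0.12
        beta = normalize_strain(series, 0.12)
        assert np.allclose(beta, 1.0)

    def test_beta_zero_at_rest(self, quiet_profile):
        theta = np.linspace(40, 110, 20)
        series = compute_strain(theta, quiet_profile(theta), quiet_profile)
        beta = normalize_strain(series, 0.12)
        assert np.allclose(beta, 0.0)

    def test_nonpositive_smax_rejected(self, quiet_profile):
        theta = np.linspace(40, 110, 20)
        series = compute_strain(theta, quiet_profile(theta), quiet_profile)
        with pytest.raises(ParameterError):
            normalize_strain(series, 0.0)

    def test_peak_beta_near_one_from_simulator(self, quiet_subject,
                                               quiet_trial, quiet_profile):
        series = extract_strain(quiet_trial, quiet_profile, window_deg=0.0)
        beta = normalize_strain(
            series, lambda th: strain_profile(quiet_subject, th) + 1e-9)
        sel = series.strain > 0.01
        assert np.max(beta[sel]) == pytest.approx(1.0, abs=1e-3)
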