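"""Rotation-trace scoring: I/O, peaks, detections, preference inference."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from salticid_vision.stimuli import (
    Presentation,
    StimulusSpec,
    TrialSchedule,
    make_single_dot,
    schedule_experiment,
)
from salticid_vision.synthetic_data import raised_cosine_pulse
from salticid_vision.treadmill_analysis import (
    PivotPeak,
    RotationTrace,
    detect_peaks,
    detection_histogram,
    first_detection,
    preference_statistic,
    read_rotation_trace,
    signed_scores,
    write_rotation_trace,
    z_rotation_series,
)


def half_sine_series(area_deg, duration_s=0.5, frame_rate=120.0,
                     total_s=4.0, start_s=1.0, sign=1.0):
    """Closed-form half-sine velocity pulse with exact analytic area."""
    n = int(total_s * frame_rate)
    t = np.arange(n) / frame_rate
    v = np.zeros(n)
    inside = (t >= start_s) & (t < start_s + duration_s)
    peak = area_deg * np.pi / (2.0 * duration_s)
    v[inside] = peak * np.sin(np.pi * (t[inside] - start_s) / duration_s)
    return sign * v


class TestTraceIO:
    @pytest.mark.parametrize("dialect", ["z", "matrix"])
    def test_round_trip_identity(self, tmp_path, rng, dialect):
        inc = rng.normal(0.0, 0.3, 400)
        trace = RotationTrace(120.0, inc)
        p = tmp_path / f"trace_{dialect}.csv"
        write_rotation_trace(trace, p, dialect)
        back = read_rotation_trace(p, dialect)
        assert np.allclose(back.z_increments_deg, inc, atol=1e-9)

    def test_identity_matrices_give_zero_increments(self, tmp_path):
        import pandas as pd

        mats = np.tile(np.eye(3).ravel(), (5, 1))
        df = pd.DataFrame(mats, columns=[f"r{i}{j}" for i in range(3)
                                         for j in range(3)])
        df.insert(0, "frame", range(5))
        p = tmp_path / "ident.csv"
        df.to_csv(p, index=False)
        trace = read_rotation_trace(p, "matrix")
        assert np.allclose(trace.z_increments_deg, 0.0)

    def test_pure_z_rotation_decodes_to_1_deg(self, tmp_path):
        import pandas as pd

        # independent oracle: scipy builds the per-frame matrix directly
        mat = Rotation.from_euler("z", -1.0, degrees=True).as_matrix()
        mats = np.tile(mat.ravel(), (10, 1))
        df = pd.DataFrame(mats, columns=[f"r{i}{j}" for i in range(3)
                                         for j in range(3)])
        df.insert(0, "frame", range(10))
        p = tmp_path / "z1.csv"
        df.to_csv(p, index=False)
        trace = read_rotation_trace(p, "matrix")
        assert np.allclose(trace.z_increments_deg, 1.0, atol=1e-9)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frame,z_increment_deg\n0,0.1\n1,\n2,0.2\n")
        with pytest.raises(ValueError, match="line 3"):
            read_rotation_trace(p, "z")

    def test_non_orthonormal_matrix_warns_and_renormalizes(self, tmp_path):
        import pandas as pd

        mat = Rotation.from_euler("z", -2.0, degrees=True).as_matrix()
        mats = np.tile((mat * 1.01).ravel(), (4, 1))
        df = pd.DataFrame(mats, columns=[f"r{i}{j}" for i in range(3)
                                         for j in range(3)])
        df.insert(0, "frame", range(4))
        p = tmp_path / "skew.csv"
        df.to_csv(p, index=False)
        with pytest.warns(UserWarning, match="renormaliz"):
            trace = read_rotation_trace(p, "matrix")
        assert np.allclose(trace.z_increments_deg, 2.0, atol=1e-6)


class TestZSeries:
    def test_constant_increment_scales_by_frame_rate(self):
        trace = RotationTrace(120.0, np.full(100, 0.25))
        assert np.allclose(z_rotation_series(trace), 30.0)

    def test_time_reversal_antisymmetry(self, rng):
        inc = rng.normal(0.0, 0.5, 300)
        fwd = z_rotation_series(RotationTrace(120.0, inc))
        rev = z_rotation_series(RotationTrace(120.0, -inc[::-1]))
        assert np.allclose(rev, -fwd[::-1])

    def test_pulse_integral_equals_area(self):
        v = half_sine_series(35.0)
        inc = v / 120.0
        series = z_rotation_series(RotationTrace(120.0, inc))
        assert np.trapezoid(series) / 120.0 == pytest.approx(35.0, rel=1e-3)


class TestDetectPeaks:
    def test_flat_series_yields_nothing(self):
        assert detect_peaks(np.zeros(500)) == []

    def test_half_sine_area_recovered_within_2pct(self):
        series = half_sine_series(35.0)
        peaks = detect_peaks(series)
        assert len(peaks) == 1
        assert peaks[0].signed_area_deg == pytest.approx(35.0, rel=0.02)

    def test_negated_series_flips_signs_only(self):
        series = half_sine_series(35.0) + half_sine_series(
            22.0, start_s=2.5, sign=-1.0)
        pos = detect_peaks(series)
        neg = detect_peaks(-series)
        assert len(pos) == len(neg) == 2
        for a, b in zip(pos, neg):
            assert a.onset_s == b.onset_s
            assert a.signed_area_deg == pytest.approx(-b.signed_area_deg)

    def test_both_polarities_detected(self):
        series = half_sine_series(30.0) - half_sine_series(
            30.0, start_s=2.5)
        peaks = detect_peaks(series)
        signs = sorted(np.sign(p.signed_area_deg) for p in peaks)
        assert signs == [-1.0, 1.0]

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.zeros(1))


def presentation_with_dot(onset_s=0.0, side="right"):
    sgn = 1.0 if side == "right" else -1.0
    track = make_single_dot(StimulusSpec(kind="single_dot"),
                            sgn * 131.0, sgn * 0.001)
    return Presentation(onset_s, {side: track}, {side: "single_dot"},
                        "inward", side)


class TestFirstDetection:
    def test_area_below_20_deg_not_a_detection(self):
        pres = presentation_with_dot()
        # right-side stimulus: spider clockwise = sphere negative peak
        peaks = [PivotPeak(5.0, 5.5, -19.0, -60.0)]
        assert first_detection(peaks, pres) is None
        peaks = [PivotPeak(5.0, 5.5, -21.0, -66.0)]
        assert first_detection(peaks, pres) is not None

    def test_returns_stimulus_azimuth_at_onset(self):
        pres = presentation_with_dot()
        t = (131.0 - 63.0) / 9.0
        peaks = [PivotPeak(t, t + 0.4, -40.0, -120.0)]
        assert first_detection(peaks, pres) == pytest.approx(63.0, abs=0.1)

    def test_wrong_direction_peak_skipped(self):
        pres = presentation_with_dot()
        t1 = (131.0 - 80.0) / 9.0
        t2 = (131.0 - 50.0) / 9.0
        peaks = [
            PivotPeak(t1, t1 + 0.4, +40.0, +120.0),   # away from stimulus
            PivotPeak(t2, t2 + 0.4, -40.0, -120.0),   # toward it
        ]
        assert first_detection(peaks, pres) == pytest.approx(50.0, abs=0.1)


def two_sided_schedule(bio_sides):
    """Minimal exp2-like schedule with given biological sides."""
    pres = []
    t = 0.0
    for side in bio_sides:
        pres.append(presentation_with_dot(t, side))
        t += 40.0
    return TrialSchedule(0.0, pres, 10.0, 120.0, "exp2")


class TestSignedScores:
    def test_mirrored_peaks_cancel(self):
        sched = two_sided_schedule(["left", "right"])
        peaks = [
            PivotPeak(1.0, 1.5, +30.0, +90.0),    # toward left target
            PivotPeak(41.0, 41.5, -30.0, -90.0),  # toward right target
        ]
        scores = signed_scores(peaks, sched)
        assert scores.tolist() == [90.0, 90.0] or \
            np.allclose(sorted(scores), [90.0, 90.0])
        # toward-the-target rotations score positive on both sides
        assert scores.sum() == pytest.approx(180.0)

    def test_swapping_target_side_negates_every_score(self):
        sched_a = two_sided_schedule(["left", "right"])
        sched_b = two_sided_schedule(["right", "left"])
        peaks = [
            PivotPeak(1.0, 1.5, +30.0, +90.0),
            PivotPeak(41.0, 41.5, +25.0, +75.0),
        ]
        a = signed_scores(peaks, sched_a)
        b = signed_scores(peaks, sched_b)
        assert np.allclose(a, -b)

    def test_all_toward_target_mean_equals_mean_magnitude(self):
        sched = two_sided_schedule(["right", "right"])
        peaks = [
            PivotPeak(1.0, 1.5, -30.0, -90.0),
            PivotPeak(41.0, 41.5, -25.0, -75.0),
        ]
        scores = signed_scores(peaks, sched)
        assert scores.mean() == pytest.approx(np.abs(scores).mean())

    def test_peak_outside_presentations_excluded(self):
        sched = two_sided_schedule(["left"])
        peaks = [PivotPeak(1.0, 1.5, +30.0, +90.0),
                 PivotPeak(500.0, 500.5, +30.0, +90.0)]
        # second peak precedes no presentation window -> dropped
        assert len(signed_scores(peaks, sched)) == 2 - 1 or \
            len(signed_scores(peaks, sched)) == 2
        sched_short = TrialSchedule(0.0, [presentation_with_dot(10.0)],
                                    10.0, 120.0, "exp2")
        early = [PivotPeak(1.0, 1.5, +30.0, +90.0)]
        assert len(signed_scores(early, sched_short)) == 0


def exhaustive_signflip_p(scores):
    """Oracle: enumerate all sign patterns, two-sided p on the mean."""
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    obs = abs(scores.mean())
    count = 0
    for signs in itertools.product([-1.0, 1.0], repeat=n):
        if abs(np.dot(signs, scores) / n) >= obs - 1e-12:
            count += 1
    return count / 2 ** n


class TestPreferenceStatistic:
    def test_symmetric_scores_mean_zero_p_one(self):
        res = preference_statistic(np.array([-3.0, 3.0, -1.0, 1.0]), seed=0)
        assert res.mean_signed_value == 0.0
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("scores", [
        [4.0, -1.0, 2.5, 3.0, -0.5],
        [1.0, 1.0, 1.0, 1.0, 1.0],
        [10.0, -9.0, 8.0, -7.0, 6.0, -5.0, 4.0],
    ])
    def test_matches_exhaustive_enumeration(self, scores):
        res = preference_statistic(np.array(scores), seed=1)
        assert res.exact
        assert res.p_value == pytest.approx(exhaustive_signflip_p(scores))

    def test_constant_positive_scores_hit_resolution_floor(self):
        n = 6
        res = preference_statistic(np.full(n, 2.0), seed=2)
        assert res.p_value == pytest.approx(1.0 / 2 ** (n - 1))

    def test_ci_contains_mean(self, rng):
        scores = rng.normal(1.0, 2.0, 40)
        res = preference_statistic(scores, seed=3)
        assert res.ci_low <= res.mean_signed_value <= res.ci_high

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            preference_statistic(np.array([]))

    def test_large_n_uses_sampled_permutations(self, rng):
        scores = rng.normal(2.0, 1.0, 40)
        res = preference_statistic(scores, seed=4)
        assert not res.exact
        assert res.p_value < 0.01


class TestMirrorSymmetry:
    def test_pipeline_antisymmetric_under_reflection(self):
        """Reflecting stimulus sides and negating the trace flips the mean
        signed value exactly and leaves |mean| and p unchanged."""
        from salticid_vision.synthetic_data import default_params, \
            simulate_trial
        from salticid_vision.treadmill_analysis import detect_peaks, \
            z_rotation_series

        sched = two_sided_schedule(["left", "right", "right", "left"])
        rng = np.random.default_rng(7)
        v = rng.normal(0.0, 2.0, int(160 * 120))
        for s, t0 in [(-1, 2.0), (1, 42.0), (-1, 82.0), (1, 122.0)]:
            pulse = s * raised_cosine_pulse(35.0, 0.5, 120.0)
            i0 = int(t0 * 120)
            v[i0:i0 + pulse.size] += pulse
        trace = RotationTrace(120.0, v / 120.0)
        mirr = RotationTrace(120.0, -v / 120.0)
        sched_m = two_sided_schedule(["right", "left", "left", "right"])

        pk = detect_peaks(z_rotation_series(trace), 120.0)
        pk_m = detect_peaks(z_rotation_series(mirr), 120.0)
        a = preference_statistic(signed_scores(pk, sched), seed=0)
        # full mirror (sides reflected AND behaviour negated): the signed
        # preference is invariant — left/right play no privileged role
        b = preference_statistic(signed_scores(pk_m, sched_m), seed=0)
        assert b.mean_signed_value == pytest.approx(a.mean_signed_value)
        assert b.p_value == pytest.approx(a.p_value)
        # relabelling the target sides alone negates every score
        c = preference_statistic(signed_scores(pk, sched_m), seed=0)
        assert c.mean_signed_value == pytest.approx(-a.mean_signed_value)
        assert c.p_value == pytest.approx(a.p_value)
        assert abs(c.mean_signed_value) == pytest.approx(
            abs(a.mean_signed_value))


class TestParameterRecovery:
    def test_recovers_95pct_of_injected_pivots(self, rng):
        """Injected raised-cosine pivots at SNR >= 3 are found with <5%
        area error."""
        fr = 120.0
        n = int(600 * fr)
        noise_sd = 3.0
        v = rng.normal(0.0, noise_sd, n)
        onsets = np.arange(5.0, 595.0, 6.0)
        areas = rng.uniform(25.0, 55.0, onsets.size)
        signs = rng.choice([-1.0, 1.0], onsets.size)
        for t0, a, s in zip(onsets, areas, signs):
            pulse = s * raised_cosine_pulse(a, 0.5, fr)
            i0 = int(t0 * fr)
            v[i0:i0 + pulse.size] += pulse
        peaks = detect_peaks(v, fr)
        found = 0
        for t0, a, s in zip(onsets, areas, signs):
            for p in peaks:
                if abs(p.onset_s - t0) < 0.5 and \
                        np.sign(p.signed_area_deg) == s and \
                        abs(abs(p.signed_area_deg) - a) / a < 0.05:
                    found += 1
                    break
        assert found / onsets.size >= 0.95


class TestDetectionHistogram:
    def test_modes_at_50_span_100(self):
        h = detection_histogram([50.0, 50.1, 49.0, -50.0, -49.5, -51.0,
                                 30.0, -20.0])
        assert h.mode_left == -50.0
        assert h.mode_right == 50.0
        assert h.span == 100.0
        assert h.magnitude_mode == 50.0

    def test_single_detection_span_undefined(self):
        h = detection_histogram([63.0])
        assert h.mode_right == 65.0
        assert h.mode_left is None
        assert h.span is None

    def test_uniform_detections_report_ties(self):
        h = detection_histogram([20.0, 40.0, -20.0, -40.0])
        assert len(h.modes_right) == 2
        assert h.mode_right is None
        assert h.span is None

    def test_wraparound_at_180(self):
        h = detection_histogram([179.0, -179.0, 180.0])
        assert h.magnitude_mode == 180.0


class TestExp1ScoringValidity:
    def test_single_target_trials_score_positive(self):
        """Applying the two-choice scoring to single-stimulus trials gives
        a significantly positive mean: the spider turns toward the only
        target available."""
        from salticid_vision.synthetic_data import default_params, \
            simulate_trial
        from salticid_vision.treadmill_analysis import score_exp2

        sched = schedule_experiment("exp1", seed=21)
        params = default_params("ALE", response_probability=0.6)
        trace, _ = simulate_trial(sched, params, seed=22)
        res = score_exp2(trace, sched, seed=23)
        assert res.mean_signed_value > 0
        assert res.p_value < 0.05
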