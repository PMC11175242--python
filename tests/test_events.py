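"""Pull onset, magnitude, step segmentation, trunk angle and recovery."""

import numpy as np
import pytest

from vpull.keypoints import KEYPOINT_INDEX, AnalysisConfig, Trajectory
from vpull.preprocess import ScalarSeries
from vpull.events import (
    NoPullDetectedError,
    PullEvent,
    Step,
    TrunkResponse,
    analyze_trial,
    detect_pull_onset,
    detect_steps,
    max_retropulsion,
    pull_magnitude,
    recovery_latency,
    trunk_angle_series,
)
from vpull.synthetic import (
    StepSpec,
    TrialParams,
    generate_trial,
    min_jerk_speed,
)

CFG = AnalysisConfig()
RATE = 30.0
DT = 1.0 / RATE


def gaussian_pulse_series(peak=3.0, sigma=0.06, t0=3.0, noise_sd=0.05, seed=0, n=300):
    """Resultant shoulder-acceleration series: quiet baseline plus one
    Gaussian pulse whose support starts at t0 (center t0 + 2σ)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / RATE
    acc = peak * np.exp(-((t - t0 - 2 * sigma) ** 2) / (2 * sigma**2))
    acc = np.abs(acc + rng.normal(0, noise_sd, n))
    return ScalarSeries(acc, RATE)


class TestPullOnset:
    def test_gaussian_pulse_onset_at_pulse_foot(self):
        """At low acceleration noise the last-local-minimum rule lands on
        the pulse foot. The pulse is indistinguishable from the noise
        minima (which lie near zero for a rectified noise floor) until
        3·exp(−u²/2) exceeds a few hundredths: u ≈ −3.4, about 0.08 s
        before the nominal support start at 3.0 s. Onset must therefore
        land in [support start − 4 frames, support start + 1 frame]."""
        for seed in range(10):
            s = gaussian_pulse_series(seed=seed)
            pull = detect_pull_onset(s, CFG)
            assert 3.0 - 4 * DT - 1e-9 <= pull.onset_time <= 3.0 + DT + 1e-9
            assert pull.onset_time <= pull.crossing_time

    def test_constant_zero_no_pull(self):
        s = ScalarSeries(np.zeros(300), RATE)
        with pytest.raises(NoPullDetectedError):
            detect_pull_onset(s, CFG)

    def test_monotone_ramp_fallback_to_crossing(self):
        """A ramp has no local minimum after the baseline, so onset falls
        back to the crossing time."""
        t = np.arange(300) / RATE
        ramp = np.where(t >= 1.0, 0.5 * (t - 1.0), 0.0)
        pull = detect_pull_onset(ScalarSeries(ramp, RATE), CFG)
        assert pull.onset_time == pull.crossing_time
        assert pull.crossing_time >= 1.0

    def test_threshold_is_baseline_mean_plus_3sd(self):
        s = gaussian_pulse_series(seed=3)
        pull = detect_pull_onset(s, CFG)
        base = s.values[:30]
        expect = base.mean() + 3 * base.std(ddof=1)
        assert pull.threshold_used == pytest.approx(expect, rel=1e-6)

    def test_onset_not_after_crossing_invariant(self):
        with pytest.raises(ValueError):
            PullEvent(onset_time=2.0, crossing_time=1.0, threshold_used=1.0)


class TestPullMagnitude:
    def test_filtered_gaussian_pulse_peak(self):
        """Noiseless Gaussian pulse with analytic peak 3.0 m/s² through the
        full pipeline. The expected attenuation is the product of three
        independently computed factors: zero-phase double-pass Butterworth
        response at the pulse bandwidth (~0.96), the iterated-gradient
        stencil response sin²(ω·dt)/(ω·dt)² (~0.93 at 30 Hz), and the
        braking-pulse overlap (~0.995) — reported peak in [2.55, 3.0]."""
        p = TrialParams(max_tilt=0.0, steps=(), pull_peak_acc=3.0, noise_sd=0.0)
        traj, _ = generate_trial(p)
        res = analyze_trial(traj, CFG)
        assert 2.55 <= res.pull.magnitude <= 3.0

    def test_window_rule_excludes_late_peak(self):
        """A larger peak outside the 1 s window after onset is ignored."""
        t = np.arange(300) / RATE
        acc = 3.0 * np.exp(-((t - 3.2) ** 2) / (2 * 0.06**2))
        acc += 5.0 * np.exp(-((t - 5.0) ** 2) / (2 * 0.06**2))
        rng = np.random.default_rng(0)
        s = ScalarSeries(np.abs(acc + rng.normal(0, 0.05, 300)), RATE)
        pull = detect_pull_onset(s, CFG)
        mag = pull_magnitude(s, pull, CFG)
        assert mag == pytest.approx(3.0, abs=0.3)

    def test_window_truncated_at_recording_end(self, caplog):
        t = np.arange(150) / RATE
        acc = 3.0 * np.exp(-((t - 4.7) ** 2) / (2 * 0.06**2))
        rng = np.random.default_rng(1)
        s = ScalarSeries(np.abs(acc + rng.normal(0, 0.05, 150)), RATE)
        pull = detect_pull_onset(s, CFG)
        with caplog.at_level("WARNING"):
            mag = pull_magnitude(s, pull, CFG)
        assert mag > 2.0
        assert "truncated" in caplog.text

    def test_healthy_cohort_magnitudes_plausible(self):
        """Healthy-profile trials yield mean measured pull magnitudes on the
        clinically reported scale (≈2.3–3.7 m/s²)."""
        from vpull.synthetic import cohort_generator

        mags = [
            analyze_trial(traj, CFG).pull.magnitude
            for traj, _ in cohort_generator("healthy", 20, seed=77)
        ]
        assert 2.3 <= np.mean(mags) <= 3.7


def minjerk_speed_series(L=0.32, T=0.4, start=3.5, n=300):
    t = np.arange(n) / RATE
    v = min_jerk_speed(L, T, t - start)
    return ScalarSeries(np.asarray(v), RATE)


def const_pos_series(n=300):
    pos = np.zeros((n, 3))
    return ScalarSeries(pos, RATE)


def minjerk_pos_series(L=0.32, T=0.4, start=3.5, n=300):
    from vpull.synthetic import min_jerk_displacement

    t = np.arange(n) / RATE
    pos = np.zeros((n, 3))
    pos[:, 2] = min_jerk_displacement(L, T, t - start)
    return ScalarSeries(pos, RATE)


PULL = PullEvent(onset_time=3.0, crossing_time=3.05, threshold_used=1.0)


class TestStepDetection:
    def test_single_minjerk_swing(self):
        """One backward swing (L=0.32 m, T=0.4 s, peak 1.5 m/s) gives one
        step whose boundaries match the analytic 0.7 m/s crossings and
        whose length matches the crossing-bounded analytic displacement."""
        vel = minjerk_speed_series()
        pos = minjerk_pos_series()
        quiet_v, quiet_p = ScalarSeries(np.zeros(300), RATE), const_pos_series()
        steps = detect_steps(vel, quiet_v, pos, quiet_p, PULL, CFG)
        assert len(steps) == 1
        st = steps[0]
        # analytic crossings of 30(L/T)(τ²-2τ³+τ⁴) = 0.7
        tau = np.linspace(0, 1, 2_000_001)
        v = 30 * (0.32 / 0.4) * (tau**2 - 2 * tau**3 + tau**4)
        above = v > 0.7
        t_start = 3.5 + 0.4 * tau[np.argmax(above)]
        t_end = 3.5 + 0.4 * tau[len(above) - 1 - np.argmax(above[::-1])]
        assert abs(st.start - t_start) <= DT
        assert abs(st.end - t_end) <= DT
        # step length is the displacement between the threshold crossings;
        # the analytic value L·(s(τ_hi) − s(τ_lo)) excludes the sub-threshold
        # tails of the minimum-jerk profile
        s_mj = lambda x: 10 * x**3 - 15 * x**4 + 6 * x**5
        tau_lo = (t_start - 3.5) / 0.4
        tau_hi = (t_end - 3.5) / 0.4
        expect = 0.32 * (s_mj(tau_hi) - s_mj(tau_lo))
        assert st.length == pytest.approx(expect, rel=0.02)
        assert st.side == "left"
        assert st.peak_velocity == pytest.approx(1.5, abs=0.01)

    def test_subthreshold_speed_no_steps(self):
        vel = minjerk_speed_series(L=0.1, T=0.4)  # peak 0.47 < 0.7
        steps = detect_steps(
            vel, ScalarSeries(np.zeros(300), RATE),
            minjerk_pos_series(L=0.1), const_pos_series(), PULL, CFG,
        )
        assert steps == []

    def test_merge_rule(self):
        """Two swings separated by a 0.5 s sub-threshold interval stay two
        steps; a 33 ms sub-threshold dip merges into one."""
        t = np.arange(300) / RATE
        far = np.asarray(min_jerk_speed(0.32, 0.4, t - 3.5)) + np.asarray(
            min_jerk_speed(0.32, 0.4, t - 4.4)
        )  # crossings ~[3.56,3.84] and [4.46,4.74]: gap ≈ 0.62 s
        pos = minjerk_pos_series()
        quiet = ScalarSeries(np.zeros(300), RATE)
        steps = detect_steps(
            ScalarSeries(far, RATE), quiet, pos, const_pos_series(), PULL, CFG
        )
        assert len(steps) == 2

        # rectangular profile with a one-frame dip: sub-threshold gap 1 sample
        rect = np.zeros(300)
        rect[105:111] = 1.2
        rect[111] = 0.1  # 33 ms dip
        rect[112:118] = 1.2
        steps = detect_steps(
            ScalarSeries(rect, RATE), quiet, pos, const_pos_series(), PULL, CFG
        )
        assert len(steps) == 1

    def test_min_duration_filter(self):
        spike = np.zeros(300)
        spike[120:122] = 1.5  # ~2 frames above threshold < 100 ms
        steps = detect_steps(
            ScalarSeries(spike, RATE), ScalarSeries(np.zeros(300), RATE),
            const_pos_series(), const_pos_series(), PULL, CFG,
        )
        assert steps == []

    def test_steps_before_onset_discarded(self):
        vel = minjerk_speed_series(start=2.0)  # swing entirely before onset 3.0
        steps = detect_steps(
            vel, ScalarSeries(np.zeros(300), RATE),
            minjerk_pos_series(start=2.0), const_pos_series(), PULL, CFG,
        )
        assert steps == []

    def test_threshold_monotonicity(self):
        """Raising the velocity threshold never increases the step count."""
        traj, _ = generate_trial(TrialParams(seed=9))
        counts = []
        for thr in (0.5, 0.7, 0.9, 1.1, 1.3):
            cfg = AnalysisConfig(step_velocity_threshold=thr)
            try:
                counts.append(analyze_trial(traj, cfg).step_count)
            except NoPullDetectedError:  # pragma: no cover
                counts.append(0)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def rigid_tilt_trajectory(angle_deg, axis="sagittal", n=300):
    """Static skeleton that rotates rigidly about the mid-hip after t=2 s."""
    from vpull.synthetic import _static_skeleton

    base = _static_skeleton(1.73)
    hip_mid = 0.5 * (base[KEYPOINT_INDEX["left_hip"]] + base[KEYPOINT_INDEX["right_hip"]])
    times = np.arange(n) / RATE
    xyz = np.broadcast_to(base, (n, 17, 3)).copy()
    phi = np.where(times >= 2.0, np.radians(angle_deg), 0.0)
    c, s = np.cos(phi), np.sin(phi)
    upper = [k for k in KEYPOINT_INDEX if k not in
             ("left_hip", "right_hip", "left_knee", "right_knee", "left_ankle", "right_ankle")]
    for name in upper:
        j = KEYPOINT_INDEX[name]
        d = base[j] - hip_mid
        if axis == "sagittal":  # rotate in y-z
            xyz[:, j, 1] = hip_mid[1] + c * d[1] - s * d[2]
            xyz[:, j, 2] = hip_mid[2] + s * d[1] + c * d[2]
        else:  # lateral lean: rotate in x-y
            xyz[:, j, 0] = hip_mid[0] + c * d[0] - s * d[1]
            xyz[:, j, 1] = hip_mid[1] + s * d[0] + c * d[1]
    return Trajectory(times, xyz, np.ones((n, 17)), RATE)


class TestTrunkAngle:
    def test_static_baseline_angle_zero(self):
        traj = rigid_tilt_trajectory(0.0)
        sag, _ = trunk_angle_series(traj, CFG)
        assert np.allclose(sag.values, 0.0, atol=1e-9)

    def test_backward_rotation_reads_negative_ten(self):
        """A rigid 10° backward rotation about the mid-hip reads −10°."""
        traj = rigid_tilt_trajectory(-10.0)
        sag, _ = trunk_angle_series(traj, CFG)
        assert sag.values[-1] == pytest.approx(-10.0, abs=0.1)

    def test_lateral_lean_invisible_in_sagittal_plane(self):
        traj = rigid_tilt_trajectory(10.0, axis="lateral")
        sag, full3d = trunk_angle_series(traj, CFG)
        assert abs(sag.values[-1]) <= 0.1
        assert full3d.values[-1] == pytest.approx(10.0, abs=0.1)

    def test_max_retropulsion_picks_most_negative_after_onset(self):
        angle = ScalarSeries(np.zeros(300), RATE)
        angle.values[150:200] = -12.0
        angle.values[50:60] = -20.0  # before onset: ignored
        trunk = max_retropulsion(angle, PULL)
        assert trunk.max_retropulsion_angle == -12.0
        assert trunk.time_of_max == pytest.approx(150 / RATE)

    def test_zero_angle_after_onset(self):
        trunk = max_retropulsion(ScalarSeries(np.zeros(300), RATE), PULL)
        assert trunk.max_retropulsion_angle == 0.0


class TestRecovery:
    def _trunk(self, angle_values):
        series = ScalarSeries(np.asarray(angle_values, dtype=float), RATE)
        mask = series.times >= PULL.onset_time
        i = int(np.argmin(series.values[mask]))
        return TrunkResponse(
            max_retropulsion_angle=float(series.values[mask][i]),
            time_of_max=float(series.times[mask][i]),
            angle_series=series,
        )

    def test_linear_return_latency(self):
        """Angle returns linearly from −12° to −3° (75% reduction) at
        onset+1.5 s; one step ends earlier, so latency is 1.5 s."""
        t = np.arange(300) / RATE
        angle = np.zeros(300)
        down = (t >= 3.0) & (t < 3.4)
        angle[down] = -12.0 * (t[down] - 3.0) / 0.4
        up = t >= 3.4  # linear return reaching 0 at 5.0 s: hits −3° at 4.6 s
        angle[up] = np.minimum(-12.0 + 12.0 * (t[up] - 3.4) / 1.6, 0.0)
        trunk = self._trunk(angle)
        steps = [Step("left", 3.5, 3.8, 0.3, 1.2, 1.0)]
        lat = recovery_latency(steps, trunk, PULL, CFG)
        # |angle| <= 3 when t >= 3.4 + 1.2 = 4.6 -> latency 1.6 s within a frame
        assert lat == pytest.approx(1.6, abs=DT + 1e-9)

    def test_never_recovering_returns_none(self):
        t = np.arange(300) / RATE
        angle = np.where(t >= 3.2, -12.0, 0.0)
        trunk = self._trunk(angle)
        assert recovery_latency([], trunk, PULL, CFG) is None

    def test_both_conditions_required(self):
        """Angle recovers at onset+1.0 s but the last step ends at
        onset+1.8 s: latency is governed by the later condition."""
        t = np.arange(300) / RATE
        angle = np.zeros(300)
        dip = (t >= 3.2) & (t < 3.5)
        angle[dip] = -12.0
        trunk = self._trunk(angle)  # fully back to 0 right after 3.5 s
        steps = [Step("left", 3.4, 4.8, 0.3, 1.2, 1.0)]
        lat = recovery_latency(steps, trunk, PULL, CFG)
        assert lat == pytest.approx(1.8, abs=DT + 1e-9)


class TestAnalyzeTrialComposition:
    def test_healthy_trial_round_trip(self):
        params = TrialParams(seed=42)
        traj, gt = generate_trial(params)
        res = analyze_trial(traj, CFG)
        assert res.step_count == 1
        assert res.stepped and res.recovered_unaided
        assert abs(res.steps[0].start - gt.true_steps[0].start) <= DT
        assert res.steps[0].length == pytest.approx(gt.true_steps[0].length, rel=0.05)
        assert res.trunk.max_retropulsion_angle == pytest.approx(gt.max_tilt, abs=0.5)
        assert res.recovery_latency == pytest.approx(
            gt.recovery_time - gt.onset_time, abs=2 * DT
        )

    def test_impaired_trial_no_recovery(self):
        steps = tuple(
            StepSpec(side, lat, 0.22, 0.38)
            for side, lat in zip(
                ("left", "right", "left", "right"), (0.45, 1.0, 1.55, 2.1)
            )
        )
        params = TrialParams(
            max_tilt=-18.0, recovers=False, steps=steps, seed=7
        )
        traj, gt = generate_trial(params)
        res = analyze_trial(traj, CFG)
        assert res.step_count == 4
        assert res.recovery_latency is None
        assert not res.recovered_unaided

    def test_determinism(self):
        traj, _ = generate_trial(TrialParams(seed=5))
        r1 = analyze_trial(traj, CFG)
        r2 = analyze_trial(traj, CFG)
        assert r1.pull.onset_time == r2.pull.onset_time
        assert r1.pull.magnitude == r2.pull.magnitude
        assert [(s.start, s.end, s.length) for s in r1.steps] == [
            (s.start, s.end, s.length) for s in r2.steps
        ]
        assert r1.trunk.max_retropulsion_angle == r2.trunk.max_retropulsion_angle
        assert r1.recovery_latency == r2.recovery_latency

    def test_time_shift_equivariance(self):
        """Shifting all timestamps by Δ shifts event times by Δ and leaves
        magnitudes, lengths and angles unchanged."""
        traj, _ = generate_trial(TrialParams(seed=11))
        delta = 0.5  # 15 frames
        shifted = Trajectory(
            traj.times + delta, traj.xyz.copy(), traj.confidence.copy(),
            traj.nominal_rate, dict(traj.meta),
        )
        r0 = analyze_trial(traj, CFG)
        r1 = analyze_trial(shifted, CFG)
        assert r1.pull.onset_time == pytest.approx(r0.pull.onset_time + delta, abs=1e-9)
        assert r1.pull.magnitude == pytest.approx(r0.pull.magnitude, abs=1e-9)
        assert r1.step_count == r0.step_count
        for a, b in zip(r0.steps, r1.steps):
            assert b.start == pytest.approx(a.start + delta, abs=1e-9)
            assert b.length == pytest.approx(a.length, abs=1e-9)
        assert r1.trunk.max_retropulsion_angle == pytest.approx(
            r0.trunk.max_retropulsion_angle, abs=1e-9
        )

    def test_unusable_trajectory_raises(self, rng):
        from conftest import random_trajectory
        from vpull.events import UnusableTrajectoryError

        traj = random_trajectory(rng, n=40)
        j = KEYPOINT_INDEX["left_ankle"]
        traj.xyz[5:20, j] = np.nan
        traj.confidence[5:20, j] = 0.0
        bad = Trajectory(traj.times, traj.xyz, traj.confidence)
        with pytest.raises(UnusableTrajectoryError):
            analyze_trial(bad, CFG)
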