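"""Pull-test event detection: pull onset/magnitude, stepping, truncal response.

The analysis chain mirrors the clinical construct of the test of
retropulsion. The examiner delivers a sudden backward shoulder pull; the
participant responds with corrective steps and a backward trunk excursion
and (ideally) regains quiet stance. From a 3D keypoint trajectory this
module extracts:

* **pull onset and magnitude** from the resultant (Euclidean-norm)
  acceleration of the shoulder midpoint — the perturbation crosses a
  threshold of 3 SD above the 1 s quiet-stance baseline, and onset is
  refined to the last local minimum of the acceleration curve preceding
  that crossing (the foot of the acceleration pulse);
* **corrective steps** from bilateral resultant ankle velocities by
  0.7 m/s threshold crossings, with interval merging and a minimum
  duration to suppress noise-induced micro-intervals;
* **truncal response** as the signed sagittal-plane angle of the
  shoulder-midpoint-to-hip-midpoint vector relative to baseline posture
  (backward lean negative);
* **balance recovery** as the earliest moment when stepping has
  terminated and the backward bending angle has shrunk by at least 75%
  from its post-pull maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .keypoints import AnalysisConfig, Trajectory, validate_required_keypoints
from .preprocess import (
    ScalarSeries,
    baseline_stats,
    differentiate,
    midpoint_series,
    regularize,
    resultant,
    smooth_trajectory,
)

__all__ = [
    "PullEvent",
    "Step",
    "TrunkResponse",
    "PullTestResult",
    "NoPullDetectedError",
    "UnusableTrajectoryError",
    "detect_pull_onset",
    "pull_magnitude",
    "detect_steps",
    "trunk_angle_series",
    "max_retropulsion",
    "recovery_latency",
    "analyze_trial",
    "result_to_record",
]

logger = logging.getLogger(__name__)


class NoPullDetectedError(RuntimeError):
    """The shoulder acceleration never exceeds the baseline threshold."""


class UnusableTrajectoryError(RuntimeError):
    """Required keypoints have gaps too long for analysis."""


@dataclass
class PullEvent:
    """Onset and dose of the backward perturbation."""

    onset_time: float  # s; foot of the acceleration pulse
    crossing_time: float  # s; threshold crossing leading into the pulse peak
    threshold_used: float  # m/s²
    magnitude: float | None = None  # m/s²; peak resultant shoulder acceleration

    def __post_init__(self) -> None:
        if self.onset_time > self.crossing_time + 1e-12:
            raise ValueError("onset_time must not exceed crossing_time")


@dataclass(frozen=True)
class Step:
    """One corrective step segmented from the ankle velocity profile."""

    side: str  # "left" | "right"
    start: float  # s; upward 0.7 m/s crossing (interpolated)
    end: float  # s; downward crossing
    length: float  # m; horizontal (x-z) ankle displacement start -> end
    peak_velocity: float  # m/s; max resultant ankle speed within the step
    mean_velocity: float  # m/s; mean resultant speed (secondary metric)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class TrunkResponse:
    """Backward trunk-bending summary. Angles in degrees, backward negative."""

    max_retropulsion_angle: float  # deg, <= 0
    time_of_max: float  # s
    angle_series: ScalarSeries  # sagittal-plane signed angle, deg
    max_angle_3d: float = 0.0  # unsigned 3D angle to baseline at its max (secondary)


@dataclass
class PullTestResult:
    """Everything the pipeline derives from one pull-test trial."""

    pull: PullEvent
    steps: list[Step]
    trunk: TrunkResponse
    recovery_latency: float | None  # s from pull onset; None = not recovered
    meta: dict = field(default_factory=dict)

    @property
    def step_count(self) -> int:
        return len(self.steps)

    @property
    def stepped(self) -> bool:
        return self.step_count > 0

    @property
    def recovered_unaided(self) -> bool:
        return self.recovery_latency is not None

    @property
    def first_step_latency(self) -> float | None:
        return self.steps[0].start - self.pull.onset_time if self.stepped else None

    @property
    def first_step_length(self) -> float | None:
        return self.steps[0].length if self.stepped else None

    @property
    def first_step_velocity(self) -> float | None:
        return self.steps[0].peak_velocity if self.stepped else None


# ---------------------------------------------------------------------------
# Pull onset and magnitude
# ---------------------------------------------------------------------------


def detect_pull_onset(
    shoulder_acc: ScalarSeries, cfg: AnalysisConfig | None = None
) -> PullEvent:
    """Locate the pull in the resultant shoulder acceleration series.

    The threshold is ``baseline mean + onset_sd_multiplier × baseline SD``
    over the first second of quiet stance. The crossing is the start of
    the first above-threshold excursion that (a) holds for at least two
    consecutive samples and (b) reaches at least half of the post-baseline
    maximum — a debounce that rejects isolated noise spikes over the
    threshold while still locking onto the perturbation impulse rather
    than later response-related peaks (trunk deceleration, braking).
    Onset is then the last local minimum (a sample not larger than either
    neighbour; the earliest sample of a plateau) strictly before the
    crossing; if none exists after the baseline, the crossing itself is
    the onset.

    Raises :class:`NoPullDetectedError` if no qualifying excursion exists.
    """
    cfg = cfg or AnalysisConfig()
    base = baseline_stats(shoulder_acc, cfg)
    x = shoulder_acc.values
    # relative epsilon keeps a zero-variance (noise-free) baseline from
    # producing a zero threshold that numerical filter ripple would cross
    eps = 1e-9 * max(1.0, float(np.max(np.abs(x))))
    thr = base.mean + cfg.onset_sd_multiplier * base.sd + eps
    n = x.shape[0]
    n_base = int(round(cfg.baseline_window * shoulder_acc.rate))
    # guard the zero-phase filter's edge-transient zone at the recording end
    guard = min(3 * cfg.filter_order, max(n - n_base - 1, 0))
    seg = x[n_base : n - guard]
    if seg.size == 0 or not np.any(seg > thr):
        raise NoPullDetectedError(
            f"shoulder acceleration never exceeds threshold {thr:.3g} m/s²"
        )
    peak = float(np.max(seg))
    # a qualifying excursion must reach twice the threshold's elevation over
    # the baseline (capped at 0.8×peak so a weak but dominant pulse still
    # qualifies) and at least half the post-baseline maximum
    gate = max(0.5 * peak, min(base.mean + 2 * (thr - base.mean), 0.7 * peak))
    above = x > thr
    crossing = None
    i = n_base
    while i < n - 1:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            # excursion x[i..j]
            if j > i and np.max(x[i : j + 1]) >= gate:
                crossing = i
                break
            i = j + 1
        else:
            i += 1
    if crossing is None:  # single-sample excursions only: fall back to first
        crossing = n_base + int(np.argmax(seg > thr))
    onset = crossing
    for i in range(crossing - 1, n_base, -1):
        if x[i] <= x[i - 1] and x[i] <= x[i + 1]:
            onset = i
            while onset - 1 > n_base and x[onset - 1] == x[onset]:
                onset -= 1  # plateau: earliest sample
            break
    times = shoulder_acc.times
    return PullEvent(
        onset_time=float(times[onset]),
        crossing_time=float(times[crossing]),
        threshold_used=float(thr),
    )


def pull_magnitude(
    shoulder_acc: ScalarSeries, pull: PullEvent, cfg: AnalysisConfig | None = None
) -> float:
    """Peak resultant shoulder acceleration within the pull window.

    The search window is ``[onset, onset + pull_peak_window]``; an
    unbounded search could pick up step-related shoulder accelerations.
    A window extending past the recording is truncated with a warning.
    """
    cfg = cfg or AnalysisConfig()
    times = shoulder_acc.times
    t_end = pull.onset_time + cfg.pull_peak_window
    if t_end > times[-1] + 1e-12:
        logger.warning(
            "pull peak window truncated to recording end (%.3f s)", times[-1]
        )
        t_end = times[-1]
    mask = (times >= pull.onset_time - 1e-12) & (times <= t_end + 1e-12)
    return float(np.max(shoulder_acc.values[mask]))


# ---------------------------------------------------------------------------
# Stepping response
# ---------------------------------------------------------------------------


def _crossing_time(times, vals, i_lo, i_hi, thr) -> float:
    """Linear interpolation of the threshold crossing between two samples."""
    v0, v1 = vals[i_lo], vals[i_hi]
    if v1 == v0:
        return float(times[i_hi])
    frac = (thr - v0) / (v1 - v0)
    frac = min(max(frac, 0.0), 1.0)
    return float(times[i_lo] + frac * (times[i_hi] - times[i_lo]))


def _supra_intervals(speed: ScalarSeries, thr: float) -> list[tuple[float, float]]:
    """Maximal intervals with speed > thr, endpoints interpolated."""
    v = speed.values
    t = speed.times
    above = v > thr
    if not above.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    out = []
    for s, e in zip(idx[::2], idx[1::2]):  # v[s:e] above
        start = _crossing_time(t, v, s - 1, s, thr) if s > 0 else float(t[0])
        end = _crossing_time(t, v, e - 1, e, thr) if e < len(v) else float(t[-1])
        out.append((start, end))
    return out


def detect_steps(
    ankle_vel_left: ScalarSeries,
    ankle_vel_right: ScalarSeries,
    ankle_pos_left: ScalarSeries,
    ankle_pos_right: ScalarSeries,
    pull: PullEvent,
    cfg: AnalysisConfig | None = None,
) -> list[Step]:
    """Segment corrective steps from bilateral resultant ankle speeds.

    Per foot: maximal intervals with speed above the 0.7 m/s threshold
    that start at or after pull onset (anticipatory movement falls outside
    the clinical scheme); intervals separated by a sub-threshold gap
    shorter than ``step_merge_gap`` are merged; intervals shorter than
    ``min_step_duration`` are discarded. Step length is the horizontal
    (x-z plane) ankle displacement between the interpolated start and end
    crossings — ground displacement, so vertical ankle lift does not
    inflate it. Steps of both feet are merged and sorted by start time.
    """
    cfg = cfg or AnalysisConfig()
    thr = cfg.step_velocity_threshold
    steps: list[Step] = []
    for side, vel, pos in (
        ("left", ankle_vel_left, ankle_pos_left),
        ("right", ankle_vel_right, ankle_pos_right),
    ):
        intervals = [
            iv for iv in _supra_intervals(vel, thr) if iv[0] >= pull.onset_time - 1e-9
        ]
        merged: list[list[float]] = []
        for start, end in intervals:
            if merged and start - merged[-1][1] < cfg.step_merge_gap:
                merged[-1][1] = end
            else:
                merged.append([start, end])
        for start, end in merged:
            if end - start < cfg.min_step_duration:
                continue
            t = vel.times
            inside = (t >= start) & (t <= end)
            peak = float(np.max(vel.values[inside])) if inside.any() else thr
            mean = float(np.mean(vel.values[inside])) if inside.any() else thr
            px = np.interp([start, end], pos.times, pos.values[:, 0])
            pz = np.interp([start, end], pos.times, pos.values[:, 2])
            length = float(np.hypot(px[1] - px[0], pz[1] - pz[0]))
            steps.append(
                Step(
                    side=side,
                    start=start,
                    end=end,
                    length=length,
                    peak_velocity=peak,
                    mean_velocity=mean,
                )
            )
    steps.sort(key=lambda s: s.start)
    return steps


# ---------------------------------------------------------------------------
# Truncal response
# ---------------------------------------------------------------------------


def trunk_angle_series(
    traj: Trajectory, cfg: AnalysisConfig | None = None
) -> tuple[ScalarSeries, ScalarSeries]:
    """Signed sagittal trunk angle (deg) relative to baseline posture.

    The trunk vector runs from the hip midpoint to the shoulder midpoint.
    The baseline vector is its mean over the quiet-stance window. The
    primary angle is measured between the projections of both vectors onto
    the sagittal (y-z) plane, signed so that backward lean (shoulders
    displaced toward +z relative to the hips) is negative; a pure lateral
    lean therefore reads 0. The unsigned full 3D angle to baseline is
    returned alongside as a secondary series.

    Expects a regularized trajectory with shoulders and hips present.
    """
    cfg = cfg or AnalysisConfig()
    sh = midpoint_series(traj, "left_shoulder", "right_shoulder")
    hip = midpoint_series(traj, "left_hip", "right_hip")
    v = sh.values - hip.values  # (n, 3)
    if not np.all(np.isfinite(v)):
        raise UnusableTrajectoryError("shoulders/hips missing in some frames")
    n_base = int(round(cfg.baseline_window * traj.nominal_rate))
    if v.shape[0] < n_base:
        raise ValueError("trajectory shorter than baseline window")
    v0 = v[:n_base].mean(axis=0)

    # sagittal projection: (y, z) components
    ay, az = v0[1], v0[2]
    by, bz = v[:, 1], v[:, 2]
    cross = ay * bz - az * by  # negative for backward lean given y-down
    dot = ay * by + az * bz
    sagittal = np.degrees(np.arctan2(cross, dot))

    norm0 = np.linalg.norm(v0)
    norms = np.linalg.norm(v, axis=1)
    cosang = np.clip(v @ v0 / (norms * norm0), -1.0, 1.0)
    full3d = np.degrees(np.arccos(cosang))

    t0 = float(traj.times[0])
    return (
        ScalarSeries(sagittal, traj.nominal_rate, t0),
        ScalarSeries(full3d, traj.nominal_rate, t0),
    )


def max_retropulsion(
    angle_series: ScalarSeries,
    pull: PullEvent,
    angle_3d: ScalarSeries | None = None,
) -> TrunkResponse:
    """Maximum backward bending angle (most negative) at or after pull onset."""
    t = angle_series.times
    mask = t >= pull.onset_time - 1e-12
    vals = angle_series.values[mask]
    i = int(np.argmin(vals))
    t_max = float(t[mask][i])
    max3d = 0.0
    if angle_3d is not None:
        max3d = float(np.max(angle_3d.values[angle_3d.times >= pull.onset_time - 1e-12]))
    return TrunkResponse(
        max_retropulsion_angle=float(vals[i]),
        time_of_max=t_max,
        angle_series=angle_series,
        max_angle_3d=max3d,
    )


def recovery_latency(
    steps: list[Step],
    trunk: TrunkResponse,
    pull: PullEvent,
    cfg: AnalysisConfig | None = None,
) -> float | None:
    """Latency of balance recovery relative to pull onset, or None.

    Recovery is the earliest time at or after the retropulsion maximum
    where (a) stepping has terminated — the time is at or past the end of
    the final detected step — and (b) the backward bending angle has been
    reduced by at least ``recovery_fraction`` from its maximum, i.e.
    ``|angle| <= (1 − recovery_fraction)·|max|``.
    """
    cfg = cfg or AnalysisConfig()
    level = (1.0 - cfg.recovery_fraction) * abs(trunk.max_retropulsion_angle)
    t = trunk.angle_series.times
    a = trunk.angle_series.values
    t_min = trunk.time_of_max
    if steps:
        t_min = max(t_min, max(s.end for s in steps))
    ok = (t >= t_min - 1e-12) & (np.abs(a) <= level + 1e-12)
    if not ok.any():
        return None
    return float(t[np.argmax(ok)] - pull.onset_time)


# ---------------------------------------------------------------------------
# Whole-trial composition
# ---------------------------------------------------------------------------


def analyze_trial(traj: Trajectory, cfg: AnalysisConfig | None = None) -> PullTestResult:
    """Run the full pipeline on one trial.

    Composition: validate -> regularize -> smooth -> shoulder-midpoint
    acceleration -> pull onset/magnitude -> ankle-velocity step
    segmentation -> trunk angle -> recovery. Deterministic given the
    trajectory and configuration.
    """
    cfg = cfg or AnalysisConfig()
    report = validate_required_keypoints(traj, cfg)
    if not report.usable:
        bad = {k: g for k, g in report.longest_gap.items() if g > cfg.max_gap_interp}
        raise UnusableTrajectoryError(
            f"required keypoints with over-long gaps (frames): {bad or 'empty input'}"
        )
    reg = regularize(traj, cfg)
    sm = smooth_trajectory(reg, cfg)

    shoulder_acc = resultant(
        differentiate(midpoint_series(sm, "left_shoulder", "right_shoulder"), order=2)
    )
    pull = detect_pull_onset(shoulder_acc, cfg)
    pull.magnitude = pull_magnitude(shoulder_acc, pull, cfg)

    pos_l = ScalarSeries(sm.keypoint("left_ankle"), sm.nominal_rate, float(sm.times[0]))
    pos_r = ScalarSeries(sm.keypoint("right_ankle"), sm.nominal_rate, float(sm.times[0]))
    vel_l = resultant(differentiate(pos_l, order=1))
    vel_r = resultant(differentiate(pos_r, order=1))
    steps = detect_steps(vel_l, vel_r, pos_l, pos_r, pull, cfg)

    sagittal, full3d = trunk_angle_series(sm, cfg)
    trunk = max_retropulsion(sagittal, pull, full3d)
    latency = recovery_latency(steps, trunk, pull, cfg)

    return PullTestResult(
        pull=pull, steps=steps, trunk=trunk, recovery_latency=latency,
        meta=dict(traj.meta),
    )


def result_to_record(result: PullTestResult) -> dict:
    """Flatten a result into one serializable row (units in column names)."""
    rec = {
        "subject_id": result.meta.get("subject_id"),
        "examiner_id": result.meta.get("examiner_id"),
        "trial_id": result.meta.get("trial_id"),
        "pull_onset_s": result.pull.onset_time,
        "pull_magnitude_m_s2": result.pull.magnitude,
        "step_count": result.step_count,
        "stepped": result.stepped,
        "first_step_latency_s": result.first_step_latency,
        "first_step_length_m": result.first_step_length,
        "first_step_velocity_m_s": result.first_step_velocity,
        "first_step_mean_velocity_m_s": (
            result.steps[0].mean_velocity if result.stepped else None
        ),
        "retropulsion_angle_deg": result.trunk.max_retropulsion_angle,
        "retropulsion_angle_3d_deg": result.trunk.max_angle_3d,
        "recovery_latency_s": result.recovery_latency,
        "recovered_unaided": result.recovered_unaided,
    }
    return rec
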