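"""Synthetic pull-test trials with analytically known ground truth.

The generator emulates the kinematic phenomenology of a recorded pull
test — quiet stance, a sudden backward perturbation at the shoulders, a
backward trunk excursion with (or without) recovery, and threshold-
crossing corrective steps — as a COCO-17 skeleton trajectory sampled at
the sensor rate, with i.i.d. Gaussian measurement noise per coordinate.
It is a kinematic template, not a physics simulation: each response
component is authored directly so that every derived metric has a
closed-form or numerically exact ground truth.

Construction, in the camera frame (x left, y down, z backward/depth):

* a static anthropometric skeleton scaled to subject height;
* a whole-body backward translation whose acceleration is a biphasic
  pulse: the prescribed Gaussian push ``A·exp(−(t−t₀−2σ)²/2σ²)`` followed
  by an impulse-balanced braking Gaussian (4× wider, 1/4 amplitude,
  0.8 s later) so the body comes to rest displaced ~``A·σ·√(2π)·0.8`` m
  backward. Translating the whole body keeps the trunk vector — and with
  it the retropulsion-angle ground truth — exactly equal to the authored
  tilt profile;
* a trunk rotation about the mid-hip in the sagittal plane: C²
  minimum-jerk rise to ``max_tilt`` (negative = backward) over
  ``tilt_rise`` seconds, starting ``tilt_delay`` after the pull (the
  trunk lags the shoulder impulse), then a critically damped
  exponential-family return with time constant ``tilt_recovery_tau`` if
  the trial recovers, else a plateau;
* per corrective step, a minimum-jerk backward ankle displacement of
  given length and duration (peak speed ``1.875·L/T``), the same-side
  knee following at half amplitude and a small vertical foot lift
  (10% of step length);
* i.i.d. Gaussian noise of SD ``noise_sd`` on every coordinate.

Ground-truth step boundaries are the 0.7 m/s crossings of the noiseless
resultant ankle velocity (translation + step + lift), solved numerically
to 1e-6 s; onset is the start of the push pulse's effective support
(µ − 2σ); the recovery time combines the closed-form tilt-return
crossing with the last true step end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm as _norm

from .keypoints import COCO_KEYPOINTS, KEYPOINT_INDEX, Trajectory

__all__ = [
    "StepSpec",
    "TrialParams",
    "TrueStep",
    "SyntheticGroundTruth",
    "min_jerk_speed",
    "min_jerk_displacement",
    "generate_trial",
    "cohort_generator",
    "PROFILES",
]

# --------------------------------------------------------------------------
# Anthropometry: landmark heights above the floor and half-widths, as
# fractions of subject height H. Cosmetic for the detectors (which use only
# relative geometry) but keeps generated skeletons visually plausible.
# --------------------------------------------------------------------------
_LEVELS = {  # height fraction above floor
    "nose": 0.935,
    "eye": 0.945,
    "ear": 0.930,
    "shoulder": 0.818,
    "elbow": 0.630,
    "wrist": 0.490,
    "hip": 0.530,
    "knee": 0.285,
    "ankle": 0.039,
}
_HALF_WIDTHS = {  # lateral (x) offset fraction, left positive
    "nose": 0.0,
    "eye": 0.033,
    "ear": 0.070,
    "shoulder": 0.115,
    "elbow": 0.130,
    "wrist": 0.140,
    "hip": 0.095,
    "knee": 0.100,
    "ankle": 0.100,
}
_CAMERA_HEIGHT = 1.0  # m above floor (y = camera height − landmark height)
_CAMERA_DISTANCE = 2.0  # m, baseline depth of the participant

_UPPER_BODY = (
    "nose", "left_eye", "right_eye", "left_ear", "right_ear",
    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
    "left_wrist", "right_wrist",
)

# Biphasic perturbation shape constants (relative to the push pulse).
_BRAKE_WIDTH_RATIO = 4.0
_BRAKE_DELAY = 0.80  # s between push and brake centers
_STEP_LIFT_RATIO = 0.10  # vertical foot lift as a fraction of step length
_KNEE_FOLLOW = 0.5

_STEP_THRESHOLD = 0.7  # m/s; the clinical step-segmentation threshold


@dataclass(frozen=True)
class StepSpec:
    """One commanded step: foot side, latency after pull onset, length, duration."""

    side: str  # "left" | "right"
    latency: float  # s after pull onset
    length: float  # m
    duration: float  # s


@dataclass
class TrialParams:
    """Generator parameters for one simulated trial."""

    duration: float = 10.0  # s
    rate: float = 30.0  # Hz
    subject_height: float = 1.73  # m
    pull_time: float = 3.0  # s; start of the push pulse's support
    pull_peak_acc: float = 3.0  # m/s²
    pull_pulse_sigma: float = 0.06  # s
    max_tilt: float = -10.0  # deg, negative = backward
    tilt_rise: float = 0.55  # s
    tilt_delay: float = 0.15  # s after pull onset before the trunk reacts
    tilt_recovery_tau: float = 0.40  # s
    recovers: bool = True
    steps: Sequence[StepSpec] = field(
        default_factory=lambda: (StepSpec("left", 0.55, 0.32, 0.40),)
    )
    noise_sd: float = 0.002  # m per coordinate per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pull_time <= 1.5:
            raise ValueError("pull_time must exceed 1.5 s (quiet baseline)")
        if self.duration <= self.pull_time + 1.0:
            raise ValueError("recording too short for the perturbation")
        per_side: dict[str, list[StepSpec]] = {"left": [], "right": []}
        for s in self.steps:
            if s.side not in per_side:
                raise ValueError(f"unknown foot side {s.side!r}")
            if s.latency <= 0 or s.duration <= 0 or s.length < 0:
                raise ValueError("step latency/duration must be positive")
            per_side[s.side].append(s)
        for side, specs in per_side.items():
            specs.sort(key=lambda s: s.latency)
            for a, b in zip(specs, specs[1:]):
                if a.latency + a.duration > b.latency:
                    raise ValueError(f"overlapping steps on the {side} foot")


@dataclass(frozen=True)
class TrueStep:
    """Ground-truth threshold-crossing boundaries of one step."""

    side: str
    start: float  # s; upward 0.7 m/s crossing of the noiseless speed
    end: float  # s; downward crossing
    length: float  # m; horizontal ankle displacement between crossings
    peak_velocity: float  # m/s


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Analytically derived true event times/magnitudes for one trial."""

    onset_time: float
    peak_acc: float
    true_steps: tuple[TrueStep, ...]
    max_tilt: float  # deg
    time_of_max_tilt: float
    recovery_time: float | None  # absolute s, None if never recovered


# --------------------------------------------------------------------------
# Closed-form motion components
# --------------------------------------------------------------------------


def min_jerk_speed(L: float, T: float, t) -> np.ndarray | float:
    """Speed of a minimum-jerk point-to-point displacement.

    ``v(t) = 30·(L/T)·(τ² − 2τ³ + τ⁴)`` with ``τ = t/T``; zero outside
    [0, T]; the peak, at τ = 1/2, equals 1.875·L/T.
    """
    t = np.asarray(t, dtype=float)
    tau = np.clip(t / T, 0.0, 1.0)
    v = 30.0 * (L / T) * (tau**2 - 2 * tau**3 + tau**4)
    v = np.where((t < 0) | (t > T), 0.0, v)
    return v if v.ndim else float(v)


def min_jerk_displacement(L: float, T: float, t) -> np.ndarray | float:
    """Displacement of the minimum-jerk profile: L·(10τ³ − 15τ⁴ + 6τ⁵)."""
    t = np.asarray(t, dtype=float)
    tau = np.clip(t / T, 0.0, 1.0)
    d = L * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return d if d.ndim else float(d)


def _lift_profile(L: float, T: float, t) -> np.ndarray:
    """Vertical foot lift: smooth bell 16τ²(1−τ)², peak _STEP_LIFT_RATIO·L."""
    t = np.asarray(t, dtype=float)
    tau = np.clip(t / T, 0.0, 1.0)
    return _STEP_LIFT_RATIO * L * 16 * tau**2 * (1 - tau) ** 2


def _lift_velocity(L: float, T: float, t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    tau = np.clip(t / T, 0.0, 1.0)
    inside = (t >= 0) & (t <= T)
    dv = _STEP_LIFT_RATIO * L * 16 * (2 * tau - 6 * tau**2 + 4 * tau**3) / T
    return np.where(inside, dv, 0.0)


def _pulse_centers(p: TrialParams) -> tuple[float, float, float, float]:
    """(push center, push sigma, brake center, brake sigma)."""
    c1 = p.pull_time + 2 * p.pull_pulse_sigma
    s1 = p.pull_pulse_sigma
    return c1, s1, c1 + _BRAKE_DELAY, _BRAKE_WIDTH_RATIO * s1


def pull_acceleration(p: TrialParams, t) -> np.ndarray:
    """Whole-body backward acceleration: Gaussian push minus balanced brake."""
    c1, s1, c2, s2 = _pulse_centers(p)
    A = p.pull_peak_acc
    t = np.asarray(t, dtype=float)
    push = A * np.exp(-((t - c1) ** 2) / (2 * s1**2))
    brake = (A * s1 / s2) * np.exp(-((t - c2) ** 2) / (2 * s2**2))
    return push - brake


def pull_velocity(p: TrialParams, t) -> np.ndarray:
    c1, s1, c2, s2 = _pulse_centers(p)
    imp = p.pull_peak_acc * s1 * np.sqrt(2 * np.pi)
    t = np.asarray(t, dtype=float)
    return imp * (_norm.cdf((t - c1) / s1) - _norm.cdf((t - c2) / s2))


def pull_displacement(p: TrialParams, t) -> np.ndarray:
    c1, s1, c2, s2 = _pulse_centers(p)
    imp = p.pull_peak_acc * s1 * np.sqrt(2 * np.pi)
    t = np.asarray(t, dtype=float)

    def antider(c, s):
        u = (t - c) / s
        return s * (u * _norm.cdf(u) + _norm.pdf(u))

    return imp * (antider(c1, s1) - antider(c2, s2))


def tilt_angle(p: TrialParams, t) -> np.ndarray:
    """Trunk tilt profile in degrees (negative = backward)."""
    t = np.asarray(t, dtype=float)
    ts = p.pull_time + p.tilt_delay
    tp = ts + p.tilt_rise
    theta = np.zeros_like(t)
    rising = (t >= ts) & (t < tp)
    # C² minimum-jerk rise (zero angular velocity AND acceleration at both
    # ends): muscle-driven trunk motion has no acceleration jumps, and a
    # discontinuous angular acceleration at tilt start would superimpose a
    # spurious spike onto the shoulder-acceleration pulse.
    tau = (t[rising] - ts) / p.tilt_rise
    theta[rising] = p.max_tilt * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    after = t >= tp
    if p.recovers:
        # critically-damped return (1+x)·e^{−x}: exponential-family decay with
        # zero initial slope, so the angular velocity is continuous at the
        # rise/return transition (a slope jump would inject a spurious spike
        # into the shoulder acceleration).
        x = (t[after] - tp) / p.tilt_recovery_tau
        theta[after] = p.max_tilt * (1 + x) * np.exp(-x)
    else:
        theta[after] = p.max_tilt
    return theta


# --------------------------------------------------------------------------
# Skeleton assembly
# --------------------------------------------------------------------------


def _static_skeleton(height: float) -> np.ndarray:
    """(17, 3) quiet-stance skeleton in the camera frame."""
    xyz = np.zeros((len(COCO_KEYPOINTS), 3))
    for name in COCO_KEYPOINTS:
        if name == "nose":
            part, sign = "nose", 0.0
        else:
            side, part = name.split("_", 1)
            sign = 1.0 if side == "left" else -1.0
        xyz[KEYPOINT_INDEX[name]] = (
            sign * _HALF_WIDTHS[part] * height,
            _CAMERA_HEIGHT - _LEVELS[part] * height,
            _CAMERA_DISTANCE,
        )
    return xyz


def _ankle_motion(
    p: TrialParams, side: str
) -> tuple[Callable, Callable, Callable, Callable]:
    """Closures (z_disp(t), z_vel(t), y_lift(t), y_vel(t)) for one foot's
    step train, excluding the whole-body translation."""
    specs = [s for s in p.steps if s.side == side]

    def z_disp(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for s in specs:
            out += min_jerk_displacement(s.length, s.duration, t - p.pull_time - s.latency)
        return out

    def z_vel(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for s in specs:
            out += min_jerk_speed(s.length, s.duration, t - p.pull_time - s.latency)
        return out

    def y_lift(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for s in specs:
            out += _lift_profile(s.length, s.duration, t - p.pull_time - s.latency)
        return out

    def y_vel(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for s in specs:
            out += _lift_velocity(s.length, s.duration, t - p.pull_time - s.latency)
        return out

    return z_disp, z_vel, y_lift, y_vel


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------


def _bisect(f: Callable[[float], float], lo: float, hi: float, tol: float = 1e-6) -> float:
    flo = f(lo)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if hi - lo < tol:
            break
        if (f(mid) > 0) == (flo > 0):
            lo = mid
            flo = f(mid)
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _true_steps_for_side(p: TrialParams, side: str) -> list[TrueStep]:
    """Threshold crossings of the noiseless resultant ankle speed, solved on
    a 1 kHz grid and refined by bisection to 1e-6 s."""
    z_disp, z_vel, y_lift, y_vel = _ankle_motion(p, side)

    def speed(t):
        t = np.asarray(t, dtype=float)
        vz = pull_velocity(p, t) + z_vel(t)
        vy = -y_vel(t)  # lift is upward = −y
        return np.hypot(vz, vy)

    dense = np.arange(0.0, p.duration, 1e-3)
    s = speed(dense)
    above = s > _STEP_THRESHOLD
    if not above.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    steps = []
    f = lambda t: float(speed(np.array([t]))[0]) - _STEP_THRESHOLD
    for a, b in zip(idx[::2], idx[1::2]):
        start = _bisect(f, dense[a - 1], dense[a]) if a > 0 else dense[0]
        end = _bisect(f, dense[b - 1], dense[min(b, len(dense) - 1)])
        dz = (pull_displacement(p, np.array([end]))[0] + z_disp(np.array([end]))[0]) - (
            pull_displacement(p, np.array([start]))[0] + z_disp(np.array([start]))[0]
        )
        inside = (dense >= start) & (dense <= end)
        steps.append(
            TrueStep(
                side=side,
                start=float(start),
                end=float(end),
                length=float(abs(dz)),
                peak_velocity=float(s[inside].max()),
            )
        )
    return steps


def _ground_truth(p: TrialParams) -> SyntheticGroundTruth:
    true_steps: list[TrueStep] = []
    for side in ("left", "right"):
        found = _true_steps_for_side(p, side)
        n_spec = sum(1 for s in p.steps if s.side == side)
        if len(found) != n_spec:
            raise ValueError(
                f"{side} foot: {n_spec} steps commanded but {len(found)} "
                "threshold-crossing intervals in the noiseless profile "
                "(step too slow/fast or steps merged)"
            )
        true_steps.extend(found)
    true_steps.sort(key=lambda s: s.start)

    ts = p.pull_time + p.tilt_delay
    t_peak = ts + p.tilt_rise
    recovery: float | None = None
    if p.recovers and p.max_tilt < 0:
        # critically-damped return crosses 25% of |max_tilt| where
        # (1+x)·e^{−x} = 1/4, x ≈ 2.6926
        from scipy.optimize import brentq

        x25 = brentq(lambda x: (1 + x) * np.exp(-x) - 0.25, 0.1, 20.0, xtol=1e-12)
        t_angle = t_peak + p.tilt_recovery_tau * x25
        t_rec = max(t_angle, max((s.end for s in true_steps), default=t_angle))
        if t_rec <= p.duration:
            recovery = float(t_rec)
    elif p.recovers and p.max_tilt == 0:
        recovery = float(max((s.end for s in true_steps), default=t_peak))
    return SyntheticGroundTruth(
        onset_time=float(p.pull_time),
        peak_acc=float(p.pull_peak_acc),
        true_steps=tuple(true_steps),
        max_tilt=float(p.max_tilt),
        time_of_max_tilt=float(t_peak),
        recovery_time=recovery,
    )


# --------------------------------------------------------------------------
# Trial generation
# --------------------------------------------------------------------------


def generate_trial(params: TrialParams) -> tuple[Trajectory, SyntheticGroundTruth]:
    """Synthesize one trial; deterministic given ``params.seed``."""
    p = params
    n = int(round(p.duration * p.rate))
    t = np.arange(n) / p.rate
    base = _static_skeleton(p.subject_height)
    xyz = np.broadcast_to(base, (n, *base.shape)).copy()

    # trunk rotation about the static mid-hip, sagittal (y-z) plane
    hip_mid = 0.5 * (
        base[KEYPOINT_INDEX["left_hip"]] + base[KEYPOINT_INDEX["right_hip"]]
    )
    phi = np.radians(tilt_angle(p, t))  # negative = backward
    c, s = np.cos(phi), np.sin(phi)
    for name in _UPPER_BODY:
        j = KEYPOINT_INDEX[name]
        dy = base[j, 1] - hip_mid[1]
        dz = base[j, 2] - hip_mid[2]
        xyz[:, j, 1] = hip_mid[1] + c * dy - s * dz
        xyz[:, j, 2] = hip_mid[2] + s * dy + c * dz

    # stepping: ankle + knee of the stepping side
    for side in ("left", "right"):
        z_disp, _, y_lift, _ = _ankle_motion(p, side)
        dz = z_disp(t)
        dy = y_lift(t)
        ja = KEYPOINT_INDEX[f"{side}_ankle"]
        jk = KEYPOINT_INDEX[f"{side}_knee"]
        xyz[:, ja, 2] += dz
        xyz[:, ja, 1] -= dy
        xyz[:, jk, 2] += _KNEE_FOLLOW * dz
        xyz[:, jk, 1] -= _KNEE_FOLLOW * dy

    # whole-body perturbation translation
    xyz[:, :, 2] += pull_displacement(p, t)[:, None]

    rng = np.random.default_rng(p.seed)
    xyz = xyz + rng.normal(0.0, p.noise_sd, xyz.shape)
    conf = np.ones((n, len(COCO_KEYPOINTS)))
    meta = {
        "synthetic": True,
        "seed": p.seed,
        "subject_height_m": p.subject_height,
        "profile": getattr(p, "_profile", None),
    }
    traj = Trajectory(t, xyz, conf, p.rate, meta)
    return traj, _ground_truth(p)


# --------------------------------------------------------------------------
# Cohort profiles
#
# Phenomenological group profiles: healthy responses take 1-2 long, fast
# corrective steps with a modest backward excursion and quick recovery;
# slightly impaired responses take 3-5 shorter, slower steps with a larger
# excursion but still recover; moderately impaired responses take many
# short steps and fail to recover without assistance. Examiners tend to
# pull patients slightly more softly.
# --------------------------------------------------------------------------


def _clipped_normal(rng, mean, sd, lo, hi):
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _draw_params(profile: str, rng: np.random.Generator, seed: int) -> TrialParams:
    if profile == "healthy":
        n_steps = 1 if rng.random() < 0.3 else 2
        peak_acc = _clipped_normal(rng, 3.0, 0.5, 2.0, 4.2)
        max_tilt = _clipped_normal(rng, -10.5, 2.5, -17.0, -5.0)
        tau = _clipped_normal(rng, 0.40, 0.08, 0.28, 0.60)
        tilt_rise = _clipped_normal(rng, 0.55, 0.05, 0.45, 0.70)
        recovers = True
        lat0 = _clipped_normal(rng, 0.55, 0.08, 0.35, 0.80)
        length0 = _clipped_normal(rng, 0.32, 0.06, 0.22, 0.45)
        peak_speed = (1.5, 0.15, 1.25, 1.85)
        shrink = 0.75
    elif profile == "slight":
        n_steps = int(rng.integers(3, 6))
        peak_acc = _clipped_normal(rng, 2.4, 0.4, 1.8, 3.4)
        max_tilt = _clipped_normal(rng, -14.0, 3.0, -22.0, -8.0)
        tau = _clipped_normal(rng, 0.60, 0.10, 0.40, 0.90)
        tilt_rise = _clipped_normal(rng, 0.65, 0.05, 0.55, 0.80)
        recovers = True
        lat0 = _clipped_normal(rng, 0.45, 0.08, 0.30, 0.70)
        length0 = _clipped_normal(rng, 0.24, 0.04, 0.18, 0.32)
        peak_speed = (1.05, 0.10, 0.90, 1.25)
        shrink = 0.90
    elif profile == "moderate":
        n_steps = int(rng.integers(4, 7))
        peak_acc = _clipped_normal(rng, 2.4, 0.4, 1.8, 3.4)
        max_tilt = _clipped_normal(rng, -18.0, 3.0, -26.0, -10.0)
        tau = 1.0  # irrelevant: no recovery
        tilt_rise = _clipped_normal(rng, 0.70, 0.05, 0.60, 0.85)
        recovers = False
        lat0 = _clipped_normal(rng, 0.45, 0.08, 0.30, 0.70)
        length0 = _clipped_normal(rng, 0.22, 0.03, 0.18, 0.30)
        peak_speed = (1.05, 0.10, 0.90, 1.25)
        shrink = 0.90
    else:
        raise ValueError(f"unknown profile {profile!r}")

    steps: list[StepSpec] = []
    side = "left" if rng.random() < 0.5 else "right"
    latency = lat0
    length = length0
    for _ in range(n_steps):
        # draw the peak ankle speed and derive the duration (T = 1.875·L/v̂):
        # steps are threshold-crossing events by definition, so peaks sit
        # well above the 0.7 m/s segmentation threshold
        v_peak = _clipped_normal(rng, *peak_speed)
        duration = 1.875 * length / v_peak
        steps.append(StepSpec(side, latency, length, duration))
        gap = _clipped_normal(rng, 0.18, 0.04, 0.12, 0.30)
        latency += duration + gap
        length = max(0.18, length * _clipped_normal(rng, shrink, 0.08, 0.6, 1.0))
        side = "right" if side == "left" else "left"

    p = TrialParams(
        subject_height=_clipped_normal(rng, 1.73, 0.09, 1.50, 1.95),
        pull_time=_clipped_normal(rng, 3.0, 0.3, 2.2, 4.0),
        pull_peak_acc=peak_acc,
        max_tilt=max_tilt,
        tilt_rise=tilt_rise,
        tilt_recovery_tau=tau,
        recovers=recovers,
        steps=tuple(steps),
        seed=seed,
    )
    p._profile = profile  # provenance tag picked up by generate_trial meta
    return p


PROFILES = ("healthy", "slight", "moderate")


def cohort_generator(
    profile: str, n: int, seed: int
) -> list[tuple[Trajectory, SyntheticGroundTruth]]:
    """Generate ``n`` seeded trials from one clinical profile.

    Reproducible: the same (profile, n, seed) yields bit-identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        trial_seed = int(rng.integers(0, 2**31 - 1))
        params = _draw_params(profile, rng, trial_seed)
        out.append(generate_trial(params))
    return out
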