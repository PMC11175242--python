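"""Domain types, trajectory file I/O and validation for keypoint time series.

The pipeline's universal input is a :class:`Trajectory`: a timestamped
sequence of COCO-17 skeletons in metric 3D camera coordinates. The
coordinate convention is a right-handed camera frame — x to the
participant's left as seen by the camera (image right), y down, z away
from the camera (depth). The participant faces the camera, so backward
motion is increasing z and vertical up is −y. Units are meters and
seconds everywhere; degrees appear only at reporting boundaries.

A missing keypoint is encoded as all-NaN coordinates with confidence 0 —
unambiguous and serializable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "COCO_KEYPOINTS",
    "REQUIRED_KEYPOINTS",
    "Keypoint3D",
    "SkeletonFrame",
    "Trajectory",
    "AnalysisConfig",
    "CameraIntrinsics",
    "KeypointReport",
    "TrajectoryError",
    "read_trajectory",
    "write_trajectory",
    "read_keypoints_2d",
    "validate_required_keypoints",
]

# Canonical COCO 17-keypoint schema. Files use these names, never indices:
# index-order bugs are the dominant failure mode in pose pipelines.
COCO_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)
KEYPOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(COCO_KEYPOINTS)}

# Landmarks the analysis actually consumes: bilateral shoulders (pull),
# hips (trunk angle) and ankles (stepping response).
REQUIRED_KEYPOINTS: tuple[str, ...] = (
    "left_shoulder",
    "right_shoulder",
    "left_hip",
    "right_hip",
    "left_ankle",
    "right_ankle",
)


class TrajectoryError(ValueError):
    """Malformed or invalid trajectory data."""


@dataclass(frozen=True)
class Keypoint3D:
    """One keypoint: metric camera coordinates plus detector confidence."""

    x: float
    y: float
    z: float
    confidence: float = 1.0

    @property
    def missing(self) -> bool:
        return not (
            np.isfinite(self.x) and np.isfinite(self.y) and np.isfinite(self.z)
        )

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise TrajectoryError(
                f"confidence must be in [0, 1], got {self.confidence}"
            )


@dataclass(frozen=True)
class SkeletonFrame:
    """A full 17-keypoint skeleton at one instant."""

    time: float
    keypoints: Mapping[str, Keypoint3D]

    def __post_init__(self) -> None:
        if self.time < 0:
            raise TrajectoryError(f"frame time must be >= 0, got {self.time}")
        unknown = set(self.keypoints) - set(COCO_KEYPOINTS)
        if unknown:
            raise TrajectoryError(f"unknown keypoint names: {sorted(unknown)}")


MISSING = Keypoint3D(np.nan, np.nan, np.nan, 0.0)


@dataclass
class Trajectory:
    """Ordered keypoint time series backed by dense numpy arrays.

    Attributes
    ----------
    times : (n,) array of seconds from recording start, strictly increasing.
    xyz : (n, 17, 3) array of camera-frame coordinates in meters; a missing
        keypoint is all-NaN in its row.
    confidence : (n, 17) array in [0, 1]; 0 where missing.
    nominal_rate : nominal sampling rate in Hz (30 for the RGB-D sensor).
    meta : free-form provenance (subject id, examiner id, trial id, ...).
    """

    times: np.ndarray
    xyz: np.ndarray
    confidence: np.ndarray
    nominal_rate: float = 30.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        n = self.times.shape[0]
        if self.xyz.shape != (n, len(COCO_KEYPOINTS), 3):
            raise TrajectoryError(
                f"xyz shape {self.xyz.shape} != ({n}, 17, 3)"
            )
        if self.confidence.shape != (n, len(COCO_KEYPOINTS)):
            raise TrajectoryError(
                f"confidence shape {self.confidence.shape} != ({n}, 17)"
            )
        if n and self.times[0] < 0:
            raise TrajectoryError("frame times must be >= 0")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            bad = int(np.argmin(np.diff(self.times)))
            raise TrajectoryError(
                f"frame times must be strictly increasing (violation near row {bad + 1})"
            )
        if self.nominal_rate <= 0:
            raise TrajectoryError("nominal_rate must be positive")
        # Normalise partial NaNs: any non-finite coordinate flags the whole
        # keypoint missing.
        bad = ~np.all(np.isfinite(self.xyz), axis=2)
        self.xyz[bad] = np.nan
        self.confidence[bad] = 0.0
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise TrajectoryError("confidence values must lie in [0, 1]")

    # -- construction / viewing -------------------------------------------

    @classmethod
    def from_frames(
        cls,
        frames: Iterable[SkeletonFrame],
        nominal_rate: float = 30.0,
        meta: dict | None = None,
    ) -> "Trajectory":
        frames = list(frames)
        n = len(frames)
        times = np.array([f.time for f in frames], dtype=float)
        xyz = np.full((n, len(COCO_KEYPOINTS), 3), np.nan)
        conf = np.zeros((n, len(COCO_KEYPOINTS)))
        for i, f in enumerate(frames):
            for name, kp in f.keypoints.items():
                j = KEYPOINT_INDEX[name]
                if not kp.missing:
                    xyz[i, j] = (kp.x, kp.y, kp.z)
                    conf[i, j] = kp.confidence
        return cls(times, xyz, conf, nominal_rate, meta or {})

    def frame(self, i: int) -> SkeletonFrame:
        kps = {}
        for name, j in KEYPOINT_INDEX.items():
            x, y, z = self.xyz[i, j]
            kps[name] = Keypoint3D(x, y, z, float(self.confidence[i, j]))
        return SkeletonFrame(float(self.times[i]), kps)

    @property
    def n_frames(self) -> int:
        return int(self.times.shape[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.n_frames > 1 else 0.0

    def keypoint(self, name: str) -> np.ndarray:
        """(n, 3) view of one keypoint's coordinates."""
        return self.xyz[:, KEYPOINT_INDEX[name], :]

    def present(self, name: str) -> np.ndarray:
        """(n,) boolean mask: keypoint has finite coordinates at the frame."""
        return np.all(np.isfinite(self.keypoint(name)), axis=1)

    def copy(self) -> "Trajectory":
        return Trajectory(
            self.times.copy(),
            self.xyz.copy(),
            self.confidence.copy(),
            self.nominal_rate,
            dict(self.meta),
        )


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera intrinsics (pixels)."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")


@dataclass
class AnalysisConfig:
    """All tunable constants of the analysis pipeline.

    The clinically established values: a 4th-order Butterworth low-pass at
    7 Hz for trajectory smoothing, pull onset threshold 3 SD above a 1 s
    quiet-stance baseline, step velocity threshold 0.7 m/s, and balance
    recovery at a 75% reduction of the backward bending angle. The
    remaining fields are implementation plumbing: a search window for the
    pull peak, minimum step duration and sub-threshold merge gap to
    suppress spurious threshold crossings at 30 Hz, and confidence/gap
    limits for input validation.
    """

    filter_order: int = 4
    filter_cutoff: float = 7.0  # Hz
    baseline_window: float = 1.0  # s
    onset_sd_multiplier: float = 3.0
    step_velocity_threshold: float = 0.7  # m/s
    recovery_fraction: float = 0.75
    pull_peak_window: float = 1.0  # s
    min_step_duration: float = 0.100  # s
    step_merge_gap: float = 0.067  # s (2 frames at 30 Hz)
    confidence_floor: float = 0.3
    max_gap_interp: int = 5  # frames

    def __post_init__(self) -> None:
        positive = (
            "filter_order",
            "filter_cutoff",
            "baseline_window",
            "onset_sd_multiplier",
            "step_velocity_threshold",
            "pull_peak_window",
            "min_step_duration",
            "step_merge_gap",
            "max_gap_interp",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.recovery_fraction < 1.0):
            raise ValueError("recovery_fraction must lie in (0, 1)")
        if not (0.0 <= self.confidence_floor <= 1.0):
            raise ValueError("confidence_floor must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "AnalysisConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {k: v for k, v in mapping.items()}
        if "filter_order" in kwargs:
            kwargs["filter_order"] = int(kwargs["filter_order"])
        if "max_gap_interp" in kwargs:
            kwargs["max_gap_interp"] = int(kwargs["max_gap_interp"])
        numeric = known - {"filter_order", "max_gap_interp"}
        for k in list(kwargs):
            if k in numeric:
                kwargs[k] = float(kwargs[k])  # type: ignore[arg-type]
        return cls(**kwargs)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# File I/O
#
# CSV long dialect: header time_s,keypoint,x_m,y_m,z_m,confidence; one row
# per (frame, keypoint); missing keypoints have empty coordinate fields.
# JSON dialect: {"meta": {...}, "rate_hz": 30, "frames":
#   [{"t": 0.0, "kp": {"left_shoulder": [x, y, z, c], ...}}, ...]};
# missing keypoints are simply absent from "kp".
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["time_s", "keypoint", "x_m", "y_m", "z_m", "confidence"]
_CSV_2D_COLUMNS = ["time_s", "keypoint", "u_px", "v_px", "confidence", "depth_m"]


def _infer_dialect(path: Path) -> str:
    return "json" if path.suffix.lower() == ".json" else "csv-long"


def read_trajectory(
    path: str | Path,
    dialect: str | None = None,
    nominal_rate: float = 30.0,
) -> Trajectory:
    """Read a trajectory file (``csv-long`` or ``json`` dialect).

    The dialect is inferred from the file extension when not given. Rows
    are sorted by time; duplicated timestamps or unknown keypoint names
    raise :class:`TrajectoryError` naming the offending value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "json":
        return _read_json(path)
    if dialect == "csv-long":
        return _read_csv_long(path, nominal_rate)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv_long(path: Path, nominal_rate: float) -> Trajectory:
    try:
        df = pd.read_csv(path, dtype={"keypoint": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TrajectoryError(f"{path}: cannot parse CSV: {exc}") from exc
    missing_cols = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrajectoryError(f"{path}: missing columns {missing_cols}")
    unknown = set(df["keypoint"].unique()) - set(COCO_KEYPOINTS)
    if unknown:
        raise TrajectoryError(f"{path}: unknown keypoint names {sorted(unknown)}")
    if df["time_s"].isna().any():
        row = int(df.index[df["time_s"].isna()][0])
        raise TrajectoryError(f"{path}: missing time_s at data row {row}")

    times = np.array(sorted(df["time_s"].unique()), dtype=float)
    if len(times) > 1 and np.min(np.diff(times)) <= 0:
        raise TrajectoryError(f"{path}: non-monotone timestamps")
    dup = df.duplicated(subset=["time_s", "keypoint"])
    if dup.any():
        row = int(df.index[dup][0])
        raise TrajectoryError(
            f"{path}: duplicated (time_s, keypoint) at data row {row}"
        )
    t_index = {t: i for i, t in enumerate(times)}
    n = len(times)
    xyz = np.full((n, len(COCO_KEYPOINTS), 3), np.nan)
    conf = np.zeros((n, len(COCO_KEYPOINTS)))
    rows_i = df["time_s"].map(t_index).to_numpy()
    rows_j = df["keypoint"].map(KEYPOINT_INDEX).to_numpy()
    coords = df[["x_m", "y_m", "z_m"]].to_numpy(dtype=float)
    c = df["confidence"].to_numpy(dtype=float)
    c = np.where(np.isnan(c), 0.0, c)
    xyz[rows_i, rows_j] = coords
    conf[rows_i, rows_j] = c
    return Trajectory(times, xyz, conf, nominal_rate)


def _read_json(path: Path) -> Trajectory:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise TrajectoryError(f"{path}: invalid JSON: {exc}") from exc
    try:
        frames = payload["frames"]
        rate = float(payload.get("rate_hz", 30.0))
        meta = dict(payload.get("meta", {}))
    except (KeyError, TypeError) as exc:
        raise TrajectoryError(f"{path}: missing 'frames' field") from exc
    n = len(frames)
    times = np.empty(n)
    xyz = np.full((n, len(COCO_KEYPOINTS), 3), np.nan)
    conf = np.zeros((n, len(COCO_KEYPOINTS)))
    for i, fr in enumerate(frames):
        try:
            times[i] = float(fr["t"])
            kp = fr.get("kp", {})
        except (KeyError, TypeError) as exc:
            raise TrajectoryError(f"{path}: malformed frame {i}") from exc
        for name, vals in kp.items():
            if name not in KEYPOINT_INDEX:
                raise TrajectoryError(f"{path}: unknown keypoint {name!r} in frame {i}")
            j = KEYPOINT_INDEX[name]
            x, y, z, c = (float(v) if v is not None else np.nan for v in vals)
            xyz[i, j] = (x, y, z)
            conf[i, j] = 0.0 if np.isnan(c) else c
    if n > 1 and np.min(np.diff(times)) <= 0:
        raise TrajectoryError(f"{path}: non-monotone timestamps")
    return Trajectory(times, xyz, conf, rate, meta)


def write_trajectory(
    traj: Trajectory, path: str | Path, dialect: str | None = None
) -> Path:
    """Write a trajectory; lossless round trip to 1e-9 m for finite values."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "json":
        frames = []
        for i in range(traj.n_frames):
            kp = {}
            for name, j in KEYPOINT_INDEX.items():
                row = traj.xyz[i, j]
                if np.all(np.isfinite(row)):
                    kp[name] = [
                        float(row[0]),
                        float(row[1]),
                        float(row[2]),
                        float(traj.confidence[i, j]),
                    ]
            frames.append({"t": float(traj.times[i]), "kp": kp})
        payload = {
            "meta": traj.meta,
            "rate_hz": traj.nominal_rate,
            "frames": frames,
        }
        path.write_text(json.dumps(payload))
        return path
    if dialect == "csv-long":
        n = traj.n_frames
        k = len(COCO_KEYPOINTS)
        out = pd.DataFrame(
            {
                "time_s": np.repeat(traj.times, k),
                "keypoint": np.tile(COCO_KEYPOINTS, n),
                "x_m": traj.xyz[:, :, 0].ravel(),
                "y_m": traj.xyz[:, :, 1].ravel(),
                "z_m": traj.xyz[:, :, 2].ravel(),
                "confidence": traj.confidence.ravel(),
            }
        )
        # missing keypoints -> empty coordinate fields
        out.to_csv(path, index=False, float_format="%.12g", na_rep="")
        return path
    raise ValueError(f"unknown dialect {dialect!r}")


def read_keypoints_2d(path: str | Path) -> pd.DataFrame:
    """Read the 2D-plus-depth dialect: time_s,keypoint,u_px,v_px,confidence,depth_m.

    Depth is pre-sampled at the keypoint pixel (raw depth-image decoding is
    out of scope). Returns a validated long-format DataFrame; use
    :func:`vpull.preprocess.project_trajectory` to lift it to 3D.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"keypoint": str})
    missing_cols = [c for c in _CSV_2D_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrajectoryError(f"{path}: missing columns {missing_cols}")
    unknown = set(df["keypoint"].unique()) - set(COCO_KEYPOINTS)
    if unknown:
        raise TrajectoryError(f"{path}: unknown keypoint names {sorted(unknown)}")
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KeypointReport:
    """Per-required-keypoint availability summary."""

    fraction_present: dict[str, float]
    longest_gap: dict[str, int]  # frames
    usable: bool


def validate_required_keypoints(
    traj: Trajectory, cfg: AnalysisConfig | None = None
) -> KeypointReport:
    """Report availability of the landmarks the analysis needs.

    A keypoint counts as present at a frame when its coordinates are
    finite and its confidence is at least ``cfg.confidence_floor``. The
    trajectory is flagged unusable if any required keypoint has a run of
    more than ``cfg.max_gap_interp`` consecutive absent frames (such gaps
    are too long to interpolate).
    """
    cfg = cfg or AnalysisConfig()
    fractions: dict[str, float] = {}
    gaps: dict[str, int] = {}
    usable = True
    n = traj.n_frames
    for name in REQUIRED_KEYPOINTS:
        present = traj.present(name) & (
            traj.confidence[:, KEYPOINT_INDEX[name]] >= cfg.confidence_floor
        )
        fractions[name] = float(present.mean()) if n else 0.0
        longest = run = 0
        for p in present:
            run = 0 if p else run + 1
            longest = max(longest, run)
        if n == 0:
            longest = 0
        gaps[name] = longest
        if longest > cfg.max_gap_interp or n == 0:
            usable = False
    return KeypointReport(fractions, gaps, usable)
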