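"""Per-user display calibration workflow and multi-marker pose resolution.

An optical see-through HMD renders each eye through a default projection
matrix whose eye position only approximates the wearer's.  The per-user
calibration session shows a virtual reticle at a sequence of known 3D
positions in the display (eye) frame; for each, the user aligns a tracked
physical marker with the reticle and confirms, yielding one 3D-3D point
correspondence (marker centroid in the tracking-camera frame vs reticle
position in the eye frame) per confirmation and per eye.  The camera-to-eye
offset is then the least-squares rigid transform between the two point sets,
estimated independently per eye, and is applied as a right-multiplied
correction to each default projection matrix.

The module also resolves the pose of a pre-constructed rigid fiducial
configuration (four square markers with known relative poses) from any subset
of at least two detected markers, by stacking the marker corner points and
solving the same rigid alignment problem.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import (
    DegenerateConfigurationError,
    IncompleteSessionError,
    InsufficientCorrespondencesError,
    InsufficientMarkersError,
)
from .rigid_geometry import (
    CorrespondenceSet,
    ProjectionMatrix,
    RigidTransform3D,
    compose,
    correct_projection,
    estimate_rigid_transform,
)

__all__ = [
    "FRUSTUM_FOV_DEG",
    "Observation",
    "CalibrationSession",
    "CalibrationResult",
    "FiducialConfiguration",
    "default_reticle_positions",
    "run_session",
    "calibrate",
    "resolve_object_pose",
    "save_session_json",
    "load_session_json",
    "save_result_json",
]

#: Display field of view (horizontal, vertical) in degrees.
FRUSTUM_FOV_DEG = (43.0, 29.0)

DEFAULT_N_TARGET = 10


@dataclass(frozen=True)
class Observation:
    """One confirm event: a tracked-marker centroid seen while a reticle is shown."""

    eye: str  # "left" | "right"
    point: np.ndarray  # marker centroid, camera frame, meters
    timestamp_s: float

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))


@dataclass
class CalibrationSession:
    """Collected reticle/marker correspondences for both eyes plus timing."""

    reticle_positions: np.ndarray  # (n_target, 3), eye/display frame, meters
    collected: dict[str, CorrespondenceSet]
    timestamps: dict[str, list[float]]
    n_target: int = DEFAULT_N_TARGET

    def __post_init__(self):
        if self.n_target < 3:
            raise ValueError("n_target must be at least 3")
        for eye, cs in self.collected.items():
            if len(cs) > self.n_target:
                raise ValueError(f"{eye}: more pairs than n_target")
            ts = self.timestamps.get(eye, [])
            if any(b < a for a, b in zip(ts, ts[1:])):
                raise ValueError(f"{eye}: timestamps not non-decreasing")


@dataclass
class CalibrationResult:
    left_offset: RigidTransform3D
    right_offset: RigidTransform3D
    left_P: ProjectionMatrix
    right_P: ProjectionMatrix
    rms_residual_mm: dict[str, float]
    calibration_time_s: float

    def __post_init__(self):
        if any(v < 0 for v in self.rms_residual_mm.values()):
            raise ValueError("negative residual")
        if self.calibration_time_s <= 0:
            raise ValueError("calibration time must be positive")


def default_reticle_positions(
    n: int = DEFAULT_N_TARGET,
    depths: tuple[float, float] = (0.4, 0.6),
    frustum_fraction: float = 2.0 / 3.0,
) -> np.ndarray:
    """Reticle layout: two depth planes with corner + center positions.

    Positions span the central ``frustum_fraction`` of the display frustum
    (43 x 29 degrees) at depths covering the peri-personal workspace; the
    depth spread is what conditions the 3D rigid fit.  For n = 10 this is the
    four corners plus the center at each of two depths.
    """
    hx = math.tan(math.radians(FRUSTUM_FOV_DEG[0] / 2)) * frustum_fraction
    hy = math.tan(math.radians(FRUSTUM_FOV_DEG[1] / 2)) * frustum_fraction
    base = np.array([(-1, -1), (1, -1), (1, 1), (-1, 1), (0, 0)], dtype=float)
    pts = []
    i = 0
    while len(pts) < n:
        z = depths[0] if (i // len(base)) % 2 == 0 else depths[1]
        scale = 1.0 / (1 + (i // (2 * len(base))))  # shrink on extra cycles
        ux, uy = base[i % len(base)]
        pts.append([ux * hx * z * scale, uy * hy * z * scale, z])
        i += 1
    return np.array(pts[:n])


def in_frustum(point_eye: np.ndarray) -> bool:
    """Whether an eye-frame point lies inside the display field of view."""
    x, y, z = point_eye
    if z <= 0:
        return False
    return (
        abs(x) <= math.tan(math.radians(FRUSTUM_FOV_DEG[0] / 2)) * z
        and abs(y) <= math.tan(math.radians(FRUSTUM_FOV_DEG[1] / 2)) * z
    )


def run_session(
    reticle_positions: np.ndarray,
    observations: Iterable[Observation] | Iterator[Observation],
    n_target: int | None = None,
    warn: bool = True,
) -> CalibrationSession:
    """Accumulate reticle/marker correspondences from a confirm-event stream.

    Observations are consumed in presentation order; the i-th confirmed
    observation for an eye pairs with the i-th reticle position.  A reticle
    position outside the display frustum triggers a warning but the pair is
    still accepted (the user may genuinely misalign).  The session is complete
    once every eye seen in the stream has ``n_target`` pairs.

    Raises
    ------
    IncompleteSessionError
        If the stream ends before any eye reaches ``n_target`` pairs.
    """
    import warnings

    reticle_positions = np.atleast_2d(np.asarray(reticle_positions, dtype=float))
    n_target = n_target if n_target is not None else len(reticle_positions)
    if n_target < 3:
        raise ValueError("n_target must be at least 3")
    if len(reticle_positions) < n_target:
        raise ValueError("fewer reticle positions than n_target")

    if warn:
        for i, r in enumerate(reticle_positions[:n_target]):
            if not in_frustum(r):
                warnings.warn(f"reticle position {i} outside the display frustum")

    pairs: dict[str, list[np.ndarray]] = {}
    times: dict[str, list[float]] = {}
    for obs in observations:
        got = pairs.setdefault(obs.eye, [])
        if len(got) >= n_target:
            continue
        got.append(obs.point)
        times.setdefault(obs.eye, []).append(obs.timestamp_s)

    if not pairs or any(len(v) < n_target for v in pairs.values()):
        counts = {k: len(v) for k, v in pairs.items()} or {"(none)": 0}
        raise IncompleteSessionError(
            f"stream ended with {counts} of {n_target} pairs collected"
        )

    collected = {
        eye: CorrespondenceSet(
            np.array(v), reticle_positions[: len(v)], eye_label=eye
        )
        for eye, v in pairs.items()
    }
    return CalibrationSession(reticle_positions, collected, times, n_target)


def calibrate(
    session: CalibrationSession,
    defaults: dict[str, ProjectionMatrix],
) -> CalibrationResult:
    """Estimate per-eye camera-to-eye offsets and corrected projection matrices.

    Each eye is calibrated independently: the offset is the least-squares
    rigid transform taking observed marker centroids (camera frame) to reticle
    positions (eye frame); the corrected projection is the default projection
    right-multiplied by that offset.  A degenerate or under-determined eye
    aborts the whole calibration — partial stereo correction is perceptually
    worse than none.
    """
    offsets: dict[str, RigidTransform3D] = {}
    corrected: dict[str, ProjectionMatrix] = {}
    residuals: dict[str, float] = {}
    for eye in ("left", "right"):
        cs = session.collected.get(eye)
        if cs is None:
            raise InsufficientCorrespondencesError(f"{eye} eye: no pairs collected")
        try:
            offset, report = estimate_rigid_transform(cs)
        except (InsufficientCorrespondencesError, DegenerateConfigurationError) as e:
            raise type(e)(f"{eye} eye: {e}") from e
        offsets[eye] = offset
        corrected[eye] = correct_projection(defaults[eye], offset)
        residuals[eye] = report.rms_residual * 1000.0  # m -> mm

    ts = [t for eye in session.timestamps.values() for t in eye]
    duration = (max(ts) - min(ts)) if len(ts) >= 2 else 0.0
    return CalibrationResult(
        left_offset=offsets["left"],
        right_offset=offsets["right"],
        left_P=corrected["left"],
        right_P=corrected["right"],
        rms_residual_mm=residuals,
        calibration_time_s=max(duration, 1e-6),
    )


# ---------------------------------------------------------------------------
# Fiducial configuration pose resolution


@dataclass
class FiducialConfiguration:
    """Four labelled square markers at known poses relative to one object frame."""

    markers: dict[str, RigidTransform3D]  # label -> marker-to-object pose
    marker_side_mm: float = 50.0

    def __post_init__(self):
        if len(self.markers) != 4:
            raise ValueError("exactly 4 labelled markers required")
        if self.marker_side_mm <= 0:
            raise ValueError("marker side must be positive")

    def corner_points_local(self) -> np.ndarray:
        """Square corner points in a marker's own frame (meters, z = 0)."""
        h = self.marker_side_mm / 2000.0  # mm -> m, half-side
        return np.array([[-h, -h, 0], [h, -h, 0], [h, h, 0], [-h, h, 0]])


def resolve_object_pose(
    config: FiducialConfiguration,
    detected: dict[str, RigidTransform3D],
) -> RigidTransform3D:
    """Object-to-camera pose from >= 2 detected markers of the configuration.

    Each detected marker contributes its four corner points, expressed once in
    the object frame (through the configured marker-to-object pose) and once
    in the camera frame (through the detected marker-to-camera pose); the
    object pose is the rigid transform aligning the stacked object-frame
    corners to the stacked camera-frame corners.  Requiring only two of the
    four markers keeps the alignment robust to occlusion.

    Raises
    ------
    InsufficientMarkersError
        Fewer than two detected markers match the configuration labels.
    """
    labels = [lab for lab in detected if lab in config.markers]
    if len(labels) < 2:
        raise InsufficientMarkersError(
            f"{len(labels)} configured marker(s) detected; need at least 2"
        )
    local = config.corner_points_local()
    obj_pts = np.vstack([config.markers[lab].apply(local) for lab in labels])
    cam_pts = np.vstack([detected[lab].apply(local) for lab in labels])
    pose, _ = estimate_rigid_transform(
        CorrespondenceSet(obj_pts, cam_pts, eye_label="object")
    )
    return RigidTransform3D(
        pose.rotation, pose.translation, frame_from="object", frame_to="camera"
    )


def simulate_marker_detections(
    config: FiducialConfiguration,
    object_pose: RigidTransform3D,
    labels: Iterable[str] | None = None,
) -> dict[str, RigidTransform3D]:
    """Noise-free marker-to-camera poses implied by an object pose (testing aid)."""
    labels = list(labels) if labels is not None else list(config.markers)
    return {lab: compose(object_pose, config.markers[lab]) for lab in labels}


# ---------------------------------------------------------------------------
# File interfaces


def save_session_json(session: CalibrationSession, path: str | Path) -> None:
    payload = {
        "n_target": session.n_target,
        "reticle_positions_m": session.reticle_positions.tolist(),
        "eyes": {
            eye: {
                "source_m": cs.source.tolist(),
                "target_m": cs.target.tolist(),
                "timestamps_s": session.timestamps.get(eye, []),
            }
            for eye, cs in session.collected.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_session_json(path: str | Path) -> CalibrationSession:
    d = json.loads(Path(path).read_text())
    collected = {
        eye: CorrespondenceSet(
            np.array(v["source_m"]), np.array(v["target_m"]), eye_label=eye
        )
        for eye, v in d["eyes"].items()
    }
    times = {eye: list(v["timestamps_s"]) for eye, v in d["eyes"].items()}
    return CalibrationSession(
        np.array(d["reticle_positions_m"]), collected, times, d["n_target"]
    )


def save_result_json(result: CalibrationResult, path: str | Path) -> None:
    def tf(t: RigidTransform3D):
        return {
            "rotation": [float(x) for x in t.rotation.ravel()],
            "translation_m": [float(x) for x in t.translation],
        }

    payload = {
        "left_offset": tf(result.left_offset),
        "right_offset": tf(result.right_offset),
        "left_P": [float(x) for x in result.left_P.P.ravel()],
        "right_P": [float(x) for x in result.right_P.P.ravel()],
        "rms_residual_mm": result.rms_residual_mm,
        "calibration_time_s": result.calibration_time_s,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
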