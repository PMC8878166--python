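"""Core 3D geometry: pinhole projection, least-squares rigid alignment, projection correction.

The central primitive is the estimation of the rigid transform (rotation +
translation) that best maps one 3D point set onto a corresponding one in the
least-squares sense, solved in closed form via the singular value decomposition
of the cross-covariance matrix with an explicit determinant correction so the
result is always a proper rotation (never a reflection).  This transform is the
camera-to-eye offset of an optical see-through display calibration, and it is
applied as a right-multiplied correction to the display's default 3x4
projection matrices.

Conventions
-----------
Right-handed coordinates; the camera looks down +z; image origin is the top
left corner with u rightward and v downward.  3D quantities are in meters,
image quantities in pixels.  Points are column vectors and transforms
premultiply, so the corrected projection is ``P = P_default @ T``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    BehindCameraError,
    DegenerateConfigurationError,
    InsufficientCorrespondencesError,
)

__all__ = [
    "RigidTransform3D",
    "CameraModel",
    "ProjectionMatrix",
    "CorrespondenceSet",
    "RigidFitReport",
    "project",
    "estimate_rigid_transform",
    "correct_projection",
    "compose",
    "invert",
    "load_transform_json",
    "save_transform_json",
    "load_correspondences_csv",
    "save_correspondences_csv",
]

_ORTHO_TOL = 1e-9
_DEGENERACY_RTOL = 1e-10  # second singular value relative to the largest
_DET_TIE_TOL = 1e-12


@dataclass(frozen=True)
class RigidTransform3D:
    """A proper rigid transform: ``x -> rotation @ x + translation`` (meters)."""

    rotation: np.ndarray
    translation: np.ndarray
    frame_from: str = ""
    frame_to: str = ""

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite transform components")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation determinant is not +1 (reflection?)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls, frame_from: str = "", frame_to: str = "") -> "RigidTransform3D":
        return cls(np.eye(3), np.zeros(3), frame_from, frame_to)

    @classmethod
    def from_matrix(cls, T: np.ndarray, **kw) -> "RigidTransform3D":
        T = np.asarray(T, dtype=float)
        return cls(T[:3, :3], T[:3, 3], **kw)

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous form."""
        T = np.eye(4)
        T[:3, :3] = self.rotation
        T[:3, 3] = self.translation
        return T

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array or a single 3-vector."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            np.max(np.abs(self.rotation - np.eye(3))) <= tol
            and np.max(np.abs(self.translation)) <= tol
        )


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics; focal lengths and principal point in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    s: float = 0.0
    width: int = 896
    height: int = 504

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx <= self.width and 0 <= self.cy <= self.height):
            raise ValueError("principal point outside the sensor")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, self.s, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    def projection(self, extrinsics: RigidTransform3D | None = None) -> "ProjectionMatrix":
        """``[K | 0]`` composed with optional extrinsics (world-to-camera)."""
        P = self.K @ np.hstack([np.eye(3), np.zeros((3, 1))])
        out = ProjectionMatrix(P)
        if extrinsics is not None:
            out = correct_projection(out, extrinsics)
        return out


@dataclass(frozen=True)
class ProjectionMatrix:
    """A 3x4 projection; the left 3x3 block must have full rank."""

    P: np.ndarray

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float).reshape(3, 4)
        if np.linalg.matrix_rank(P[:, :3]) != 3:
            raise ValueError("projection 3x3 block is rank deficient")
        object.__setattr__(self, "P", P)

    def project(self, point: Sequence[float]) -> np.ndarray:
        """Project a 3D point (homogeneous division); raises behind-camera on w<=0."""
        xh = np.append(np.asarray(point, dtype=float), 1.0)
        u = self.P @ xh
        if u[2] <= 0:
            raise BehindCameraError("point projects with non-positive depth")
        return u[:2] / u[2]


@dataclass
class CorrespondenceSet:
    """Paired 3D points: tracked-marker centroids (source) vs reticle positions (target)."""

    source: np.ndarray
    target: np.ndarray
    eye_label: str = "left"

    def __post_init__(self):
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.source.shape != self.target.shape or self.source.shape[1] != 3:
            raise ValueError("source/target must be matching (N, 3) arrays")
        if len(self.source) < 1:
            raise ValueError("at least one pair required")
        if len(np.unique(self.source, axis=0)) != len(self.source):
            raise ValueError("duplicate source points")

    def __len__(self) -> int:
        return len(self.source)


@dataclass
class RigidFitReport:
    """Residual diagnostics of a least-squares rigid fit."""

    per_pair_residuals: np.ndarray  # Euclidean residual per pair, meters
    rms_residual: float  # meters
    n_pairs: int = field(default=0)


def project(
    camera: CameraModel, extrinsics: RigidTransform3D, point: Sequence[float]
) -> np.ndarray:
    """Pinhole projection of a world point to image pixels.

    The point is first mapped into the camera frame by ``extrinsics``; the
    camera-frame point ``(xc, yc, zc)`` then projects to
    ``u = (fx*xc + s*yc)/zc + cx`` and ``v = fy*yc/zc + cy``.

    Raises
    ------
    BehindCameraError
        If the camera-frame depth ``zc`` is not positive.
    """
    pc = extrinsics.apply(np.asarray(point, dtype=float))
    if pc[2] <= 0:
        raise BehindCameraError(f"camera-frame depth {pc[2]:.4g} <= 0")
    u = (camera.fx * pc[0] + camera.s * pc[1]) / pc[2] + camera.cx
    v = camera.fy * pc[1] / pc[2] + camera.cy
    return np.array([u, v])


def estimate_rigid_transform(
    corr: CorrespondenceSet,
) -> tuple[RigidTransform3D, RigidFitReport]:
    """Least-squares rigid alignment of corresponding 3D point sets (Kabsch/SVD).

    Minimizes ``sum_i || R a_i + t - b_i ||^2`` over proper rotations R and
    translations t, where ``a`` is the source set and ``b`` the target set.
    Both sets are centered on their centroids, the 3x3 cross-covariance
    ``H = sum_i (b_i - c_b)(a_i - c_a)^T`` is factorized as ``H = U S V^T``,
    and the rotation is ``R = U diag(1, 1, d) V^T`` with ``d = det(U V^T)``.
    The determinant factor forces a proper rotation when the unconstrained
    orthogonal optimum would be a reflection.  The translation is
    ``t = c_b - R c_a``.

    Returns the transform and a residual report (per-pair Euclidean residuals
    and their RMS).

    Raises
    ------
    InsufficientCorrespondencesError
        Fewer than 3 pairs: the rigid solution is not unique.
    DegenerateConfigurationError
        Collinear source points, or a cross-covariance whose determinant
        branch is numerically undefined.
    """
    a = corr.source
    b = corr.target
    n = len(a)
    if n < 3:
        raise InsufficientCorrespondencesError(
            f"{n} pair(s) supplied; a unique rigid transform needs at least 3"
        )
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb

    # Collinear source points leave a rotation about the line unconstrained.
    sv = np.linalg.svd(a0, compute_uv=False)
    if sv[1] < _DEGENERACY_RTOL * sv[0]:
        raise DegenerateConfigurationError("source points are (near-)collinear")

    H = b0.T @ a0
    U, S, Vt = np.linalg.svd(H)
    X = U @ Vt
    d = np.linalg.det(X)
    if abs(d) < _DET_TIE_TOL:
        raise DegenerateConfigurationError("rank-deficient cross-covariance")
    d = 1.0 if d > 0 else -1.0
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = cb - R @ ca

    transform = RigidTransform3D(R, t)
    res = np.linalg.norm(transform.apply(a) - b, axis=1)
    report = RigidFitReport(
        per_pair_residuals=res,
        rms_residual=float(np.sqrt(np.mean(res**2))),
        n_pairs=n,
    )
    return transform, report


def correct_projection(
    default: ProjectionMatrix, offset: RigidTransform3D
) -> ProjectionMatrix:
    """Apply a rigid eye-offset correction to a default projection: ``P = P_default @ T``."""
    return ProjectionMatrix(default.P @ offset.as_matrix())


def compose(t1: RigidTransform3D, t2: RigidTransform3D) -> RigidTransform3D:
    """``compose(t1, t2)`` applies t2 first, then t1 (matrix order ``T1 @ T2``)."""
    return RigidTransform3D(
        t1.rotation @ t2.rotation,
        t1.rotation @ t2.translation + t1.translation,
        frame_from=t2.frame_from,
        frame_to=t1.frame_to,
    )


def invert(t: RigidTransform3D) -> RigidTransform3D:
    Rt = t.rotation.T
    return RigidTransform3D(
        Rt, -Rt @ t.translation, frame_from=t.frame_to, frame_to=t.frame_from
    )


# ---------------------------------------------------------------------------
# File interfaces


def save_transform_json(t: RigidTransform3D, path: str | Path) -> None:
    payload = {
        "rotation": [float(x) for x in t.rotation.ravel()],  # row-major
        "translation_m": [float(x) for x in t.translation],
        "frame_from": t.frame_from,
        "frame_to": t.frame_to,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_transform_json(path: str | Path) -> RigidTransform3D:
    d = json.loads(Path(path).read_text())
    return RigidTransform3D(
        np.array(d["rotation"], dtype=float).reshape(3, 3),
        np.array(d["translation_m"], dtype=float),
        frame_from=d.get("frame_from", ""),
        frame_to=d.get("frame_to", ""),
    )


def save_correspondences_csv(
    sets: Iterable[CorrespondenceSet], path: str | Path
) -> None:
    lines = ["eye,src_x,src_y,src_z,dst_x,dst_y,dst_z"]
    for cs in sets:
        for s, t in zip(cs.source, cs.target):
            lines.append(
                f"{cs.eye_label},{s[0]:.9g},{s[1]:.9g},{s[2]:.9g},"
                f"{t[0]:.9g},{t[1]:.9g},{t[2]:.9g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def load_correspondences_csv(path: str | Path) -> dict[str, CorrespondenceSet]:
    """Read per-eye correspondence sets keyed by eye label."""
    import csv

    rows: dict[str, list[tuple[list[float], list[float]]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            src = [float(row[k]) for k in ("src_x", "src_y", "src_z")]
            dst = [float(row[k]) for k in ("dst_x", "dst_y", "dst_z")]
            rows.setdefault(row["eye"], []).append((src, dst))
    return {
        eye: CorrespondenceSet(
            np.array([p[0] for p in pairs]),
            np.array([p[1] for p in pairs]),
            eye_label=eye,
        )
        for eye, pairs in rows.items()
    }
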