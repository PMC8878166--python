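"""Guidance-accuracy metrics: scan registration, point extraction, TRE, ASSD, FRE.

User performance in a point-and-trace task is evaluated from paper templates
digitized at 300 DPI.  Each scanned user trace is aligned to the ground-truth
template with a 3-degree-of-freedom (rotation + translation) 2D rigid
registration, user-marked points are segmented and circle-fit, and accuracy is
quantified as:

* TRE (target registration error): per-point Euclidean distance between a
  ground-truth target and the corresponding user point, summarized as
  mean +/- SD and as the RMS TRE ``sqrt(mean^2 + sd^2)``;
* ASSD (average symmetric surface distance): the mean of nearest-boundary
  distances taken in both directions between the ground-truth contour and the
  user-drawn contour, normalized by total boundary length;
* FRE (fiducial registration error): RMS distance between corresponding
  fiducial centroids after registration.

All metrics are reported in millimeters; at the default 300 DPI one pixel is
25.4/300 ~= 0.0847 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage import draw as skdraw
from skimage import measure, morphology, transform as sktransform
from skimage.registration import phase_cross_correlation

from .errors import (
    CountMismatchError,
    EmptyContourError,
    FiducialsNotFoundError,
    InvalidBaselineError,
    NoPairsError,
    PointCountMismatchError,
    RegistrationFailedError,
)

__all__ = [
    "DEFAULT_DPI",
    "MM_PER_INCH",
    "TraceScan",
    "Rigid2D",
    "PointMatchResult",
    "MetricReport",
    "TreSummary",
    "mm_per_px",
    "detect_corner_fiducials",
    "register_scan",
    "extract_points",
    "extract_contour_mask",
    "match_points",
    "compute_tre",
    "rms_from_mean_sd",
    "compute_assd",
    "assd_from_masks",
    "rasterize_polyline",
    "compute_fre",
    "percent_improvement",
    "seconds_to_minutes",
    "evaluate_trial",
]

DEFAULT_DPI = 300
MM_PER_INCH = 25.4

#: Side length and page inset of the corner square-marker fiducials (mm).
FIDUCIAL_SIDE_MM = 10.0
FIDUCIAL_INSET_MM = 5.0

#: Default radius of a printed/drawn target dot (mm).
DOT_RADIUS_MM = 1.5
#: Default half-width of a drawn stroke (mm).
STROKE_RADIUS_MM = 0.25

_BIN_THRESHOLD = 128  # ink is darker than this
_REG_QUALITY_LIMIT_MM = 2.0


def mm_per_px(dpi: float) -> float:
    return MM_PER_INCH / dpi


@dataclass
class TraceScan:
    """A grayscale raster of a scanned template or user trace."""

    image: np.ndarray
    dpi: float = DEFAULT_DPI
    corner_fiducials: np.ndarray | None = None  # (4, 2) centroids, (x, y) px

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 2 or self.image.size == 0:
            raise ValueError("scan image must be a non-empty 2D array")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")

    @property
    def ink_mask(self) -> np.ndarray:
        """Boolean mask of dark (inked) pixels."""
        return self.image < _BIN_THRESHOLD

    def save_png(self, path: str | Path) -> None:
        from PIL import Image

        Image.fromarray(self.image.astype(np.uint8), mode="L").save(
            str(path), dpi=(self.dpi, self.dpi)
        )

    @classmethod
    def load_png(cls, path: str | Path, dpi: float | None = None) -> "TraceScan":
        from PIL import Image

        with Image.open(str(path)) as im:
            arr = np.asarray(im.convert("L"))
            if dpi is None:
                dpi = float(im.info.get("dpi", (DEFAULT_DPI, DEFAULT_DPI))[0])
                # PNG stores px/meter; undo the round-trip quantization
                if abs(dpi - round(dpi)) < 0.01:
                    dpi = float(round(dpi))
        return cls(arr, dpi=dpi)


@dataclass(frozen=True)
class Rigid2D:
    """2D rigid map ``p' = R(theta) p + t`` on (x, y) pixel coordinates.

    ``theta`` is in degrees, constrained to (-180, 180]; positive theta turns
    the +x axis toward +y (clockwise on screen with y pointing down).
    """

    theta_deg: float
    tx: float
    ty: float

    def __post_init__(self):
        if not all(map(math.isfinite, (self.theta_deg, self.tx, self.ty))):
            raise ValueError("non-finite rigid parameters")
        th = ((self.theta_deg + 180.0) % 360.0) - 180.0
        if th == -180.0:
            th = 180.0
        object.__setattr__(self, "theta_deg", th)

    @property
    def rotation(self) -> np.ndarray:
        c, s = math.cos(math.radians(self.theta_deg)), math.sin(
            math.radians(self.theta_deg)
        )
        return np.array([[c, -s], [s, c]])

    def apply(self, points_xy: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_xy, dtype=float))
        return p @ self.rotation.T + np.array([self.tx, self.ty])

    def inverse(self) -> "Rigid2D":
        R = self.rotation
        t = -R.T @ np.array([self.tx, self.ty])
        return Rigid2D(-self.theta_deg, t[0], t[1])

    @classmethod
    def about_center(
        cls, theta_deg: float, shift_xy: Sequence[float], center_xy: Sequence[float]
    ) -> "Rigid2D":
        """Rotation about ``center_xy`` followed by a shift."""
        tmp = cls(theta_deg, 0.0, 0.0)
        c = np.asarray(center_xy, dtype=float)
        t = c + np.asarray(shift_xy, dtype=float) - tmp.rotation @ c
        return cls(theta_deg, t[0], t[1])


@dataclass
class PointMatchResult:
    """Ground-truth/user point pairs (mm) sequenced by the recorded task order."""

    truth_mm: np.ndarray  # (N, 2)
    user_mm: np.ndarray  # (N, 2)
    order: np.ndarray  # task-order index of each pair, strictly increasing
    n_unmatched_truth: int = 0
    n_unmatched_user: int = 0

    def __post_init__(self):
        self.truth_mm = np.atleast_2d(np.asarray(self.truth_mm, dtype=float))
        self.user_mm = np.atleast_2d(np.asarray(self.user_mm, dtype=float))
        self.order = np.asarray(self.order, dtype=int)
        if np.any(np.diff(self.order) <= 0):
            raise ValueError("order indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.truth_mm)


@dataclass
class TreSummary:
    samples_mm: np.ndarray
    mean_mm: float
    sd_mm: float
    rmse_mm: float


@dataclass
class MetricReport:
    """All per-trial evaluation outputs."""

    tre_samples_mm: np.ndarray
    tre_mean_mm: float
    tre_sd_mm: float
    tre_rmse_mm: float
    assd_mm: float
    task_time_s: float
    calibration_time_s: float  # NaN when the paradigm involves no calibration
    paradigm: str = ""
    nasa_tlx: np.ndarray | None = None  # six subscales, 0-100
    registration_quality_mm: float = float("nan")

    def __post_init__(self):
        if not (self.tre_rmse_mm + 1e-12 >= self.tre_mean_mm >= 0):
            raise ValueError("TRE summary violates rmse >= mean >= 0")
        if self.assd_mm < 0:
            raise ValueError("negative ASSD")
        if self.task_time_s <= 0:
            raise ValueError("task time must be positive")


# ---------------------------------------------------------------------------
# Scan registration


def _fiducial_area_px(dpi: float) -> float:
    side = FIDUCIAL_SIDE_MM / mm_per_px(dpi)
    return side * side


def detect_corner_fiducials(scan: TraceScan) -> np.ndarray:
    """Locate the 4 corner square-markers; returns centroids (x, y) px.

    Square markers are found as filled connected components whose area matches
    the expected 10 mm square and whose bounding-box fill ratio is high; one
    marker is required in each image quadrant.  Output order is
    [top-left, top-right, bottom-right, bottom-left].
    """
    mask = scan.ink_mask
    labels = measure.label(mask)
    expected = _fiducial_area_px(scan.dpi)
    h, w = mask.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    quadrants: dict[int, tuple[float, np.ndarray]] = {}
    for region in measure.regionprops(labels):
        if not (0.5 * expected <= region.area <= 1.6 * expected):
            continue
        bh = region.bbox[2] - region.bbox[0]
        bw = region.bbox[3] - region.bbox[1]
        if region.area / (bh * bw) < 0.7:  # squares fill their bbox
            continue
        y, x = region.centroid
        quad = (0 if y < cy else 1) * 2 + (0 if x < cx else 1)
        # keep the component closest in area to the expected square
        score = abs(region.area - expected)
        if quad not in quadrants or score < quadrants[quad][0]:
            quadrants[quad] = (score, np.array([x, y]))
    if len(quadrants) != 4:
        raise FiducialsNotFoundError(
            f"found corner markers in {len(quadrants)} of 4 quadrants"
        )
    # quadrant codes: 0=TL, 1=TR, 2=BL, 3=BR -> order TL, TR, BR, BL
    out = np.array([quadrants[q][1] for q in (0, 1, 3, 2)])
    scan.corner_fiducials = out
    return out


def _reg_image(scan: TraceScan, sigma: float = 2.0) -> np.ndarray:
    """Smoothed float ink image used by the intensity metric."""
    return ndimage.gaussian_filter(scan.ink_mask.astype(float), sigma)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    denom = math.sqrt(float(np.sum(a * a)) * float(np.sum(b * b)))
    if denom == 0:
        return 0.0
    return float(np.sum(a * b)) / denom


def _warp_by(img: np.ndarray, rig: Rigid2D) -> np.ndarray:
    """Resample ``img`` so its content is mapped through ``rig`` (xy convention)."""
    M = np.eye(3)
    M[:2, :2] = rig.rotation
    M[:2, 2] = (rig.tx, rig.ty)
    tform = sktransform.EuclideanTransform(matrix=np.linalg.inv(M))
    return sktransform.warp(img, tform, order=1, cval=0.0, preserve_range=True)


def register_scan(
    template: TraceScan,
    user: TraceScan,
    coarse: str = "fiducials",
    refine: bool = True,
    theta_range_deg: float = 10.0,
    theta_step_deg: float = 0.5,
    downsample: int = 4,
) -> tuple[Rigid2D, float]:
    """3-DoF rigid alignment of a user scan onto the ground-truth template.

    The returned transform maps user-scan pixel coordinates into template
    pixel coordinates.  A coarse estimate comes either from the four corner
    square-marker centroids (``coarse="fiducials"``) or from an exhaustive
    rotation sweep with per-angle phase-correlation translation
    (``coarse="grid"``); it is then refined by maximizing normalized
    cross-correlation between the Gaussian-smoothed binarized images.  The
    refined estimate is kept only if it improves the intensity metric.

    Alignment quality is the mean distance (mm) between the four corresponding
    corner-marker centroids after alignment — the quantitative version of
    checking fiducial overlap visually.

    Raises
    ------
    FiducialsNotFoundError
        If either scan does not show all four corner markers.
    RegistrationFailedError
        If the final quality exceeds 2.0 mm.
    """
    if template.dpi != user.dpi:
        raise ValueError("template and user scans must share a dpi")
    fid_t = detect_corner_fiducials(template)
    fid_u = detect_corner_fiducials(user)

    img_t = _reg_image(template)
    img_u = _reg_image(user)
    ds = max(1, int(downsample))
    small_t = img_t[::ds, ::ds]
    small_u = img_u[::ds, ::ds]

    if coarse == "fiducials":
        tf = sktransform.estimate_transform("euclidean", fid_u, fid_t)
        init = Rigid2D(math.degrees(tf.rotation), tf.translation[0], tf.translation[1])
    elif coarse == "grid":
        h, w = small_u.shape
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
        best = (None, -np.inf)
        for th in np.arange(-theta_range_deg, theta_range_deg + 1e-9, theta_step_deg):
            rot = Rigid2D.about_center(th, (0.0, 0.0), center)
            rotated = _warp_by(small_u, rot)
            shift, _, _ = phase_cross_correlation(
                small_t, rotated, upsample_factor=4, normalization=None
            )
            cand = Rigid2D.about_center(th, (shift[1], shift[0]), center)
            score = _ncc(small_t, _warp_by(small_u, cand))
            if score > best[1]:
                best = (cand, score)
        cand = best[0]
        init = Rigid2D(cand.theta_deg, cand.tx * ds, cand.ty * ds)
    else:
        raise ValueError(f"unknown coarse mode {coarse!r}")

    est = init
    if refine:
        x0 = np.array([init.theta_deg, init.tx / ds, init.ty / ds])

        def cost(x):
            return 1.0 - _ncc(small_t, _warp_by(small_u, Rigid2D(x[0], x[1], x[2])))

        res = optimize.minimize(
            cost, x0, method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-10, "maxiter": 300},
        )
        refined = Rigid2D(res.x[0], res.x[1] * ds, res.x[2] * ds)
        if cost(res.x) <= cost(x0):
            est = refined

    quality_mm = float(
        np.mean(np.linalg.norm(est.apply(fid_u) - fid_t, axis=1))
    ) * mm_per_px(template.dpi)
    if quality_mm > _REG_QUALITY_LIMIT_MM:
        raise RegistrationFailedError(
            f"fiducial alignment quality {quality_mm:.2f} mm exceeds "
            f"{_REG_QUALITY_LIMIT_MM} mm"
        )
    return est, quality_mm


# ---------------------------------------------------------------------------
# Point extraction


def _fit_circle_kasa(xy: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle fit; returns (cx, cy, r)."""
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    return float(cx), float(cy), float(math.sqrt(max(c + cx * cx + cy * cy, 0.0)))


def _dot_regions(scan: TraceScan, dot_radius_mm: float):
    """Opened-image connected components that look like marked dots."""
    res = mm_per_px(scan.dpi)
    r_dot_px = dot_radius_mm / res
    r_open = max(2, int(round(STROKE_RADIUS_MM / res)) + 2)
    opened = morphology.opening(scan.ink_mask, morphology.disk(r_open))
    labels = measure.label(opened)
    expected_area = math.pi * r_dot_px**2
    keep = []
    for region in measure.regionprops(labels):
        if not (0.3 * expected_area <= region.area <= 2.5 * expected_area):
            continue
        bh = region.bbox[2] - region.bbox[0]
        bw = region.bbox[3] - region.bbox[1]
        if max(bh, bw) > 4 * r_dot_px or min(bh, bw) < 0.8 * r_dot_px:
            continue
        keep.append(region)
    return keep, labels


def extract_points(
    scan: TraceScan,
    n_expected: int,
    dot_radius_mm: float = DOT_RADIUS_MM,
) -> np.ndarray:
    """Segment user-marked dots and circle-fit each; returns (N, 2) centers in mm.

    A morphological opening first erases thin strokes (the traced contour) so
    that dots touching the trace remain separable; remaining components are
    filtered by area and aspect against the expected dot size, and each
    surviving blob's boundary pixels are fit with an algebraic least-squares
    circle.  Pixel centers convert to mm as ``25.4/dpi`` per pixel.

    Raises
    ------
    PointCountMismatchError
        If the number of detected dots differs from ``n_expected``.
    """
    regions, _ = _dot_regions(scan, dot_radius_mm)
    if len(regions) != n_expected:
        raise PointCountMismatchError(len(regions), n_expected)
    res = mm_per_px(scan.dpi)
    centers = []
    for region in regions:
        mask = region.image
        boundary = mask & ~morphology.erosion(mask)
        rr, cc = np.nonzero(boundary)
        y0, x0 = region.bbox[0], region.bbox[1]
        cx, cy, _ = _fit_circle_kasa(np.column_stack([cc + x0, rr + y0]))
        centers.append((cx * res, cy * res))
    return np.array(centers)


def extract_contour_mask(
    scan: TraceScan,
    dot_radius_mm: float = DOT_RADIUS_MM,
) -> np.ndarray:
    """Boolean mask of the 1-px-wide user-drawn contour.

    Removes corner fiducials and dot blobs from the ink mask, then
    skeletonizes what remains (the traced curve).
    """
    mask = scan.ink_mask.copy()
    # remove corner markers
    fids = scan.corner_fiducials
    if fids is None:
        fids = detect_corner_fiducials(scan)
    half = 0.75 * FIDUCIAL_SIDE_MM / mm_per_px(scan.dpi)
    for x, y in fids:
        r0, r1 = int(max(0, y - half)), int(min(mask.shape[0], y + half + 1))
        c0, c1 = int(max(0, x - half)), int(min(mask.shape[1], x + half + 1))
        mask[r0:r1, c0:c1] = False
    # remove dots (slightly dilated so rim pixels go too)
    regions, labels = _dot_regions(scan, dot_radius_mm)
    dot_mask = np.isin(labels, [r.label for r in regions])
    if dot_mask.any():
        res = mm_per_px(scan.dpi)
        dot_mask = morphology.dilation(
            dot_mask, morphology.disk(max(2, int(round(2 * STROKE_RADIUS_MM / res))))
        )
        mask &= ~dot_mask
    return morphology.skeletonize(mask)


# ---------------------------------------------------------------------------
# Point matching and TRE


def match_points(
    truth_mm: np.ndarray,
    user_mm: np.ndarray,
    order: Sequence[int] | None = None,
) -> PointMatchResult:
    """Pair user points with ground-truth targets.

    Correspondence is established by minimum-total-distance assignment; the
    recorded task order (the sequence in which the user approached the
    targets) then sequences the matched pairs, mirroring how approach order
    disambiguates user points on the physical templates.
    """
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    truth = np.atleast_2d(np.asarray(truth_mm, dtype=float))
    user = np.atleast_2d(np.asarray(user_mm, dtype=float))
    order = np.arange(len(truth)) if order is None else np.asarray(order, dtype=int)
    cost = cdist(truth, user)
    ti, ui = linear_sum_assignment(cost)
    # sequence matched truth indices by recorded task order
    rank = {t: k for k, t in enumerate(order)}
    seq = np.argsort([rank.get(t, len(order) + t) for t in ti])
    ti, ui = ti[seq], ui[seq]
    return PointMatchResult(
        truth[ti],
        user[ui],
        np.arange(len(ti)),
        n_unmatched_truth=len(truth) - len(ti),
        n_unmatched_user=len(user) - len(ui),
    )


def compute_tre(match: PointMatchResult) -> TreSummary:
    """Per-pair Euclidean distances (mm) with mean, sample SD and RMS TRE.

    The RMS TRE combines bias and spread as ``sqrt(mean^2 + sd^2)``; the SD is
    the sample standard deviation (n-1), zero for a single pair.

    Raises
    ------
    NoPairsError
        On an empty match.
    """
    if len(match) == 0:
        raise NoPairsError("no matched pairs")
    d = np.linalg.norm(match.truth_mm - match.user_mm, axis=1)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return TreSummary(d, mean, sd, rms_from_mean_sd(mean, sd))


def rms_from_mean_sd(mean: float, sd: float) -> float:
    """RMS error from a mean and standard deviation: ``sqrt(mean^2 + sd^2)``."""
    return math.sqrt(mean * mean + sd * sd)


# ---------------------------------------------------------------------------
# ASSD


def rasterize_polyline(
    poly_mm: np.ndarray,
    origin_mm: np.ndarray,
    shape: tuple[int, int],
    resolution_mm: float,
    closed: bool = False,
) -> np.ndarray:
    """Draw a polyline as a 1-px-wide curve on a boolean canvas."""
    poly = np.atleast_2d(np.asarray(poly_mm, dtype=float))
    pts = np.round((poly - np.asarray(origin_mm)) / resolution_mm).astype(int)
    if closed and not np.array_equal(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[:1]])
    canvas = np.zeros(shape, dtype=bool)
    if len(pts) == 1:
        x, y = pts[0]
        if 0 <= y < shape[0] and 0 <= x < shape[1]:
            canvas[y, x] = True
        return canvas
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = skdraw.line(y0, x0, y1, x1)
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        canvas[rr[ok], cc[ok]] = True
    return canvas


def assd_from_masks(
    mask_g: np.ndarray, mask_m: np.ndarray, resolution_mm: float
) -> float:
    """ASSD between two rasterized boundaries on a common grid.

    ``(sum_{x in G} d(x, M) + sum_{y in M} d(y, G)) / (|G| + |M|)`` with exact
    Euclidean distance transforms; symmetric by construction.
    """
    if not mask_g.any() or not mask_m.any():
        raise EmptyContourError("empty boundary mask")
    dt_m = ndimage.distance_transform_edt(~mask_m)
    dt_g = ndimage.distance_transform_edt(~mask_g)
    s = float(dt_m[mask_g].sum() + dt_g[mask_m].sum())
    n = int(mask_g.sum() + mask_m.sum())
    return s / n * resolution_mm


def compute_assd(
    contour_g: np.ndarray,
    contour_m: np.ndarray,
    resolution_mm: float = MM_PER_INCH / DEFAULT_DPI,
    closed: bool = False,
) -> float:
    """ASSD (mm) between two contour polylines given in mm.

    Both contours are rasterized as 1-px-wide curves at ``resolution_mm`` per
    pixel on a shared grid and compared through exact Euclidean distance
    transforms.

    Raises
    ------
    EmptyContourError
        If either polyline has no vertices.
    """
    g = np.atleast_2d(np.asarray(contour_g, dtype=float))
    m = np.atleast_2d(np.asarray(contour_m, dtype=float))
    if g.size == 0 or m.size == 0:
        raise EmptyContourError("empty contour polyline")
    lo = np.minimum(g.min(axis=0), m.min(axis=0)) - 2 * resolution_mm
    hi = np.maximum(g.max(axis=0), m.max(axis=0)) + 2 * resolution_mm
    shape = (
        int(np.ceil((hi[1] - lo[1]) / resolution_mm)) + 1,
        int(np.ceil((hi[0] - lo[0]) / resolution_mm)) + 1,
    )
    mask_g = rasterize_polyline(g, lo, shape, resolution_mm, closed=closed)
    mask_m = rasterize_polyline(m, lo, shape, resolution_mm, closed=closed)
    return assd_from_masks(mask_g, mask_m, resolution_mm)


# ---------------------------------------------------------------------------
# FRE and summary arithmetic


def compute_fre(measured_mm: np.ndarray, truth_mm: np.ndarray) -> float:
    """RMS fiducial registration error: ``sqrt(mean_i ||m_i - n_i||^2)`` in mm.

    Raises
    ------
    CountMismatchError
        If the two lists differ in length or are empty.
    """
    m = np.atleast_2d(np.asarray(measured_mm, dtype=float))
    n = np.atleast_2d(np.asarray(truth_mm, dtype=float))
    if m.shape != n.shape or len(m) < 1:
        raise CountMismatchError(f"shapes {m.shape} vs {n.shape}")
    return float(np.sqrt(np.mean(np.sum((m - n) ** 2, axis=1))))


def percent_improvement(rmse_before: float, rmse_after: float) -> int:
    """``100 * (before - after) / before`` rounded to the nearest integer.

    Raises
    ------
    InvalidBaselineError
        If the baseline is not positive.
    """
    if rmse_before <= 0:
        raise InvalidBaselineError(f"baseline {rmse_before} <= 0")
    return int(round(100.0 * (rmse_before - rmse_after) / rmse_before))


def seconds_to_minutes(seconds: float, ndigits: int | None = None) -> float:
    """Convert a duration to minutes, optionally rounded for reporting."""
    m = seconds / 60.0
    return round(m, ndigits) if ndigits is not None else m


# ---------------------------------------------------------------------------
# Trial pipeline


def evaluate_trial(
    truth_points_mm: np.ndarray,
    truth_contour_mm: np.ndarray,
    template: TraceScan,
    user: TraceScan,
    order: Sequence[int] | None = None,
    task_time_s: float = float("nan"),
    calibration_time_s: float = float("nan"),
    paradigm: str = "",
    nasa_tlx: np.ndarray | None = None,
    coarse: str = "fiducials",
) -> MetricReport:
    """Full evaluation of one scanned trial against its ground truth.

    Registers the user scan to the template, extracts and matches the marked
    points (TRE) and the traced contour (ASSD), and assembles a MetricReport.
    All geometry is expressed in template-page mm after alignment.
    """
    rig, quality = register_scan(template, user, coarse=coarse)
    res = mm_per_px(template.dpi)

    user_pts_px = extract_points(user, n_expected=len(truth_points_mm)) / res
    user_pts_mm = rig.apply(user_pts_px) * res
    match = match_points(truth_points_mm, user_pts_mm, order=order)
    tre = compute_tre(match)

    contour_mask = extract_contour_mask(user)
    rr, cc = np.nonzero(contour_mask)
    mapped = rig.apply(np.column_stack([cc, rr]))  # (x, y) template px
    shape = template.image.shape
    idx = np.round(mapped).astype(int)
    ok = (idx[:, 1] >= 0) & (idx[:, 1] < shape[0]) & (idx[:, 0] >= 0) & (idx[:, 0] < shape[1])
    user_mask = np.zeros(shape, dtype=bool)
    user_mask[idx[ok, 1], idx[ok, 0]] = True
    truth_mask = rasterize_polyline(
        truth_contour_mm, np.zeros(2), shape, res, closed=True
    )
    assd = assd_from_masks(truth_mask, user_mask, res)

    task_time = task_time_s if math.isfinite(task_time_s) else 1.0
    return MetricReport(
        tre_samples_mm=tre.samples_mm,
        tre_mean_mm=tre.mean_mm,
        tre_sd_mm=tre.sd_mm,
        tre_rmse_mm=tre.rmse_mm,
        assd_mm=assd,
        task_time_s=task_time,
        calibration_time_s=calibration_time_s,
        paradigm=paradigm,
        nasa_tlx=nasa_tlx,
        registration_quality_mm=quality,
    )
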