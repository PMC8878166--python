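"""Synthetic study inputs: phantoms, rendered templates, simulated users and calibrations.

Everything the evaluation pipeline consumes can be generated here from a seed:

* scar-like trace phantoms — an irregular closed contour with 19 ordered
  target points spaced roughly 1 cm apart, in five distinct variants, plus
  light anatomical landmarks (vessel polylines and an outer heart contour)
  that carry no ground-truth information;
* 300 DPI raster templates and simulated scanned user traces, each page
  carrying four corner square-markers for scan registration;
* simulated users whose point-placement and contour-tracing errors follow
  per-paradigm Gaussian error models, with task/calibration times and
  NASA-TLX draws so the statistics pipeline can run end to end;
* simulated display-calibration sessions with a known ground-truth eye
  offset.

All generators are pure functions of their seeds.  The per-paradigm error
defaults encode the study conditions the evaluation is meant to operate
under; they are derived analytically from the summary accuracy levels of the
five guidance paradigms (see the methods note) and make no claim of
behavioral realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Point as ShPoint, Polygon
from skimage import draw as skdraw
from skimage import morphology

from .display_calibration import Observation, CalibrationSession, default_reticle_positions
from .errors import GenerationFailedError
from .metrics import (
    DEFAULT_DPI,
    DOT_RADIUS_MM,
    FIDUCIAL_INSET_MM,
    FIDUCIAL_SIDE_MM,
    STROKE_RADIUS_MM,
    Rigid2D,
    TraceScan,
    compute_assd,
    compute_tre,
    match_points,
    mm_per_px,
)
from .rigid_geometry import CorrespondenceSet, RigidTransform3D, invert

__all__ = [
    "PAGE_SIZE_MM",
    "N_TARGET_POINTS",
    "PARADIGMS",
    "TracePhantom",
    "UserErrorModel",
    "PARADIGM_DEFAULTS",
    "generate_phantom",
    "render_template",
    "SimulatedTrial",
    "simulate_trial",
    "simulate_calibration_observations",
    "simulate_calibration_session",
    "simulate_study",
    "write_trial_files",
]

PAGE_SIZE_MM = 120.0
N_TARGET_POINTS = 19
PARADIGMS = ("TM", "TA", "TD", "TC", "TR")

_POINT_SPACING_MM = 10.0  # nominal target spacing
_SPACING_MIN_MM = 7.0
_SPACING_MAX_MM = 13.0  # nearest-neighbour bound
_CONTOUR_CLEARANCE_MM = 4.5  # keep dots separable from the traced contour


@dataclass
class TracePhantom:
    """Ground truth for one point-and-trace template (all coordinates in mm)."""

    contour: np.ndarray  # (N, 2) closed scar-like polyline (first != last)
    points: np.ndarray  # (19, 2) ordered target points
    landmarks: list[np.ndarray]  # vessel polylines + outer heart contour
    variant_id: int
    seed: int

    def __post_init__(self):
        if len(self.points) != N_TARGET_POINTS:
            raise ValueError(f"expected {N_TARGET_POINTS} target points")
        if not 1 <= self.variant_id <= 5:
            raise ValueError("variant_id must be in 1..5")
        nn = _nearest_neighbour_distances(self.points)
        if nn.min() < _SPACING_MIN_MM - 1e-9 or nn.max() > _SPACING_MAX_MM + 1e-9:
            raise ValueError("point spacing outside [7, 13] mm nearest-neighbour band")


def _nearest_neighbour_distances(points: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(points))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def _scar_contour(rng: np.random.Generator, variant_id: int) -> np.ndarray:
    """Irregular closed radial contour centered on the page."""
    r0 = 27.0 + 1.5 * variant_id
    ks = (2, 3, 4, 5)
    amps = rng.uniform(0.8, 2.2, size=len(ks))
    phases = rng.uniform(0, 2 * math.pi, size=len(ks))
    phi = np.linspace(0, 2 * math.pi, 360, endpoint=False)
    r = r0 + sum(a * np.cos(k * phi + p) for a, k, p in zip(amps, ks, phases))
    c = PAGE_SIZE_MM / 2
    return np.column_stack([c + r * np.cos(phi), c + r * np.sin(phi)])


def _hex_candidates(poly: Polygon) -> np.ndarray:
    pitch = _POINT_SPACING_MM
    dy = pitch * math.sqrt(3) / 2
    inner = poly.buffer(-_CONTOUR_CLEARANCE_MM)
    pts = []
    c = PAGE_SIZE_MM / 2
    rows = np.arange(c - 45, c + 45 + 1e-9, dy)
    for i, y in enumerate(rows):
        xs = np.arange(c - 45, c + 45 + 1e-9, pitch) + (pitch / 2 if i % 2 else 0.0)
        for x in xs:
            if inner.contains(ShPoint(x, y)):
                pts.append((x, y))
    return np.array(pts) if pts else np.empty((0, 2))


def _serpentine_order(points: np.ndarray) -> np.ndarray:
    rows = np.round(points[:, 1] / (_POINT_SPACING_MM * math.sqrt(3) / 2)).astype(int)
    order = []
    for i, row in enumerate(np.unique(rows)):
        idx = np.nonzero(rows == row)[0]
        idx = idx[np.argsort(points[idx, 0])]
        order.extend(idx if i % 2 == 0 else idx[::-1])
    return np.asarray(order)


def _landmarks(rng: np.random.Generator) -> list[np.ndarray]:
    """Vessel-like polylines and an outer heart contour (guidance cues only)."""
    c = PAGE_SIZE_MM / 2
    t = np.linspace(0, 2 * math.pi, 200)
    heart = np.column_stack([c + 52 * np.cos(t), c + 3 + 49 * np.sin(t)])
    vessels = []
    for side in (-1, 1):
        s = np.linspace(0, 1, 80)
        amp = rng.uniform(5, 9)
        ph = rng.uniform(0, 2 * math.pi)
        x = c + side * rng.uniform(22, 30) + amp * np.sin(3.0 * s * math.pi + ph)
        y = 14 + (PAGE_SIZE_MM - 28) * s
        vessels.append(np.column_stack([x, y]))
    return vessels + [heart]


def generate_phantom(variant_id: int, seed: int = 0) -> TracePhantom:
    """Deterministic scar phantom for one of the five template variants.

    The contour is a radially perturbed closed curve whose base radius and
    harmonic perturbation differ per variant; the 19 target points sit on a
    jittered hexagonal lattice of ~10 mm pitch inside the contour (kept clear
    of the contour line so drawn dots stay separable from the trace), ordered
    in a serpentine task sequence.  Retries the jitter and, if needed, the
    contour until the nearest-neighbour spacing lies in the [7, 13] mm band.

    Raises
    ------
    GenerationFailedError
        If the spacing constraints cannot be met within bounded retries.
    """
    if not 1 <= variant_id <= 5:
        raise ValueError("variant_id must be in 1..5")
    rng = np.random.default_rng([seed, variant_id])
    for _ in range(10):  # contour attempts
        contour = _scar_contour(rng, variant_id)
        poly = Polygon(contour)
        cands = _hex_candidates(poly)
        if len(cands) < N_TARGET_POINTS:
            continue
        centroid = cands.mean(axis=0)
        keep = np.argsort(np.linalg.norm(cands - centroid, axis=1))[:N_TARGET_POINTS]
        base = cands[keep]
        inner = poly.buffer(-_CONTOUR_CLEARANCE_MM + 0.5)
        for _ in range(50):  # jitter attempts
            pts = base + rng.uniform(-1.2, 1.2, size=base.shape)
            nn = _nearest_neighbour_distances(pts)
            if nn.min() < _SPACING_MIN_MM or nn.max() > _SPACING_MAX_MM:
                continue
            if not all(inner.contains(ShPoint(*p)) for p in pts):
                continue
            pts = pts[_serpentine_order(pts)]
            return TracePhantom(contour, pts, _landmarks(rng), variant_id, seed)
    raise GenerationFailedError(
        f"could not satisfy spacing constraints for variant {variant_id}"
    )


# ---------------------------------------------------------------------------
# Rendering


def _draw_polyline_mask(
    canvas: np.ndarray, poly_mm: np.ndarray, res: float, closed: bool
) -> None:
    pts = np.round(np.atleast_2d(poly_mm) / res).astype(int)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = skdraw.line(y0, x0, y1, x1)
        ok = (rr >= 0) & (rr < canvas.shape[0]) & (cc >= 0) & (cc < canvas.shape[1])
        canvas[rr[ok], cc[ok]] = True


def _fiducial_centers_mm() -> np.ndarray:
    lo = FIDUCIAL_INSET_MM + FIDUCIAL_SIDE_MM / 2
    hi = PAGE_SIZE_MM - lo
    return np.array([[lo, lo], [hi, lo], [hi, hi], [lo, hi]])


def render_page(
    dpi: float = DEFAULT_DPI,
    contour_mm: np.ndarray | None = None,
    dots_mm: np.ndarray | None = None,
    landmarks_mm: Iterable[np.ndarray] = (),
    transform_mm=None,
    dot_radius_mm: float = DOT_RADIUS_MM,
) -> TraceScan:
    """Rasterize one template page at the given dpi.

    The page always carries the four black corner square-markers; landmarks
    are printed light gray (below the binarization threshold for ink) and the
    contour/dots black.  ``transform_mm``, if given, is applied to every
    coordinate before rasterization (used to emulate imperfect sheet placement
    on the scanner bed).
    """
    res = mm_per_px(dpi)
    n = int(round(PAGE_SIZE_MM / res))
    img = np.full((n, n), 255, dtype=np.uint8)
    tf = transform_mm if transform_mm is not None else (lambda p: p)
    stroke_px = max(1, int(round(STROKE_RADIUS_MM / res)))

    gray = np.zeros((n, n), dtype=bool)
    for lm in landmarks_mm:
        _draw_polyline_mask(gray, tf(np.asarray(lm)), res, closed=False)
    if gray.any():
        gray = morphology.dilation(gray, morphology.disk(stroke_px))
        img[gray] = 200

    black = np.zeros((n, n), dtype=bool)
    if contour_mm is not None:
        _draw_polyline_mask(black, tf(np.asarray(contour_mm)), res, closed=True)
    if black.any():
        black = morphology.dilation(black, morphology.disk(stroke_px))

    if dots_mm is not None:
        r_px = dot_radius_mm / res
        for x, y in tf(np.atleast_2d(dots_mm)):
            rr, cc = skdraw.disk((y / res, x / res), r_px, shape=(n, n))
            black[rr, cc] = True

    half = FIDUCIAL_SIDE_MM / 2
    for cx, cy in _fiducial_centers_mm():
        corners = np.array(
            [[cx - half, cy - half], [cx + half, cy - half],
             [cx + half, cy + half], [cx - half, cy + half]]
        )
        corners = tf(corners) / res
        rr, cc = skdraw.polygon(corners[:, 1], corners[:, 0], shape=(n, n))
        black[rr, cc] = True

    img[black] = 0
    return TraceScan(img, dpi=dpi)


def render_template(
    phantom: TracePhantom, kind: str = "truth", dpi: float = DEFAULT_DPI
) -> TraceScan:
    """Render the ground-truth template or the blank trace template.

    The blank template carries only the corner markers and the light
    landmarks; the truth template additionally shows the scar contour and the
    19 target dots.
    """
    if kind == "truth":
        return render_page(
            dpi,
            contour_mm=phantom.contour,
            dots_mm=phantom.points,
            landmarks_mm=phantom.landmarks,
        )
    if kind == "blank":
        return render_page(dpi, landmarks_mm=phantom.landmarks)
    raise ValueError(f"unknown template kind {kind!r}")


# ---------------------------------------------------------------------------
# User error models


@dataclass(frozen=True)
class UserErrorModel:
    """Per-paradigm generative model of user error, timing and workload."""

    paradigm: str
    point_sigma_mm: float  # isotropic per-axis SD of point placement
    contour_sigma_mm: float  # SD of the smooth normal trace displacement
    time_mean_s: float
    time_sd_s: float
    calib_time_mean_s: float = float("nan")  # NaN: paradigm has no calibration
    calib_time_sd_s: float = float("nan")
    tlx_means: tuple = (40.0,) * 6
    tlx_sd: float = 15.0

    def __post_init__(self):
        if self.point_sigma_mm < 0 or self.contour_sigma_mm < 0:
            raise ValueError("sigmas must be non-negative")
        if self.time_mean_s <= 0:
            raise ValueError("times must be positive")


def _sigma_from_tre_mean(tre_mean_mm: float) -> float:
    # mean of a 2D Rayleigh with per-axis sigma s is s*sqrt(pi/2)
    return tre_mean_mm / math.sqrt(math.pi / 2)


def _sigma_from_assd(assd_mm: float) -> float:
    # mean |N(0, s^2)| = s*sqrt(2/pi)
    return assd_mm / math.sqrt(2 / math.pi)


#: Study-condition defaults per guidance paradigm.  Point/contour noise is set
#: analytically from each paradigm's summary TRE/ASSD level; times are the
#: per-paradigm task and calibration time distributions; NASA-TLX subscale
#: means (mental, physical, temporal, performance, effort, frustration) follow
#: the qualitative workload ordering of the paradigms.
PARADIGM_DEFAULTS: dict[str, UserErrorModel] = {
    "TM": UserErrorModel(
        "TM", _sigma_from_tre_mean(3.4), _sigma_from_assd(1.75), 129, 72,
        tlx_means=(60, 25, 40, 45, 55, 45),
    ),
    "TA": UserErrorModel(
        "TA", _sigma_from_tre_mean(2.6), _sigma_from_assd(1.15), 130, 63,
        tlx_means=(55, 25, 40, 40, 50, 40),
    ),
    "TD": UserErrorModel(
        "TD", _sigma_from_tre_mean(1.1), _sigma_from_assd(0.51), 78, 34,
        tlx_means=(30, 20, 30, 30, 30, 20),
    ),
    "TC": UserErrorModel(
        "TC", _sigma_from_tre_mean(1.02), _sigma_from_assd(0.50), 71, 23,
        calib_time_mean_s=122, calib_time_sd_s=65,
        tlx_means=(45, 30, 35, 20, 45, 25),
    ),
    "TR": UserErrorModel(
        "TR", _sigma_from_tre_mean(0.98), _sigma_from_assd(0.51), 73, 29,
        calib_time_mean_s=85, calib_time_sd_s=38,
        tlx_means=(42, 28, 33, 18, 42, 22),
    ),
}


# ---------------------------------------------------------------------------
# Trial simulation


@dataclass
class SimulatedTrial:
    phantom: TracePhantom
    user_points_mm: np.ndarray
    user_contour_mm: np.ndarray
    order: np.ndarray  # truth indices in approach order
    perturbation: Rigid2D | None  # page-frame mm perturbation (about page center)
    scan: TraceScan | None
    task_time_s: float
    calibration_time_s: float
    nasa_tlx: np.ndarray
    paradigm: str


def _resample_closed(contour: np.ndarray, spacing_mm: float = 0.5) -> np.ndarray:
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    t = np.arange(0.0, total, spacing_mm)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def _displace_contour(
    contour: np.ndarray, sigma_mm: float, rng: np.random.Generator,
    corr_length_mm: float = 10.0, spacing_mm: float = 0.5,
) -> np.ndarray:
    """Smooth correlated normal displacement of a closed contour.

    White noise along arc length is smoothed with a wrapped Gaussian kernel of
    the given correlation length and rescaled to the target SD; independent
    per-vertex noise would produce jitter no human tracing shows.
    """
    pts = _resample_closed(contour, spacing_mm)
    n = len(pts)
    tangent = np.gradient(np.vstack([pts[-1], pts, pts[0]]), axis=0)[1:-1]
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    noise = rng.standard_normal(n)
    if sigma_mm <= 0:
        return pts
    d = ndimage.gaussian_filter1d(noise, corr_length_mm / spacing_mm, mode="wrap")
    sd = d.std()
    d = d / sd * sigma_mm if sd > 0 else d
    return pts + d[:, None] * normal


def simulate_trial(
    phantom: TracePhantom,
    model: UserErrorModel,
    seed: int = 0,
    render: bool = True,
    dpi: float = DEFAULT_DPI,
    max_theta_deg: float = 3.0,
    max_shift_mm: float = 5.0,
) -> SimulatedTrial:
    """One simulated point-and-trace trial under a paradigm error model.

    User points are the ground truth plus isotropic Gaussian placement error;
    the user contour is the ground truth displaced by a smooth correlated
    normal field.  When rendered, the whole drawn page (markers, landmarks,
    trace, dots) is rasterized at ``dpi`` under a small random rigid placement
    perturbation (|theta| <= 3 degrees, |shift| <= 5 mm per axis) so that the
    downstream scan registration is exercised.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    user_points = phantom.points + rng.normal(
        0.0, model.point_sigma_mm, size=phantom.points.shape
    )
    user_contour = _displace_contour(phantom.contour, model.contour_sigma_mm, rng)
    order = rng.permutation(N_TARGET_POINTS)

    theta = rng.uniform(-max_theta_deg, max_theta_deg)
    shift = rng.uniform(-max_shift_mm, max_shift_mm, size=2)
    center = (PAGE_SIZE_MM / 2, PAGE_SIZE_MM / 2)
    perturb = Rigid2D.about_center(theta, shift, center)

    task_time = max(15.0, rng.normal(model.time_mean_s, model.time_sd_s))
    if math.isfinite(model.calib_time_mean_s):
        calib_time = max(30.0, rng.normal(model.calib_time_mean_s, model.calib_time_sd_s))
    else:
        calib_time = float("nan")
    tlx = np.clip(rng.normal(model.tlx_means, model.tlx_sd), 0.0, 100.0)

    scan = None
    if render:
        scan = render_page(
            dpi,
            contour_mm=user_contour,
            dots_mm=user_points,
            landmarks_mm=phantom.landmarks,
            transform_mm=lambda p: perturb.apply(p),
        )
    return SimulatedTrial(
        phantom, user_points, user_contour, order, perturb, scan,
        task_time, calib_time, tlx, model.paradigm,
    )


# ---------------------------------------------------------------------------
# Calibration simulation


def simulate_calibration_observations(
    true_offsets: dict[str, RigidTransform3D],
    noise_sigma_mm: float = 0.0,
    n_points: int = 10,
    seed: int = 0,
    reticle_positions: np.ndarray | None = None,
) -> tuple[np.ndarray, list[Observation]]:
    """Confirm-event stream implied by known per-eye camera-to-eye offsets.

    A marker perfectly aligned with a reticle at eye-frame position r sits at
    ``offset^{-1}(r)`` in the camera frame; observations add isotropic
    Gaussian noise of ``noise_sigma_mm`` to that.  Timestamps accumulate
    plausible per-point confirmation intervals.
    """
    rng = np.random.default_rng(seed)
    if reticle_positions is None:
        reticle_positions = default_reticle_positions(max(n_points, 3))[:n_points] \
            if n_points >= 3 else default_reticle_positions(3)[:n_points]
    sigma_m = noise_sigma_mm / 1000.0
    obs: list[Observation] = []
    t = 0.0
    for eye in ("left", "right"):
        inv = invert(true_offsets[eye])
        for r in reticle_positions[:n_points]:
            t += max(2.0, rng.normal(6.0, 1.5))
            p = inv.apply(r) + rng.normal(0.0, sigma_m, size=3)
            obs.append(Observation(eye, p, t))
    return np.asarray(reticle_positions), obs


def simulate_calibration_session(
    true_offsets: dict[str, RigidTransform3D],
    noise_sigma_mm: float = 0.0,
    n_points: int = 10,
    seed: int = 0,
) -> CalibrationSession:
    """A complete simulated session (bypasses the event stream plumbing)."""
    reticles, obs = simulate_calibration_observations(
        true_offsets, noise_sigma_mm, n_points, seed
    )
    collected = {}
    times: dict[str, list[float]] = {}
    for eye in ("left", "right"):
        eye_obs = [o for o in obs if o.eye == eye]
        collected[eye] = CorrespondenceSet(
            np.array([o.point for o in eye_obs]),
            reticles[: len(eye_obs)],
            eye_label=eye,
        )
        times[eye] = [o.timestamp_s for o in eye_obs]
    return CalibrationSession(reticles, collected, times, max(3, n_points))


# ---------------------------------------------------------------------------
# Study simulation


def simulate_study(
    n_users: int = 10,
    seed: int = 0,
    paradigms: Sequence[str] = PARADIGMS,
    error_models: dict[str, UserErrorModel] | None = None,
    repeats: dict[str, int] | None = None,
    render: bool = False,
    metrics: Sequence[str] = ("tre", "assd"),
    assd_resolution_mm: float = 0.2,
):
    """Simulate a full user study and return a trial table (pandas DataFrame).

    Each user performs each paradigm (the calibrated-repeat paradigm twice by
    default) on a randomly drawn phantom variant.  With ``render=False`` the
    metrics are computed directly from the simulated geometry — the raster
    pipeline's contribution is well below the paradigm noise levels, so this
    fast path is used for large simulations; ``render=True`` pushes every
    trial through rendering, scan registration and point extraction.
    """
    import pandas as pd

    from .metrics import evaluate_trial

    models = dict(PARADIGM_DEFAULTS)
    if error_models:
        models.update(error_models)
    reps = {"TR": 2}
    if repeats:
        reps.update(repeats)

    root = np.random.SeedSequence(seed)
    phantoms = {v: generate_phantom(v, seed) for v in range(1, 6)}
    templates = (
        {v: render_template(p, "truth") for v, p in phantoms.items()} if render else {}
    )

    rows = []
    trial_seeds = root.spawn(n_users)
    for u in range(n_users):
        user_rng = np.random.default_rng(trial_seeds[u])
        for paradigm in paradigms:
            model = models[paradigm]
            for rep in range(reps.get(paradigm, 1)):
                variant = int(user_rng.integers(1, 6))
                tseed = int(user_rng.integers(0, 2**31 - 1))
                trial = simulate_trial(
                    phantoms[variant], model, seed=tseed, render=render
                )
                if render:
                    report = evaluate_trial(
                        trial.phantom.points,
                        trial.phantom.contour,
                        templates[variant],
                        trial.scan,
                        order=trial.order,
                        task_time_s=trial.task_time_s,
                        calibration_time_s=trial.calibration_time_s,
                        paradigm=paradigm,
                        nasa_tlx=trial.nasa_tlx,
                    )
                    tre_samples = report.tre_samples_mm
                    tre_mean, tre_sd, tre_rmse = (
                        report.tre_mean_mm, report.tre_sd_mm, report.tre_rmse_mm,
                    )
                    assd = report.assd_mm
                else:
                    tre = compute_tre(
                        match_points(trial.phantom.points, trial.user_points_mm,
                                     order=trial.order)
                    )
                    tre_samples = tre.samples_mm
                    tre_mean, tre_sd, tre_rmse = tre.mean_mm, tre.sd_mm, tre.rmse_mm
                    assd = (
                        compute_assd(
                            trial.phantom.contour, trial.user_contour_mm,
                            resolution_mm=assd_resolution_mm, closed=True,
                        )
                        if "assd" in metrics
                        else float("nan")
                    )
                rows.append(
                    {
                        "user_id": u,
                        "paradigm": paradigm,
                        "repeat_index": rep,
                        "variant_id": variant,
                        "tre_mean_mm": tre_mean,
                        "tre_sd_mm": tre_sd,
                        "tre_rmse_mm": tre_rmse,
                        "tre_samples_mm": ";".join(f"{x:.6g}" for x in tre_samples),
                        "assd_mm": assd,
                        "task_time_s": trial.task_time_s,
                        "calibration_time_s": trial.calibration_time_s,
                        **{
                            f"tlx_{name}": trial.nasa_tlx[i]
                            for i, name in enumerate(
                                ("mental", "physical", "temporal",
                                 "performance", "effort", "frustration")
                            )
                        },
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File output


def write_trial_files(
    trial: SimulatedTrial, out_dir: str | Path, stem: str
) -> dict[str, str]:
    """Write one simulated trial's scan (PNG), truth/order CSVs; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if trial.scan is not None:
        p = out / f"{stem}_scan.png"
        trial.scan.save_png(p)
        paths["scan"] = str(p)

    truth = out / f"{stem}_truth.csv"
    lines = ["role,index,x_mm,y_mm"]
    for i, (x, y) in enumerate(trial.phantom.points):
        lines.append(f"point,{i},{x:.4f},{y:.4f}")
    for i, (x, y) in enumerate(trial.phantom.contour):
        lines.append(f"contour,{i},{x:.4f},{y:.4f}")
    for i, (x, y) in enumerate(_fiducial_centers_mm()):
        lines.append(f"fiducial,{i},{x:.4f},{y:.4f}")
    truth.write_text("\n".join(lines) + "\n")
    paths["truth"] = str(truth)

    order = out / f"{stem}_order.csv"
    order.write_text(
        "task_order,point_index\n"
        + "\n".join(f"{k},{v}" for k, v in enumerate(trial.order))
        + "\n"
    )
    paths["order"] = str(order)

    meta = out / f"{stem}_meta.json"
    meta.write_text(
        json.dumps(
            {
                "paradigm": trial.paradigm,
                "variant_id": trial.phantom.variant_id,
                "task_time_s": trial.task_time_s,
                "calibration_time_s": (
                    None
                    if math.isnan(trial.calibration_time_s)
                    else trial.calibration_time_s
                ),
                "nasa_tlx": [float(x) for x in trial.nasa_tlx],
            },
            indent=2,
        )
    )
    paths["meta"] = str(meta)
    return paths
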