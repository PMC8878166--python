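"""Scan registration, point extraction, TRE/ASSD/FRE and summary arithmetic."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from skimage import draw as skdraw

from hmdcalib import metrics as mt
from hmdcalib import synthetic_data as sd
from hmdcalib.errors import (
    CountMismatchError,
    EmptyContourError,
    FiducialsNotFoundError,
    InvalidBaselineError,
    NoPairsError,
    PointCountMismatchError,
)

RES = mt.mm_per_px(mt.DEFAULT_DPI)


class TestRegisterScan:
    def test_self_registration_is_identity(self, truth_template):
        rig, quality = mt.register_scan(truth_template, truth_template)
        assert abs(rig.theta_deg) < 0.05
        origin_shift = np.linalg.norm([rig.tx, rig.ty])
        assert origin_shift < 0.1
        assert quality < 0.05

    def test_known_perturbation_recovered(self, phantom):
        template = sd.render_template(phantom, "truth")
        shift_px = np.array([12.0, -7.0])
        pert = mt.Rigid2D.about_center(
            3.0, shift_px * RES, (sd.PAGE_SIZE_MM / 2, sd.PAGE_SIZE_MM / 2)
        )
        user = sd.render_page(
            contour_mm=phantom.contour,
            dots_mm=phantom.points,
            landmarks_mm=phantom.landmarks,
            transform_mm=lambda p: pert.apply(p),
        )
        rig, quality = mt.register_scan(template, user)
        expected = mt.Rigid2D(pert.theta_deg, pert.tx / RES, pert.ty / RES).inverse()
        assert abs(rig.theta_deg - expected.theta_deg) < 0.2
        assert abs(rig.tx - expected.tx) < 0.5
        assert abs(rig.ty - expected.ty) < 0.5
        assert quality < 0.5

    def test_blank_page_has_no_fiducials(self):
        white = mt.TraceScan(np.full((400, 400), 255, dtype=np.uint8))
        with pytest.raises(FiducialsNotFoundError):
            mt.register_scan(white, white)


class TestExtractPoints:
    def test_rendered_targets_recovered_within_tenth_mm(self, phantom, truth_template):
        centers = mt.extract_points(truth_template, sd.N_TARGET_POINTS)
        match = mt.match_points(phantom.points, centers)
        tre = mt.compute_tre(match)
        assert tre.samples_mm.max() < 0.1

    def test_blank_page_yields_count_mismatch(self, phantom):
        blank = sd.render_template(phantom, "blank")
        with pytest.raises(PointCountMismatchError) as exc:
            mt.extract_points(blank, sd.N_TARGET_POINTS)
        assert exc.value.found == 0

    def test_single_dot_center_respects_dpi_conversion(self):
        img = np.full((601, 601), 255, dtype=np.uint8)
        rr, cc = skdraw.disk((300, 300), 1.5 / RES)
        img[rr, cc] = 0
        centers = mt.extract_points(mt.TraceScan(img), 1)
        np.testing.assert_allclose(centers[0], [300 * RES, 300 * RES], atol=0.05)

    def test_dot_touching_trace_still_separable(self):
        # a dot overlapping a thin stroke must survive the stroke removal
        img = np.full((601, 601), 255, dtype=np.uint8)
        rr, cc = skdraw.disk((300, 300), 1.5 / RES)
        img[rr, cc] = 0
        rr, cc = skdraw.line(310, 0, 290, 600)
        for dy in range(-3, 4):
            img[np.clip(rr + dy, 0, 600), cc] = 0
        centers = mt.extract_points(mt.TraceScan(img), 1)
        np.testing.assert_allclose(centers[0], [300 * RES, 300 * RES], atol=0.3)


class TestMatchAndTre:
    def test_identical_pairs_give_zero_error(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        tre = mt.compute_tre(mt.match_points(pts, pts))
        assert np.all(tre.samples_mm == 0)
        assert tre.rmse_mm == 0

    def test_three_four_five_triangle(self):
        truth = np.array([[0.0, 0.0]])
        user = np.array([[3.0, 4.0]])
        tre = mt.compute_tre(mt.PointMatchResult(truth, user, [0]))
        assert tre.samples_mm[0] == pytest.approx(5.0)
        assert tre.rmse_mm == pytest.approx(5.0)  # single pair: sd = 0

    def test_rms_combines_bias_and_spread(self):
        assert mt.rms_from_mean_sd(0.98, 0.5) == pytest.approx(1.10, abs=0.005)
        assert mt.rms_from_mean_sd(3.0, 0.0) == pytest.approx(3.0)

    def test_matching_survives_shuffled_detection_order(self, rng):
        truth = rng.uniform(0, 100, size=(19, 2))
        truth = truth[np.argsort(truth[:, 0])]  # spread out enough not to collide
        user = truth + rng.normal(scale=0.5, size=truth.shape)
        shuffled = user[rng.permutation(19)]
        m = mt.match_points(truth, shuffled)
        d = np.linalg.norm(m.truth_mm - m.user_mm, axis=1)
        assert d.max() < 3.0  # each truth point got its own perturbed copy back

    def test_tre_invariant_under_common_rigid_motion(self, rng):
        truth = rng.uniform(0, 50, size=(10, 2))
        user = truth + rng.normal(scale=1.0, size=truth.shape)
        base = mt.compute_tre(mt.match_points(truth, user))
        rig = mt.Rigid2D(37.0, 12.0, -4.0)
        moved = mt.compute_tre(mt.match_points(rig.apply(truth), rig.apply(user)))
        np.testing.assert_allclose(
            np.sort(moved.samples_mm), np.sort(base.samples_mm), atol=1e-9
        )

    def test_empty_match_rejected(self):
        with pytest.raises(NoPairsError):
            mt.compute_tre(
                mt.PointMatchResult(np.empty((0, 2)), np.empty((0, 2)), [])
            )


def brute_force_assd(mask_g, mask_m, res):
    pg, pm = np.argwhere(mask_g), np.argwhere(mask_m)
    d = cdist(pg, pm)
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(pg) + len(pm)) * res


class TestAssd:
    def test_identical_contours_give_zero(self):
        c = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0]])
        assert mt.compute_assd(c, c) == 0.0

    def test_parallel_segments_two_mm_apart(self):
        g = np.array([[0.0, 0.0], [50.0, 0.0]])
        m = np.array([[0.0, 2.0], [50.0, 2.0]])
        assd = mt.compute_assd(g, m, resolution_mm=RES)
        assert assd == pytest.approx(2.0, rel=0.05)

    def test_symmetry_is_exact(self, rng):
        g = np.cumsum(rng.uniform(-2, 2, size=(6, 2)), axis=0) + 20
        m = np.cumsum(rng.uniform(-2, 2, size=(6, 2)), axis=0) + 20
        assert mt.compute_assd(g, m) == mt.compute_assd(m, g)

    def test_matches_brute_force_on_random_contours(self, rng):
        for _ in range(20):
            g = np.cumsum(rng.uniform(-1.5, 1.5, size=(rng.integers(3, 8), 2)), 0) + 10
            m = np.cumsum(rng.uniform(-1.5, 1.5, size=(rng.integers(3, 8), 2)), 0) + 10
            lo = np.minimum(g.min(0), m.min(0)) - 2 * RES
            hi = np.maximum(g.max(0), m.max(0)) + 2 * RES
            shape = (
                int(np.ceil((hi[1] - lo[1]) / RES)) + 1,
                int(np.ceil((hi[0] - lo[0]) / RES)) + 1,
            )
            mask_g = mt.rasterize_polyline(g, lo, shape, RES)
            mask_m = mt.rasterize_polyline(m, lo, shape, RES)
            fast = mt.assd_from_masks(mask_g, mask_m, RES)
            brute = brute_force_assd(mask_g, mask_m, RES)
            assert fast == pytest.approx(brute, rel=1e-9)

    def test_empty_contour_rejected(self):
        with pytest.raises(EmptyContourError):
            mt.compute_assd(np.empty((0, 2)), np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestFre:
    def test_identical_lists_give_zero(self, rng):
        pts = rng.normal(size=(5, 3))
        assert mt.compute_fre(pts, pts) == 0.0

    def test_single_pair_one_mm_apart(self):
        assert mt.compute_fre([[0, 0, 0]], [[1, 0, 0]]) == pytest.approx(1.0)

    def test_rms_of_mixed_pairs(self):
        m = [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]
        n = [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]
        assert mt.compute_fre(m, n) == pytest.approx(math.sqrt(0.5))

    def test_length_mismatch_rejected(self):
        with pytest.raises(CountMismatchError):
            mt.compute_fre([[0, 0, 0]], [[0, 0, 0], [1, 1, 1]])

    def test_sensitive_to_correspondence_not_set_equality(self, rng):
        pts = rng.normal(size=(6, 3))
        assert mt.compute_fre(pts, pts) == 0.0
        swapped = pts.copy()
        swapped[[0, 1]] = swapped[[1, 0]]
        assert mt.compute_fre(pts, swapped) > 0.0


class TestPercentImprovement:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(3.64, 1.89, 48), (1.26, 1.10, 13), (2.5, 2.5, 0)],
    )
    def test_reported_values(self, before, after, expected):
        assert mt.percent_improvement(before, after) == expected

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(InvalidBaselineError):
            mt.percent_improvement(0.0, 1.0)


class TestScanIO:
    def test_png_roundtrip_preserves_pixels_and_dpi(self, tmp_path, truth_template):
        path = tmp_path / "scan.png"
        truth_template.save_png(path)
        back = mt.TraceScan.load_png(path)
        assert back.dpi == truth_template.dpi
        np.testing.assert_array_equal(back.image, truth_template.image)
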