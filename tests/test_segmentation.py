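"""Threshold estimation, exclusion polygons, interior fill and the composed
pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrvolumetry import (ImageVolume, PhantomSpec, PlanarROI, ThresholdPlan,
                         apply_threshold, estimate_threshold, exclude_polygons,
                         fill_interior, pve_bounds_for_ratio, render_phantom,
                         segment_tumour)
from mrvolumetry.phantom import NecroticCore


def square_roi(slice_index, r0, c0, r1, c1):
    return PlanarROI(slice_index, [(r0, c0), (r0, c1), (r1, c1), (r1, c0)])


def brute_force_inside(poly_vertices, r, c):
    """Independent ray-casting point-in-polygon test (boundary not handled)."""
    n = len(poly_vertices)
    inside = False
    for i in range(n):
        r1, c1 = poly_vertices[i]
        r2, c2 = poly_vertices[(i + 1) % n]
        if (c1 > c) != (c2 > c):
            r_cross = r1 + (c - c1) / (c2 - c1) * (r2 - r1)
            if r < r_cross:
                inside = not inside
    return inside


class TestEstimateThreshold:
    def test_balanced_two_class_roi_gives_midpoint(self, two_class_image):
        image, truth = two_class_image
        # 6 columns of tumour (cols 3..8) and 6 of background (cols 9..14 -> clip)
        roi = square_roi(2, 3.0, 5.5, 8.0, 11.5)  # straddles the right edge
        thr = estimate_threshold(image, roi)
        sel_mean = 0.5 * (100 + 20)
        assert thr == pytest.approx(sel_mean)

    def test_constant_region_returns_value(self, two_class_image):
        image, _ = two_class_image
        assert estimate_threshold(image, square_roi(0, 4, 4, 7, 7)) == 100.0
        assert estimate_threshold(image, square_roi(0, 0, 0, 1, 1)) == 20.0

    def test_mean_of_mixed_values(self):
        thr = estimate_threshold(
            ImageVolume(np.array([[[100.0, 100.0, 40.0]]]), (160, 160, 160)),
            square_roi(0, -0.4, -0.4, 0.4, 2.4))
        assert thr == pytest.approx(80.0)

    def test_empty_roi_raises(self, two_class_image):
        image, _ = two_class_image
        with pytest.raises(ValueError, match="zero voxel centers"):
            estimate_threshold(image, square_roi(0, 0.1, 0.1, 0.4, 0.4))

    @given(n_t=st.integers(1, 6), v_t=st.floats(30, 200), v_b=st.floats(0, 29))
    def test_balanced_roi_midpoint_property(self, n_t, v_t, v_b):
        """Equal tumour/background counts under the ROI -> exact midpoint."""
        data = np.full((1, 2, 2 * n_t), v_b)
        data[0, :, :n_t] = v_t
        image = ImageVolume(data, (160, 160, 160))
        roi = square_roi(0, -0.5, -0.5, 1.5, 2 * n_t - 0.5)
        assert estimate_threshold(image, roi) == pytest.approx((v_t + v_b) / 2)


class TestApplyThreshold:
    def test_separable_classes_recover_truth(self, two_class_image):
        image, truth = two_class_image
        mask = apply_threshold(image, 60.0)
        assert np.array_equal(mask.labels, truth)
        assert mask.provenance  # non-empty after the operation

    def test_threshold_above_maximum_gives_empty_mask(self, two_class_image):
        image, _ = two_class_image
        assert apply_threshold(image, 101.0).voxel_count() == 0

    def test_per_slice_override_replaces_global(self, two_class_image):
        image, truth = two_class_image
        plan = ThresholdPlan(60.0, {1: 0.0})
        mask = apply_threshold(image, plan)
        assert mask.labels[1].all()  # override below slice minimum: fully tumour
        assert np.array_equal(mask.labels[0], truth[0])  # others per global

    def test_override_for_missing_slice_rejected(self, two_class_image):
        image, _ = two_class_image
        with pytest.raises(IndexError):
            apply_threshold(image, ThresholdPlan(60.0, {99: 10.0}))


class TestExcludePolygons:
    def test_whole_slice_polygon_clears_slice_only(self, two_class_image):
        image, truth = two_class_image
        mask = apply_threshold(image, 60.0)
        out = exclude_polygons(mask, [square_roi(2, -1, -1, 12, 12)])
        assert out.labels[2].sum() == 0
        assert np.array_equal(out.labels[0], truth[0])

    def test_empty_polygon_list_is_identity(self, two_class_image):
        image, _ = two_class_image
        mask = apply_threshold(image, 60.0)
        out = exclude_polygons(mask, [])
        assert np.array_equal(out.labels, mask.labels)

    def test_center_aligned_square_excludes_closed_interior(self):
        """A square with corners on voxel centers (2,2)-(5,5) removes the
        4x4 block of covered centers under the default boundary policy, and
        only the 2x2 strict interior when boundary voxels stay tumour."""
        labels = np.ones((1, 8, 8), dtype=bool)
        from mrvolumetry import SegMask
        mask = SegMask(labels, (160, 160, 160), [{"op": "synthetic"}])
        out = exclude_polygons(mask, [square_roi(0, 2, 2, 5, 5)])
        assert (~out.labels[0]).sum() == 16
        removed = np.argwhere(~out.labels[0])
        assert removed.min() == 2 and removed.max() == 5
        out_t = exclude_polygons(mask, [square_roi(0, 2, 2, 5, 5)],
                                 boundary_policy="tumour")
        assert (~out_t.labels[0]).sum() == 4

    @given(st.data())
    def test_matches_brute_force_point_in_polygon(self, data):
        """Exclusion agrees with an independent ray-casting oracle on random
        convex quadrilaterals whose edges avoid voxel centers."""
        rng_pts = data.draw(st.lists(
            st.tuples(st.floats(0.3, 9.3), st.floats(0.3, 9.3)),
            min_size=4, max_size=4, unique=True))
        pts = np.array(rng_pts)
        hull_center = pts.mean(axis=0)
        order = np.argsort(np.arctan2(*(pts - hull_center).T))
        verts = [tuple(pts[i] + 0.017) for i in order]  # nudge off centers
        try:
            roi = PlanarROI(0, verts)
        except ValueError:
            return  # degenerate draw
        from mrvolumetry import SegMask
        mask = SegMask(np.ones((1, 10, 10), dtype=bool), (160, 160, 160),
                       [{"op": "synthetic"}])
        out = exclude_polygons(mask, [roi])
        for r in range(10):
            for c in range(10):
                assert out.labels[0, r, c] != brute_force_inside(verts, r, c)

    def test_vertex_order_and_polygon_order_invariance(self, two_class_image):
        image, _ = two_class_image
        mask = apply_threshold(image, 60.0)
        p1 = square_roi(1, 3, 3, 5, 5)
        p2 = square_roi(2, 6, 6, 8, 8)
        p1_rev = PlanarROI(1, list(p1.vertices)[::-1])
        a = exclude_polygons(mask, [p1, p2])
        b = exclude_polygons(mask, [p2, p1_rev])
        assert np.array_equal(a.labels, b.labels)

    def test_exclusion_never_increases_count(self, two_class_image):
        image, _ = two_class_image
        mask = apply_threshold(image, 60.0)
        out = exclude_polygons(mask, [square_roi(1, 2, 2, 9, 9)])
        assert out.voxel_count() <= mask.voxel_count()

    def test_out_of_range_slice_raises(self, two_class_image):
        image, _ = two_class_image
        mask = apply_threshold(image, 60.0)
        with pytest.raises(IndexError):
            exclude_polygons(mask, [square_roi(7, 2, 2, 4, 4)])


class TestFillInterior:
    def test_annulus_fills_to_disk(self, annulus_mask):
        filled = fill_interior(annulus_mask)
        rr, cc = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        disk = np.hypot(rr - 8, cc - 8) <= 6
        assert np.array_equal(filled.labels[0], disk)

    def test_border_connected_background_unchanged(self):
        from mrvolumetry import SegMask
        labels = np.zeros((1, 8, 8), dtype=bool)
        labels[0, 2:6, 2:6] = True
        labels[0, 3:5, 3:5] = False
        labels[0, 4, 4:] = False  # channel to the border
        mask = SegMask(labels, (160, 160, 160), [{"op": "synthetic"}])
        filled = fill_interior(mask)
        assert np.array_equal(filled.labels, labels)

    def test_idempotent_and_never_decreases(self, annulus_mask):
        once = fill_interior(annulus_mask)
        twice = fill_interior(once)
        assert np.array_equal(once.labels, twice.labels)
        assert once.voxel_count() >= annulus_mask.voxel_count()

    def test_seeded_fill_converts_only_seeded_component(self):
        from mrvolumetry import SegMask
        labels = np.zeros((1, 12, 20), dtype=bool)
        labels[0, 1:9, 1:9] = True
        labels[0, 3:6, 3:6] = False  # hole A
        labels[0, 1:9, 11:19] = True
        labels[0, 3:6, 13:16] = False  # hole B
        mask = SegMask(labels, (160, 160, 160), [{"op": "synthetic"}])
        filled = fill_interior(mask, seeds=[(0, 4, 4)], connectivity="slice")
        assert filled.labels[0, 4, 4]
        assert not filled.labels[0, 4, 14]  # hole B untouched

    def test_seed_inside_tumour_warns_and_noop(self, annulus_mask):
        with pytest.warns(UserWarning, match="inside the tumour"):
            out = fill_interior(annulus_mask, seeds=[(0, 8, 2)])
        assert np.array_equal(out.labels, annulus_mask.labels)

    def test_seed_out_of_bounds_raises(self, annulus_mask):
        with pytest.raises(IndexError):
            fill_interior(annulus_mask, seeds=[(0, 99, 0)])

    def test_thick_stack_fills_slicewise(self):
        """In a 2D stack an axial tunnel open at both end slices is a hole
        in every slice and gets filled; in a 3D volume it stays open."""
        labels = np.zeros((3, 8, 8), dtype=bool)
        labels[:, 1:7, 1:7] = True
        labels[:, 3:5, 3:5] = False  # tunnel through all slices
        from mrvolumetry import SegMask
        stack = SegMask(labels, (700, 150, 200), [{"op": "synthetic"}])
        assert fill_interior(stack).labels.all(axis=None) is np.True_ or \
            fill_interior(stack).labels[:, 1:7, 1:7].all()
        volume = SegMask(labels, (160, 160, 160), [{"op": "synthetic"}])
        assert not fill_interior(volume).labels[1, 4, 4]


class TestSegmentTumourPipeline:
    def test_sphere_phantom_mass_within_pve_bounds(self):
        """Noise-free sphere 28 voxels across, ROI straddling the rim: the
        recovered mass stays inside the extreme over/under PVE bounds for a
        voxels-per-diameter ratio of 28."""
        spec = PhantomSpec(semi_axes_um=(2240.0,) * 3, spacing_um=(160.0,) * 3)
        image, _, analytic_mm3 = render_phantom(spec)
        center = image.shape[1] // 2
        edge_col = image.shape[2] // 2 + 14
        roi = square_roi(image.shape[0] // 2, center - 4, edge_col - 4,
                         center + 4, edge_col + 4)
        mask, est = segment_tumour(image, roi)
        over, under = pve_bounds_for_ratio(28, classifier="exact_box")
        rel_err = 100 * (est.volume_mm3 - analytic_mm3) / analytic_mm3
        assert under - 1e-9 <= rel_err <= over + 1e-9

    def test_necrotic_core_phantom_recovers_full_volume(self):
        """An enclosed low-signal core is converted back to tumour, so the
        mass matches the core-included analytic volume within PVE bounds."""
        spec = PhantomSpec(
            semi_axes_um=(2240.0,) * 3, spacing_um=(160.0,) * 3,
            necrotic_cores=(NecroticCore((0.0, 0.0, 0.0), 800.0, 10.0),))
        image, _, analytic_mm3 = render_phantom(spec)
        center = image.shape[1] // 2
        roi = square_roi(image.shape[0] // 2, center - 4, center + 10,
                         center + 4, center + 18)
        mask, est = segment_tumour(image, roi)
        over, under = pve_bounds_for_ratio(28, classifier="exact_box")
        rel_err = 100 * (est.volume_mm3 - analytic_mm3) / analytic_mm3
        assert under - 1e-9 <= rel_err <= over + 1e-9

    def test_nothing_above_threshold_gives_zero_mass(self, two_class_image):
        image, _ = two_class_image
        mask, est = segment_tumour(image, square_roi(0, 3, 3, 8, 8),
                                   overrides={i: 1e6 for i in range(5)})
        assert est.mass_g == 0.0
        assert mask.voxel_count() == 0
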