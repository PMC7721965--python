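import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_geometry, random_star_polygon, square_ring
from lidckit.lidc_xml import ContourRoi, NoduleAnnotation
from lidckit.rasterize import (
    DegenerateContourError,
    MaskBuildError,
    build_mask,
    rasterize_roi,
)
from oracles import mask_oracle, strict_interior_oracle


def roi(points, sop="1.2.3.0", inclusion=True):
    return ContourRoi(sop, 0.0, inclusion, tuple(points))


class TestStrictInterior:
    def test_square_ring_5x5_has_9_interior_pixels(self):
        mask = rasterize_roi(roi(square_ring(0, 0, 5)), (10, 10))
        assert mask.sum() == 9
        assert mask[1:4, 1:4].all()

    def test_smallest_ring_3x3_single_center_pixel(self):
        mask = rasterize_roi(roi(square_ring(0, 0, 3)), (5, 5))
        assert mask.sum() == 1
        assert mask[1, 1]

    def test_collinear_points_degenerate(self):
        with pytest.raises(DegenerateContourError, match="collinear|area"):
            rasterize_roi(roi([(0, 0), (2, 2), (4, 4)]), (10, 10))

    def test_fewer_than_three_points_degenerate(self):
        with pytest.raises(DegenerateContourError):
            rasterize_roi(roi([(0, 0), (1, 1)]), (10, 10))

    def test_contour_points_outside_image_rejected(self):
        with pytest.raises(MaskBuildError, match="bounds"):
            rasterize_roi(roi([(0, 0), (20, 0), (10, 10)]), (10, 10))

    def test_self_intersecting_contour_warns_even_odd(self):
        bowtie = [(0, 0), (6, 6), (6, 0), (0, 6)]
        with pytest.warns(UserWarning, match="self-intersecting"):
            mask = rasterize_roi(roi(bowtie), (8, 8))
        # the crossing at (3,3) splits the bowtie into left and right lobes
        oracle = np.zeros((8, 8), dtype=bool)
        for tri in ([(0, 0), (0, 6), (3, 3)], [(6, 0), (6, 6), (3, 3)]):
            oracle |= strict_interior_oracle(tri, (8, 8))
        assert np.array_equal(mask, oracle)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_shapely_oracle_on_random_polygons(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(30):
            pts = random_star_polygon(rng)
            mask = rasterize_roi(roi(pts), (20, 20))
            assert np.array_equal(mask, strict_interior_oracle(pts, (20, 20)))

    def test_no_contour_path_pixel_is_ever_foreground(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            pts = random_star_polygon(rng)
            mask = rasterize_roi(roi(pts), (20, 20))
            for x, y in pts:
                assert not mask[y, x], f"contour pixel ({x},{y}) marked foreground"

    def test_invariant_to_reversal_and_rotation(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = random_star_polygon(rng)
            base = rasterize_roi(roi(pts), (20, 20))
            assert np.array_equal(base, rasterize_roi(roi(pts[::-1]), (20, 20)))
            shift = int(rng.integers(1, len(pts)))
            rotated = pts[shift:] + pts[:shift]
            assert np.array_equal(base, rasterize_roi(roi(rotated), (20, 20)))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6), shift=st.integers(1, 11))
    def test_fill_invariant_under_cyclic_rotation_property(self, seed, shift):
        pts = random_star_polygon(np.random.default_rng(seed))
        base = rasterize_roi(roi(pts), (20, 20))
        rotated = pts[shift % len(pts):] + pts[: shift % len(pts)]
        assert np.array_equal(base, rasterize_roi(roi(rotated), (20, 20)))

    def test_explicitly_closed_contour_equals_open(self):
        pts = square_ring(2, 2, 5)
        closed = pts + [pts[0]]
        a = rasterize_roi(roi(pts), (12, 12))
        b = rasterize_roi(roi(closed), (12, 12))
        assert np.array_equal(a, b)


class TestBuildMask:
    def test_include_minus_exclude_ring_arithmetic(self):
        g = make_geometry(image_shape=(16, 16))
        ann = NoduleAnnotation(
            "a",
            (
                roi(square_ring(0, 0, 9)),  # strict interior 7x7 = 49
                roi(square_ring(2, 2, 5), inclusion=False),  # strict interior 3x3 = 9
            ),
        )
        mask = build_mask(ann, g)
        assert mask.foreground_count == 40
        assert mask.nonempty_slices == [0]

    def test_three_slice_stack_of_rings(self):
        g = make_geometry(image_shape=(8, 8))
        rois = tuple(roi(square_ring(0, 0, 5), sop=f"1.2.3.{k}") for k in range(3))
        mask = build_mask(NoduleAnnotation("a", rois), g)
        assert mask.foreground_count == 27
        assert mask.nonempty_slices == [0, 1, 2]

    def test_exclusion_without_inclusion_contributes_nothing(self):
        g = make_geometry(image_shape=(16, 16))
        ann = NoduleAnnotation(
            "a",
            (
                roi(square_ring(0, 0, 5), sop="1.2.3.0"),
                roi(square_ring(0, 0, 5), sop="1.2.3.1", inclusion=False),
            ),
        )
        mask = build_mask(ann, g)
        assert mask.nonempty_slices == [0]

    def test_unresolvable_slice_reference_named_in_error(self):
        g = make_geometry()
        ann = NoduleAnnotation("a", (roi(square_ring(0, 0, 5), sop="9.9.9"),))
        with pytest.raises(MaskBuildError, match="9.9.9"):
            build_mask(ann, g)

    def test_empty_result_is_an_error(self):
        g = make_geometry(image_shape=(16, 16))
        ann = NoduleAnnotation("a", (roi(square_ring(0, 0, 5), inclusion=False),))
        with pytest.raises(MaskBuildError, match="empty"):
            build_mask(ann, g)

    def test_adding_exclusion_never_increases_foreground(self):
        g = make_geometry(image_shape=(24, 24))
        rng = np.random.default_rng(3)
        for _ in range(20):
            inc = random_star_polygon(rng, center=(12, 12), r_max=10)
            exc = random_star_polygon(rng, center=(12, 12), r_max=6)
            base = build_mask(NoduleAnnotation("a", (roi(inc),)), g)
            with_exc = NoduleAnnotation("a", (roi(inc), roi(exc, inclusion=False)))
            try:
                n = build_mask(with_exc, g).foreground_count
            except MaskBuildError:
                n = 0  # exclusion swallowed everything
            assert n <= base.foreground_count

    def test_matches_include_exclude_oracle_on_random_fixtures(self):
        g = make_geometry(image_shape=(24, 24))
        rng = np.random.default_rng(11)
        for _ in range(40):
            inc = [random_star_polygon(rng, center=(10, 10), r_max=8)]
            exc = []
            if rng.random() < 0.5:
                exc.append(random_star_polygon(rng, center=(10, 10), r_max=4))
            rois = [roi(p) for p in inc] + [roi(p, inclusion=False) for p in exc]
            oracle = mask_oracle(inc, exc, (24, 24))
            if not oracle.any():
                continue
            mask = build_mask(NoduleAnnotation("a", tuple(rois)), g)
            assert np.array_equal(mask.slice_mask(0), oracle)

    def test_multiple_included_rois_on_one_slice_union(self):
        g = make_geometry(image_shape=(20, 20))
        ann = NoduleAnnotation(
            "a", (roi(square_ring(0, 0, 5)), roi(square_ring(10, 10, 5)))
        )
        assert build_mask(ann, g).foreground_count == 18

    def test_voxel_order_is_column_row_slice(self):
        g = make_geometry(image_shape=(16, 12), n_slices=4)
        ann = NoduleAnnotation("a", (roi(square_ring(0, 0, 5), sop="1.2.3.2"),))
        mask = build_mask(ann, g)
        assert mask.voxels.shape == (12, 16, 4)  # (columns, rows, slices)
        assert mask.voxels[1, 1, 2]
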