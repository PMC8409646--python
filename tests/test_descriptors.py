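"""Scalar shape descriptors and descriptor-table assembly."""
import numpy as np
import pytest

import pitchshapes as ps
from pitchshapes.descriptors import describe_shape, descriptor_matrix
from pitchshapes.errors import DataError

from conftest import random_hull


def mer_grid_oracle(polygon, step_deg=0.1):
    """Exhaustive orientation scan: min axis-aligned bbox area over rotations."""
    v = polygon.vertices
    best = np.inf
    for theta in np.arange(0.0, 90.0, step_deg):
        t = np.radians(theta)
        R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        w = v @ R.T
        area = np.ptp(w[:, 0]) * np.ptp(w[:, 1])
        best = min(best, area)
    return best


class TestRectangularity:
    def test_axis_aligned_rectangle_is_one(self):
        rect = ps.make_canonical_shape("rectangle", scale=12.0, aspect=3.0)
        assert ps.rectangularity(rect) == pytest.approx(1.0, abs=1e-9)

    def test_rotated_rectangle_is_one(self):
        rect = ps.make_canonical_shape("rectangle", scale=12.0, aspect=3.0)
        t = np.radians(30.0)
        R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        rotated = ps.convex_hull(rect.vertices @ R.T)
        assert ps.rectangularity(rotated) == pytest.approx(1.0, abs=1e-9)

    def test_any_triangle_is_half(self):
        tri = ps.convex_hull([(0.0, 0.0), (7.0, 1.0), (3.0, 5.0)])
        assert ps.rectangularity(tri) == pytest.approx(0.5, abs=1e-9)

    def test_regular_64gon_approaches_circle_in_square(self, ngon64_polygon):
        assert ps.rectangularity(ngon64_polygon) == pytest.approx(np.pi / 4, abs=0.01)

    @pytest.mark.parametrize("seed", range(10))
    def test_calipers_match_orientation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        poly = random_hull(rng)
        calipers = poly.area / ps.rectangularity(poly)
        oracle = mer_grid_oracle(poly)
        assert calipers == pytest.approx(oracle, rel=1e-3)
        assert ps.rectangularity(poly) <= 1.0 + 1e-12

    def test_axis_aligned_mode_uses_bounding_box(self):
        tri = ps.convex_hull([(0.0, 0.0), (4.0, 0.0), (0.0, 4.0)])
        assert ps.rectangularity(tri, axis_aligned=True) == pytest.approx(0.5, abs=1e-12)


class TestCircularityAndAP:
    def test_square_circularity_is_16(self, square_polygon):
        assert ps.circularity(square_polygon) == pytest.approx(16.0, abs=1e-9)

    def test_regular_64gon_near_disk_minimum(self, ngon64_polygon):
        assert ps.circularity(ngon64_polygon) == pytest.approx(4 * np.pi, rel=0.005)

    def test_circularity_at_least_disk_bound(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            assert ps.circularity(random_hull(rng)) >= 4 * np.pi - 1e-6

    def test_ngon_circularity_decreases_toward_limit(self):
        values = [
            ps.circularity(ps.make_canonical_shape("regular_ngon", scale=5.0, n=n))
            for n in (4, 8, 16, 32, 64)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] > 4 * np.pi

    def test_scale_invariance_to_machine_precision(self):
        rng = np.random.default_rng(21)
        poly = random_hull(rng)
        scaled = poly.scaled(3.0)
        assert ps.circularity(scaled) == pytest.approx(ps.circularity(poly), abs=1e-9)
        assert ps.rectangularity(scaled) == pytest.approx(ps.rectangularity(poly), abs=1e-9)

    def test_square_side_4_ap_is_one(self):
        sq = ps.make_canonical_shape("square", scale=4.0)
        assert ps.ap_ratio(sq) == pytest.approx(1.0, abs=1e-12)

    def test_ap_scales_linearly(self):
        rng = np.random.default_rng(31)
        poly = random_hull(rng)
        assert ps.ap_ratio(poly.scaled(2.5)) == pytest.approx(2.5 * ps.ap_ratio(poly), rel=1e-9)

    def test_64gon_ap_is_half_radius(self, ngon64_polygon):
        assert ps.ap_ratio(ngon64_polygon) == pytest.approx(10.0 / 2, rel=0.005)


class TestAllDescriptors:
    def test_concatenation_order(self):
        fv = ps.all_descriptors(1.0, 2.0, 16.0, 1.1, 1.0)
        assert fv.descriptor_name == "AllD"
        assert fv.values.tolist() == [1.0, 2.0, 16.0, 1.1, 1.0]

    def test_excludes_curve_samples(self):
        assert len(ps.all_descriptors(1, 2, 3, 4, 5).values) == 5

    def test_nonfinite_component_rejected(self):
        with pytest.raises(DataError):
            ps.all_descriptors(1.0, np.nan, 16.0, 1.1, 1.0)

    def test_component_positions_independent(self):
        base = ps.all_descriptors(1, 2, 16, 1.1, 1).values
        bumped = ps.all_descriptors(1, 2, 17, 1.1, 1).values
        assert (base != bumped).tolist() == [False, False, True, False, False]


class TestDescriptorTable:
    def test_rows_and_columns(self, small_table):
        assert len(small_table) == 16
        assert list(small_table.columns[:6]) == [
            "image_id", "AP", "FA", "Circularity", "MF", "Rectangularity",
        ]
        assert sum(c.startswith("MFC_") for c in small_table.columns) == 100

    def test_degenerate_image_skipped_not_fatal(self, small_collection, caplog):
        items = list(small_collection[0][:3])
        mask = np.zeros((30, 30), bool)
        mask[14:16, 14:16] = True
        bad_img = ps.BinaryShapeImage(mask=mask, pixel_size=0.2, padding_px=14)
        items.append(("bad", items[0][1], bad_img))
        table = ps.descriptor_table(items)
        assert len(table) == 3
        assert "bad" not in set(table["image_id"])

    def test_deterministic_rerun(self, small_collection):
        items = small_collection[0][:4]
        t1 = ps.descriptor_table(items)
        t2 = ps.descriptor_table(items)
        assert t1.equals(t2)

    def test_table_consistent_with_describe_shape(self, small_collection, small_table):
        image_id, poly, image = small_collection[0][0]
        scalars, curve = describe_shape(poly, image)
        row = small_table.loc[small_table["image_id"] == image_id].iloc[0]
        assert row["Circularity"] == pytest.approx(scalars["Circularity"])
        assert row["MF"] == pytest.approx(curve.MF)

    def test_feature_vector_extraction(self, small_table):
        image_id = small_table["image_id"].iloc[0]
        assert len(ps.feature_vector(small_table, image_id, "MFC").values) == 100
        assert len(ps.feature_vector(small_table, image_id, "AllD").values) == 5
        assert len(ps.feature_vector(small_table, image_id, "MF").values) == 1
        ids, X = descriptor_matrix(small_table, "AllD")
        assert X.shape == (16, 5) and len(ids) == 16
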