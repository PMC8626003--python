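"""Normalization, embedding, minimum-area rectangle and pixel mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tximage import (
    ExpressionMatrix,
    FeatureMap,
    embed_features,
    fit_feature_map,
    min_area_rectangle,
    normalize_norm2,
    apply_normalization,
    pixels_to_genes,
    transform_to_images,
)
from conftest import random_expression


def brute_force_min_area(points: np.ndarray, step_deg: float = 0.01) -> float:
    """Independent oracle: minimum bounding-box area over a fine rotation grid."""
    best = np.inf
    for deg in np.arange(0.0, 90.0, step_deg):
        t = np.deg2rad(deg)
        c, s = np.cos(t), np.sin(t)
        rot = points @ np.array([[c, -s], [s, c]])
        ext = rot.max(axis=0) - rot.min(axis=0)
        best = min(best, ext[0] * ext[1])
    return best


class TestNormalizeNorm2:
    def test_log2_then_minmax(self):
        m = ExpressionMatrix(["g"], ["a", "b", "c"], [[0.0, 1.0, 3.0]])
        out, params = normalize_norm2(m)
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])
        assert params.loc["g", "min"] == 0.0 and params.loc["g", "max"] == 2.0

    def test_constant_gene_maps_to_zero(self):
        m = ExpressionMatrix(["g"], ["a", "b", "c"], [[5.0, 5.0, 5.0]])
        out, _ = normalize_norm2(m)
        np.testing.assert_array_equal(out.values, [[0.0, 0.0, 0.0]])

    def test_two_point_gene_hits_endpoints(self):
        m = ExpressionMatrix(["g"], ["a", "b"], [[0.0, 3.0]])
        out, _ = normalize_norm2(m)
        np.testing.assert_allclose(out.values, [[0.0, 1.0]])

    def test_transform_time_clipping(self):
        train = ExpressionMatrix(["g"], ["a", "b"], [[1.0, 3.0]])
        _, params = normalize_norm2(train)
        held_out = ExpressionMatrix(["g"], ["z"], [[100.0]])  # outside training range
        out = apply_normalization(held_out, params)
        assert out.values[0, 0] == 1.0


class TestEmbedFeatures:
    def test_deterministic_given_seed(self):
        m = random_expression(40, 12, seed=3)
        norm, _ = normalize_norm2(m)
        a = embed_features(norm, method="tsne", seed=9)
        b = embed_features(norm, method="tsne", seed=9)
        np.testing.assert_array_equal(a, b)

    def test_kpca_linear_recovers_principal_directions(self):
        # rank-2 matrix: embedding must match the top-2 PCA scores up to sign
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, 6))
        weights = rng.standard_normal((25, 2)) * np.array([3.0, 1.0])
        X = weights @ basis
        m = ExpressionMatrix([f"g{i}" for i in range(25)], [f"s{j}" for j in range(6)], X - X.min())
        coords = embed_features(m, method="kpca", seed=0)
        Xc = m.values - m.values.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        scores = Xc @ vt[:2].T
        for k in range(2):
            dot = np.dot(coords[:, k], scores[:, k])
            np.testing.assert_allclose(
                coords[:, k], np.sign(dot) * scores[:, k], atol=1e-8
            )

    def test_fewer_than_three_genes_rejected(self):
        m = ExpressionMatrix(["a", "b"], ["s1", "s2", "s3"], np.ones((2, 3)))
        with pytest.raises(ValueError, match="3 genes"):
            embed_features(m)


class TestMinAreaRectangle:
    def test_axis_aligned_square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        angle, corners = min_area_rectangle(pts)
        assert angle == pytest.approx(0.0, abs=1e-9)
        assert _area(corners) == pytest.approx(1.0)

    def test_diamond_rotated_45_degrees(self):
        pts = np.array([[0, 0], [1, 1], [2, 0], [1, -1]], float)
        angle, corners = min_area_rectangle(pts)
        assert _area(corners) == pytest.approx(2.0, rel=1e-9)
        assert angle == pytest.approx(np.pi / 4, abs=1e-9)
        assert _area(corners) == pytest.approx(brute_force_min_area(pts), rel=1e-3)

    def test_collinear_points_zero_height(self):
        angle, corners = min_area_rectangle(np.array([[0, 0], [1, 0], [2, 0]], float))
        assert _area(corners) == pytest.approx(0.0, abs=1e-12)

    def test_single_point(self):
        angle, corners = min_area_rectangle(np.array([[2.0, 3.0]]))
        assert angle == 0.0
        np.testing.assert_array_equal(corners, np.full((4, 2), [2.0, 3.0]))

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((int(rng.integers(3, 50)), 2)) * rng.gamma(2, 2)
        _, corners = min_area_rectangle(pts)
        oracle = brute_force_min_area(pts, step_deg=0.02)
        assert _area(corners) <= oracle * (1 + 1e-3)
        assert _area(corners) >= oracle * (1 - 1e-3)

    def test_area_rotation_invariant(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((30, 2))
        _, corners = min_area_rectangle(pts)
        base = _area(corners)
        for t in (0.3, 1.1, 2.0):
            c, s = np.cos(t), np.sin(t)
            _, corners_r = min_area_rectangle(pts @ np.array([[c, -s], [s, c]]))
            assert _area(corners_r) == pytest.approx(base, rel=1e-3)


def _area(corners: np.ndarray) -> float:
    e1 = np.linalg.norm(corners[1] - corners[0])
    e2 = np.linalg.norm(corners[2] - corners[1])
    return float(e1 * e2)


class TestFeatureMap:
    def test_well_separated_genes_get_distinct_pixels(self):
        coords = np.array([[0, 0], [0, 10], [10, 0], [10, 10]], float)
        m = random_expression(4, 5, seed=1)
        norm, _ = normalize_norm2(m)
        fm = fit_feature_map(norm, grid_size=380, coords=coords)
        assert len(fm.genes_of_pixel) == 4
        assert all(len(v) == 1 for v in fm.genes_of_pixel.values())

    def test_grid_size_below_two_rejected(self):
        m = random_expression(4, 5, seed=1)
        with pytest.raises(ValueError, match="grid_size"):
            fit_feature_map(m, grid_size=1, coords=np.zeros((4, 2)))

    def test_duplicated_gene_profile_shares_pixel(self):
        m = random_expression(10, 8, seed=2)
        m.values[7] = m.values[3]  # exact duplicate profile
        norm, _ = normalize_norm2(m)
        fm = fit_feature_map(norm, grid_size=64, method="kpca", seed=0)
        assert fm.pixel_of_gene("g3") == fm.pixel_of_gene("g7")

    def test_round_trip_and_multiplicity_conservation(self):
        m = random_expression(200, 10, seed=4)
        norm, _ = normalize_norm2(m)
        fm = fit_feature_map(norm, grid_size=30, method="kpca", seed=0)
        for g in fm.gene_ids:
            assert g in fm.genes_of_pixel[fm.pixel_of_gene(g)]
        assert sum(len(v) for v in fm.genes_of_pixel.values()) == fm.n_genes

    def test_boundary_points_land_inside_grid(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.5], [2.0, 1.0]])
        m = random_expression(3, 4, seed=0)
        fm = fit_feature_map(m, grid_size=10, coords=coords)
        assert fm.rows.max() < 10 and fm.cols.max() < 10
        assert fm.rows.min() >= 0 and fm.cols.min() >= 0

    def test_serialization_round_trip(self, tmp_path):
        m = random_expression(20, 6, seed=7)
        norm, params = normalize_norm2(m)
        fm = fit_feature_map(norm, grid_size=40, method="kpca", seed=3, normalization_params=params)
        p = tmp_path / "fm.json"
        fm.save(p)
        fm2 = FeatureMap.load(p)
        assert fm2.grid_size == fm.grid_size
        assert fm2.gene_ids == fm.gene_ids
        np.testing.assert_array_equal(fm2.rows, fm.rows)
        np.testing.assert_array_equal(fm2.cols, fm.cols)
        np.testing.assert_allclose(
            fm2.normalization_params.to_numpy(), fm.normalization_params.to_numpy()
        )
        fm.save(tmp_path / "fm_b.json")
        assert (tmp_path / "fm.json").read_text() == (tmp_path / "fm_b.json").read_text()


class TestTransformToImages:
    def _map_with(self, gene_pixels, grid=8):
        genes = list(gene_pixels)
        rows = [gene_pixels[g][0] for g in genes]
        cols = [gene_pixels[g][1] for g in genes]
        return FeatureMap(
            grid_size=grid, method="precomputed", seed=0, rotation_angle=0.0,
            gene_ids=genes, embedding_coords=np.zeros((len(genes), 2)),
            rows=np.array(rows), cols=np.array(cols),
        )

    def test_collision_averaging(self):
        fm = self._map_with({"a": (2, 3), "b": (2, 3)})
        m = ExpressionMatrix(["a", "b"], ["s"], [[0.2], [0.4]])
        stack = transform_to_images(m, fm)
        assert stack.images[0, 2, 3] == pytest.approx(0.3)

    def test_single_gene_single_pixel(self):
        fm = self._map_with({"a": (5, 1)})
        m = ExpressionMatrix(["a"], ["s"], [[1.0]])
        img = transform_to_images(m, fm).images[0]
        assert img[5, 1] == 1.0
        assert img.sum() == 1.0

    def test_all_zero_sample_gives_blank_image(self):
        fm = self._map_with({"a": (0, 0), "b": (4, 4)})
        m = ExpressionMatrix(["a", "b"], ["s"], [[0.0], [0.0]])
        assert transform_to_images(m, fm).images.sum() == 0.0

    def test_unknown_gene_rejected(self):
        fm = self._map_with({"a": (0, 0)})
        m = ExpressionMatrix(["zzz"], ["s"], [[0.5]])
        with pytest.raises(KeyError, match="zzz"):
            transform_to_images(m, fm)

    def test_linearity_in_sample_vector(self):
        m = random_expression(30, 6, seed=9)
        norm, _ = normalize_norm2(m)
        fm = fit_feature_map(norm, grid_size=12, method="kpca", seed=0)
        base = transform_to_images(norm, fm).images
        scaled = ExpressionMatrix(norm.gene_ids, norm.sample_ids, norm.values * 0.25)
        np.testing.assert_allclose(
            transform_to_images(scaled, fm).images, 0.25 * base, atol=1e-6
        )

    def test_pixels_to_genes_inverse_and_empty(self):
        fm = self._map_with({"a": (1, 1), "b": (1, 1), "c": (3, 0)})
        sets = pixels_to_genes(fm, [(1, 1), (0, 0), (3, 0)])
        assert sets[0] == {"a", "b"}
        assert sets[1] == frozenset()
        assert sets[2] == {"c"}
        with pytest.raises(ValueError, match="outside"):
            pixels_to_genes(fm, [(99, 0)])
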