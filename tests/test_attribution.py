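"""Expected-gradient attributions: completeness, top-k selection, gene support."""

import numpy as np
import pytest

from tximage import (
    ImageStack,
    aggregate_gene_support,
    attribute_pixels,
    select_background,
    top_k_pixels,
)
from tximage.attribution import AttributionStack
from tximage.classify import TrainedClassifier
from tximage.image import FeatureMap
from tximage import nn as tnn


def stack(images, prefix="s"):
    images = np.asarray(images, dtype=np.float32)
    return ImageStack([f"{prefix}{i}" for i in range(len(images))], images)


class LinearModel:
    """f(x) = w . x + b, no sigmoid — attribution has a closed form."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=np.float64)
        self.b = b

    def predict_proba(self, X, batch_size=None):
        return (X[..., 0] * self.w).sum(axis=(1, 2)) + self.b

    def input_gradient(self, X, batch_size=None):
        return np.broadcast_to(self.w[..., None], X.shape).copy()


def linear_clf(w, b=0.0):
    return TrainedClassifier("cnn", LinearModel(w, b))


class TestSelectBackground:
    def test_full_selection_is_whole_stack(self):
        s = stack(np.random.default_rng(0).random((7, 4, 4)))
        bg = select_background(s, n=7, seed=0)
        assert bg.sample_ids == s.sample_ids

    def test_deterministic_given_seed(self):
        s = stack(np.random.default_rng(0).random((30, 4, 4)))
        a = select_background(s, n=10, seed=42)
        b = select_background(s, n=10, seed=42)
        assert a.sample_ids == b.sample_ids

    def test_subset_is_unique_and_bounded(self):
        s = stack(np.random.default_rng(1).random((50, 4, 4)))
        bg = select_background(s, n=20, seed=3)
        assert len(set(bg.sample_ids)) == 20

    def test_oversized_request_rejected(self):
        s = stack(np.zeros((3, 4, 4)))
        with pytest.raises(ValueError, match="background"):
            select_background(s, n=4)


class TestAttributePixels:
    def test_constant_model_gives_zero_attributions(self):
        rng = np.random.default_rng(0)
        clf = linear_clf(np.zeros((5, 5)), b=0.3)
        att = attribute_pixels(clf, stack(rng.random((3, 5, 5))), stack(rng.random((4, 5, 5))))
        np.testing.assert_allclose(att.values, 0.0, atol=1e-12)

    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(1)
        w = np.zeros((4, 4))
        w[1, 2] = 0.7  # single active pixel
        targets = stack(rng.random((3, 4, 4)))
        background = stack(rng.random((6, 4, 4)))
        att = attribute_pixels(linear_clf(w), targets, background, n_steps=4)
        bg_mean = background.images.mean(axis=0)
        for i in range(3):
            expect = 0.7 * (targets.images[i, 1, 2] - bg_mean[1, 2])
            assert att.values[i, 1, 2] == pytest.approx(float(expect), rel=1e-5)
            assert att.values[i].sum() == pytest.approx(att.values[i, 1, 2], abs=1e-7)

    def test_linear_model_completeness_exact(self):
        rng = np.random.default_rng(2)
        w = rng.standard_normal((6, 6)) * 0.1
        targets = stack(rng.random((5, 6, 6)))
        background = stack(rng.random((8, 6, 6)))
        att = attribute_pixels(linear_clf(w), targets, background, n_steps=2)
        assert att.completeness_residuals.max() < 1e-5

    def test_empty_background_rejected(self):
        clf = linear_clf(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="empty"):
            attribute_pixels(clf, stack(np.zeros((1, 4, 4))), stack(np.zeros((0, 4, 4))))

    def test_cnn_completeness_within_tolerance(self):
        """Trained CNN: per-sample sum of attributions matches f(x) - E_bg f."""
        from tximage import CNNConfig, build_cnn, train_cnn

        rng = np.random.default_rng(5)
        n, size = 40, 16
        y = (rng.random(n) < 0.6).astype(int)
        imgs = rng.random((n, size, size)) * 0.3
        imgs[y == 1, 3:6, 3:6] += 0.5
        s = stack(np.clip(imgs, 0, 1))
        cfg = CNNConfig(input_size=size, conv_depths=(4, 8), dense_units=16, epochs=20,
                        validation_fraction=0.0, seed=1, learning_rate=2e-3)
        clf = train_cnn(build_cnn(cfg), s, y, cfg)
        background = select_background(s, n=20, seed=0)
        att = attribute_pixels(clf, s.subset(range(8)), background, n_steps=64)
        for i in range(8):
            gap = att.model_outputs[i] - np.mean(clf.predict_proba(background))
            assert att.completeness_residuals[i] <= 0.05 * max(abs(gap), 0.05)


class TestTopKPixels:
    def _att(self, values):
        values = np.asarray(values, dtype=float)
        return AttributionStack(
            sample_ids=[f"s{i}" for i in range(len(values))],
            values=values,
            background_ids=["b"],
            model_expectation=0.0,
            model_outputs=np.zeros(len(values)),
            completeness_residuals=np.zeros(len(values)),
        )

    def test_unique_maximum(self):
        v = np.zeros((1, 6, 6))
        v[0, 2, 4] = 1.0
        assert top_k_pixels(self._att(v), k=1) == [[(2, 4)]]

    def test_tie_breaks_by_coordinate(self):
        v = np.zeros((1, 6, 6))
        v[0, 0, 5] = 1.0
        v[0, 3, 1] = 1.0
        assert top_k_pixels(self._att(v), k=1) == [[(0, 5)]]

    def test_k_equals_grid_returns_all_sorted(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((1, 3, 3))
        pix = top_k_pixels(self._att(v), k=9)[0]
        vals = [v[0, r, c] for r, c in pix]
        assert vals == sorted(vals, reverse=True)
        assert len(set(pix)) == 9

    def test_absolute_mode_ranks_by_magnitude(self):
        v = np.zeros((1, 4, 4))
        v[0, 1, 1] = -5.0
        v[0, 2, 2] = 1.0
        assert top_k_pixels(self._att(v), k=1, mode="absolute") == [[(1, 1)]]
        assert top_k_pixels(self._att(v), k=1, mode="signed") == [[(2, 2)]]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            top_k_pixels(self._att(np.zeros((1, 2, 2))), k=5)


def toy_map():
    return FeatureMap(
        grid_size=6, method="precomputed", seed=0, rotation_angle=0.0,
        gene_ids=["gA", "gB", "gC", "gD"],
        embedding_coords=np.zeros((4, 2)),
        rows=np.array([0, 0, 2, 5]), cols=np.array([1, 1, 3, 5]),
    )  # gA and gB share pixel (0,1)


class TestAggregateGeneSupport:
    def test_counting_and_filtering(self):
        fm = toy_map()
        tops = [[(0, 1)], [(0, 1)], [(0, 1)], [(2, 3)]]
        rep = aggregate_gene_support(tops, fm, min_support=2)
        assert rep.support["gA"] == 3 and rep.support["gC"] == 1
        assert rep.ranked["gene_id"].tolist() == ["gA", "gB"]
        assert rep.ranked["support"].tolist() == [3, 3]

    def test_min_support_at_sample_count_empties_report(self):
        fm = toy_map()
        rep = aggregate_gene_support([[(0, 1)]] * 3, fm, min_support=3)
        assert rep.ranked.empty

    def test_support_invariant_to_sample_order(self):
        fm = toy_map()
        tops = [[(0, 1)], [(2, 3)], [(5, 5)], [(0, 1)]]
        a = aggregate_gene_support(tops, fm, min_support=0).support
        b = aggregate_gene_support(tops[::-1], fm, min_support=0).support
        assert a.to_dict() == b.to_dict()

    def test_never_selected_gene_has_zero_support(self):
        fm = toy_map()
        rep = aggregate_gene_support([[(0, 1)]], fm, min_support=0)
        assert rep.support["gD"] == 0

    def test_shared_pixel_genes_have_identical_support(self):
        fm = toy_map()
        rng = np.random.default_rng(0)
        tops = [
            [(int(rng.integers(0, 6)), int(rng.integers(0, 6))) for _ in range(2)]
            for _ in range(20)
        ]
        rep = aggregate_gene_support(tops, fm, min_support=0)
        assert rep.support["gA"] == rep.support["gB"]

    def test_proportional_default_min_support(self):
        fm = toy_map()
        rep = aggregate_gene_support([[(0, 1)]] * 10, fm)
        assert rep.min_support == 4  # ceil(0.36 * 10)

    def test_rank_ties_break_by_gene_id(self):
        fm = toy_map()
        tops = [[(0, 1), (2, 3)]] * 2
        rep = aggregate_gene_support(tops, fm, min_support=0)
        assert rep.top(3) == ["gA", "gB", "gC"]
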