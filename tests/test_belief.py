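"""Belief-value transform: distances, weights, effects, oracle equivalence."""

import numpy as np
import pytest

from bvfusion import (
    ConfigurationError,
    DstConfig,
    belief_value,
    belief_vector,
    classify_bv,
    fit_margin_classifier,
    gaussian_weight,
    neighbor_effect,
    normalize_distances,
    pairwise_distance,
)
from oracles import belief_value_straightline


def _random_model(seed, n=20, dim=3, separation=1.0):
    g = np.random.default_rng(seed)
    n_pos = n // 2
    X = np.vstack(
        [
            g.normal(size=(n - n_pos, dim)) - separation,
            g.normal(size=(n_pos, dim)) + separation,
        ]
    )
    y = np.array([-1] * (n - n_pos) + [1] * n_pos)
    return fit_margin_classifier(X, y, C=1.0), g


class TestDistances:
    def test_hand_computed_mahalanobis(self):
        d = pairwise_distance([0.0, 0.0], [1.0, 2.0], "mahalanobis", np.diag([1.0, 4.0]))
        assert d == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        x, xj = rng.normal(size=3), rng.normal(size=3)
        maha = pairwise_distance(x, xj, "mahalanobis", np.eye(3))
        assert maha == pytest.approx(pairwise_distance(x, xj, "euclidean"), rel=1e-12)

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "mahalanobis"])
    def test_identity_of_indiscernibles_and_symmetry(self, metric, rng):
        x, xj = rng.normal(size=4), rng.normal(size=4)
        cov = np.eye(4)
        assert pairwise_distance(x, x, metric, cov) == pytest.approx(0.0, abs=1e-12)
        assert pairwise_distance(x, xj, metric, cov) == pytest.approx(
            pairwise_distance(xj, x, metric, cov), rel=1e-12
        )


class TestNormalizeAndWeight:
    def test_hand_computed_z_scores(self):
        np.testing.assert_allclose(
            normalize_distances([1.0, 2.0, 3.0]), [-1.22474, 0.0, 1.22474], atol=1e-5
        )

    def test_centering_and_constant_contract(self, rng):
        d = rng.uniform(0, 10, size=17)
        assert normalize_distances(d).mean() == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_array_equal(normalize_distances(np.full(5, 3.3)), np.zeros(5))

    def test_gaussian_weight_values_and_shape(self):
        assert gaussian_weight(0.0) == pytest.approx(0.39894, abs=1e-5)
        assert gaussian_weight(1.0) == pytest.approx(0.24197, abs=1e-5)
        assert gaussian_weight(-1.0) == gaussian_weight(1.0)
        assert gaussian_weight(2.0) < gaussian_weight(1.0)


class TestNeighborEffect:
    def test_modes(self):
        assert neighbor_effect(0.4, 0.7) == pytest.approx(0.28)
        assert neighbor_effect(0.4, 0.7, "s") == 0.7
        assert neighbor_effect(0.4, -0.7, "w") == pytest.approx(-0.4)
        assert neighbor_effect(0.4, 0.0) == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            neighbor_effect(0.4, 0.7, "nope")


class TestBeliefValue:
    @pytest.mark.parametrize("metric", ["euclidean", "manhattan", "mahalanobis"])
    @pytest.mark.parametrize("mode", ["w", "s", "w_times_s"])
    def test_equals_straightline_oracle(self, metric, mode):
        for seed in range(15):
            model, g = _random_model(seed, n=16, dim=3)
            x = g.normal(size=3) * 2
            cfg = DstConfig(distance_metric=metric, effect_mode=mode)
            expected = belief_value_straightline(
                model.w, model.b, model.X_train, model.y_train, x,
                metric=metric, effect_mode=mode, cov_shrinkage=cfg.cov_shrinkage,
            )
            assert belief_value(model, x, cfg) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_gaussian_peak_under_product_mode(self):
        phi0 = 1.0 / np.sqrt(2 * np.pi)
        for seed in range(10):
            model, g = _random_model(seed)
            bv = belief_value(model, g.normal(size=3), DstConfig())
            assert abs(bv) <= phi0 + 1e-12

    def test_label_flip_negates_belief_value(self):
        model, g = _random_model(3, n=18, dim=2)
        x = g.normal(size=2)
        flipped = fit_margin_classifier(model.X_train, -model.y_train, C=1.0)
        cfg = DstConfig(distance_metric="euclidean")
        assert belief_value(flipped, x, cfg) == pytest.approx(
            -belief_value(model, x, cfg), abs=1e-8
        )

    def test_separated_classes_recover_labels_of_held_out_points(self):
        model, g = _random_model(5, n=30, dim=2, separation=4.0)
        for label in (-1, 1):
            for _ in range(10):
                x = g.normal(size=2) + 4.0 * label
                bv = belief_value(model, x, DstConfig())
                assert classify_bv(bv) == label

    def test_empty_side_falls_back_to_own_margin_probability(self):
        # weak regularisation leaves every training point predicted
        # positive; a test point beyond the boundary has no neighbours
        from bvfusion import margin_probability, signed_distance

        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([-1, 1, 1, 1])
        model = fit_margin_classifier(X, y, C=0.01)
        assert np.all(model.train_sides == 1)
        boundary = -model.b / model.w[0]
        x = np.array([boundary - 100.0 if model.w[0] > 0 else boundary + 100.0])
        assert signed_distance(model, x) < 0
        expected = margin_probability(signed_distance(model, x))
        assert belief_value(model, x) == pytest.approx(expected)


class TestClassifyAndVector:
    def test_sign_and_tie_break(self):
        assert classify_bv(0.1) == 1
        assert classify_bv(-0.0001) == -1
        assert classify_bv(0.0, svm_side=1) == 1
        assert classify_bv(0.0, svm_side=-1) == -1

    def test_belief_vector_composition_and_order(self):
        models = {}
        xs = {}
        for i, name in enumerate(["mean", "alff", "sampen"]):
            model, g = _random_model(seed=i, n=14, dim=2)
            models[name] = model
            xs[name] = g.normal(size=2)
        bv = belief_vector(models, xs, "subj-1")
        assert bv.F.shape == (3,)
        cfg = DstConfig()
        for i, name in enumerate(["mean", "alff", "sampen"]):
            assert bv.F[i] == pytest.approx(belief_value(models[name], xs[name], cfg))
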