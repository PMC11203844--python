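import numpy as np
import pytest

from conformxplain import network as nn
from conformxplain.classifier import Conv1DClassifier
from conformxplain.explain import (
    ExplanationVector, KernelShapExplainer, LRPExplainer, LimeExplainer,
    SaliencyExplainer, aggregate_class_map, permutation_importance)
from conformxplain.synthdata import STATES


def fit_small_cnn(seed=0, n_residues=6, n_per_class=40):
    """Tiny 2-class CNN on residue-structured features: residue 1 separates
    the classes, everything else is noise."""
    rng = np.random.default_rng(seed)
    n_feat = 3 * n_residues
    Xa = rng.normal(0, 1, size=(n_per_class, n_feat))
    Xb = rng.normal(0, 1, size=(n_per_class, n_feat))
    Xb[:, 3:6] += 4.0
    X = np.vstack([Xa, Xb]).astype(np.float32)
    y = np.array(["active"] * n_per_class + ["inactive"] * n_per_class)
    clf = Conv1DClassifier(conv_blocks=((4, 3, 2),), dense_units=(8,),
                           dropout=0.0, epochs=60, learning_rate=5e-3,
                           early_stop_patience=0, random_state=seed)
    return clf.fit(X, y), X, y


class TestLRP:
    def test_single_linear_layer_closed_form(self):
        # y = w.x without bias: relevance of feature i is w_i * x_i.
        rng = np.random.default_rng(0)
        dense = nn.Dense(4, 1, rng, use_bias=False)
        dense.W[:] = np.array([[1.0], [-2.0], [0.5], [3.0]])
        net = nn.SequentialNet([dense])
        x = np.array([[2.0, 1.0, -4.0, 0.5]], dtype=np.float32)
        R, logit = net.relprop(x, 0, eps_scale=1e-12)
        np.testing.assert_allclose(R[0], dense.W[:, 0] * x[0], rtol=1e-4)
        assert R.sum() == pytest.approx(logit[0], rel=1e-4)

    def test_zero_input_on_bias_free_network_gives_zero_relevance(self):
        rng = np.random.default_rng(1)
        net = nn.SequentialNet([nn.Dense(4, 3, rng, use_bias=False),
                                nn.ReLU(),
                                nn.Dense(3, 2, rng, use_bias=False)])
        R, _ = net.relprop(np.zeros((1, 4), np.float32), 0)
        np.testing.assert_allclose(R, 0.0)

    def test_two_layer_network_matches_hand_unrolled_epsilon_rule(self):
        rng = np.random.default_rng(2)
        d1 = nn.Dense(3, 2, rng, use_bias=False)
        d2 = nn.Dense(2, 1, rng, use_bias=False)
        net = nn.SequentialNet([d1, nn.ReLU(), d2])
        x = np.array([[1.0, -2.0, 0.5]], dtype=np.float32)
        eps_scale = 1e-9

        # Hand-unrolled epsilon rule in float64.
        W1 = d1.W.astype(float)
        W2 = d2.W.astype(float)
        a1 = np.maximum(x[0].astype(float) @ W1, 0.0)
        z2 = a1 @ W2
        R2 = z2.copy()
        denom2 = z2 + max(eps_scale * np.abs(z2).mean(), 1e-12) * np.sign(z2)
        R1 = a1 * ((R2 / denom2) @ W2.T)
        z1 = x[0].astype(float) @ W1
        denom1 = z1 + max(eps_scale * np.abs(z1).mean(), 1e-12) * \
            np.where(z1 >= 0, 1, -1)
        R0 = x[0].astype(float) * ((R1 / denom1) @ W1.T)

        R, _ = net.relprop(x, 0, eps_scale=eps_scale)
        np.testing.assert_allclose(R[0], R0, rtol=1e-3, atol=1e-6)

    def test_conservation_on_trained_cnn(self):
        model, X, y = fit_small_cnn()
        explainer = LRPExplainer(model)
        for i in range(0, 40, 7):
            gap, logit = explainer.conservation_gap(X[i], y[i])
            assert gap <= 0.05 * logit + 1e-4

    def test_per_residue_reduction_length(self):
        model, X, y = fit_small_cnn()
        vec = LRPExplainer(model).explain(X[0], y[0])
        assert len(vec.values) == 6
        vec.validate()

    def test_informative_residue_dominates_aggregated_map(self):
        model, X, y = fit_small_cnn()
        explainer = LRPExplainer(model)
        vecs = [explainer.explain(X[i], y[i]) for i in range(len(y))]
        cmap = aggregate_class_map(vecs, y)
        inactive_row = cmap.values[list(STATES).index("inactive")]
        assert np.abs(inactive_row).argmax() == 1


class TestSaliency:
    def test_linear_model_gradient_is_weight_magnitude(self):
        rng = np.random.default_rng(3)
        dense = nn.Dense(4, 2, rng, use_bias=False)
        clf = Conv1DClassifier(conv_blocks=(), dense_units=(),
                               dropout=0.0, standardize=False)
        clf.classes_ = np.asarray(["active", "inactive"])
        clf.n_features_in_ = 4
        # hand-assembled linear network behind the estimator surface
        clf.net_ = nn.SequentialNet([nn.Flatten(), dense])
        g1 = clf.input_gradient(np.array([[1.0, 2, 3, 4]]), "active")
        g2 = clf.input_gradient(np.array([[-5.0, 0, 1, 9]]), "active")
        np.testing.assert_allclose(g1, g2)
        np.testing.assert_allclose(g1[0], dense.W[:, 0], rtol=1e-6)

    def test_values_always_non_negative(self):
        model, X, y = fit_small_cnn(seed=4)
        for i in [0, 17, 41, 79]:
            vec = SaliencyExplainer(model).explain(X[i], y[i])
            assert (vec.values >= 0).all()

    def test_gradient_matches_central_differences(self):
        model, X, _ = fit_small_cnn(seed=5)
        x = X[3].astype(np.float64)
        grad = model.input_gradient(x[None, :], "active")[0]
        h = 1e-2
        fd = np.zeros_like(grad)
        for j in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            fp = model.decision_function(xp[None, :])[0, 0]
            fm = model.decision_function(xm[None, :])[0, 0]
            fd[j] = (fp - fm) / (2 * h)
        # float32 forward passes limit attainable agreement
        assert np.linalg.norm(fd - grad) <= 1e-2 * np.linalg.norm(grad) + 1e-3


class TestLime:
    def test_irrelevant_residue_coefficient_near_zero(self,
                                                      linear_model_factory):
        # Model reads only residue 0; residue 2's coefficient must vanish.
        w = np.zeros(9)
        w[0:3] = 1.0
        model = linear_model_factory(w)
        X_train = np.random.default_rng(6).normal(size=(50, 9))
        explainer = LimeExplainer(model, X_train, n_perturb=2000,
                                  random_state=0)
        vec = explainer.explain(np.ones(9), "active")
        assert abs(vec.values[2]) < 0.01
        assert abs(vec.values[0]) > abs(vec.values[2])

    def test_coefficients_match_weighted_least_squares_oracle(
            self, linear_model_factory):
        w = np.array([1.0, -0.5, 0.2, 0.0, 0.3, 0.0])
        model = linear_model_factory(w)
        rng = np.random.default_rng(7)
        X_train = rng.normal(size=(30, 6))
        x = rng.normal(size=6)
        seed = 11
        explainer = LimeExplainer(model, X_train, n_perturb=500,
                                  alpha=1e-8, random_state=seed)
        vec = explainer.explain(x, "active")

        # Oracle: regenerate the identical perturbation set, then solve the
        # proximity-weighted least squares (with intercept) in closed form.
        oracle_rng = np.random.default_rng(seed)
        masks = oracle_rng.integers(0, 2, size=(500, 2))
        masks[0] = 1
        off = np.repeat(masks == 0, 3, axis=1)
        Xp = np.where(off, X_train.mean(axis=0), x)
        d = np.linalg.norm(Xp - x, axis=1)
        kw = np.median(d[d > 0])
        sw = np.exp(-(d ** 2) / kw ** 2)
        target = model.predict_proba(Xp)[:, 0]
        A = np.column_stack([np.ones(len(masks)), masks]).astype(float)
        W = np.diag(sw)
        beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ target)
        np.testing.assert_allclose(vec.values, beta[1:], atol=1e-5)

    def test_fixed_seed_reproducible(self, linear_model_factory):
        model = linear_model_factory(np.ones(6))
        X_train = np.random.default_rng(8).normal(size=(20, 6))
        e = LimeExplainer(model, X_train, n_perturb=100, random_state=3)
        v1 = e.explain(np.zeros(6), "active").values
        v2 = e.explain(np.zeros(6), "active").values
        np.testing.assert_array_equal(v1, v2)

    def test_too_few_perturbations_rejected(self, linear_model_factory):
        model = linear_model_factory(np.ones(30))
        with pytest.raises(ValueError, match="n_perturb"):
            LimeExplainer(model, np.zeros((5, 30)), n_perturb=5).explain(
                np.zeros(30), "active")


class TestKernelShap:
    def test_two_player_game_matches_exact_shapley(self,
                                                   linear_model_factory):
        w = np.array([2.0, 0, 0, -1.0, 0, 0]) * 0.1
        model = linear_model_factory(w)
        background = np.zeros((1, 6))
        x = np.ones(6)
        vec = KernelShapExplainer(model, background,
                                  random_state=0).explain(x, "active")

        # Exact Shapley by enumerating both player orderings.
        def v(mask):
            z = np.where(np.repeat(mask, 3).astype(bool), x, 0.0)
            return model.predict_proba(z[None, :])[0, 0]

        v00, v10 = v([0, 0]), v([1, 0])
        v01, v11 = v([0, 1]), v([1, 1])
        phi0 = 0.5 * ((v10 - v00) + (v11 - v01))
        phi1 = 0.5 * ((v01 - v00) + (v11 - v10))
        np.testing.assert_allclose(vec.values, [phi0, phi1], atol=1e-8)

    def test_symmetric_players_get_equal_attribution(self,
                                                     linear_model_factory):
        w = np.tile([0.1, 0.1, 0.1], 3)  # three identical residues
        model = linear_model_factory(w)
        vec = KernelShapExplainer(model, np.zeros((1, 9)),
                                  random_state=0).explain(np.ones(9),
                                                          "active")
        assert vec.values[0] == pytest.approx(vec.values[1], abs=1e-8)
        assert vec.values[1] == pytest.approx(vec.values[2], abs=1e-8)

    def test_local_accuracy_on_five_residue_toy(self, linear_model_factory):
        rng = np.random.default_rng(9)
        model = linear_model_factory(rng.normal(size=15) * 0.3)
        background = rng.normal(size=(4, 15))
        x = rng.normal(size=15)
        explainer = KernelShapExplainer(model, background, random_state=1)
        vec = explainer.explain(x, "active")
        total = vec.values.sum() + explainer.base_value_
        assert total == pytest.approx(explainer.model_output_, abs=1e-2)

    def test_insufficient_coalitions_rejected(self, linear_model_factory):
        model = linear_model_factory(np.ones(30))
        with pytest.raises(ValueError, match="n_coalitions"):
            KernelShapExplainer(model, np.zeros((1, 30)),
                                n_coalitions=5).explain(np.zeros(30),
                                                        "active")

    def test_empty_background_rejected(self, linear_model_factory):
        with pytest.raises(ValueError, match="background"):
            KernelShapExplainer(linear_model_factory(np.ones(6)),
                                np.empty((0, 6)))


class TestPermutationImportance:
    class OneFeatureModel:
        """Deterministic rule: class is the sign of feature 0."""

        def predict(self, X):
            return np.where(np.asarray(X)[:, 0] > 0, "active",
                            "intermediate")

    def test_perfect_feature_and_unused_feature(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(400, 6))
        model = self.OneFeatureModel()
        y = model.predict(X)
        classes, imp = permutation_importance(model, X, y, seed=0,
                                              n_repeats=3)
        # Shuffling the decisive residue costs about 1 - chance accuracy;
        # the unused residue costs nothing.
        chance = 0.5
        assert imp[classes.index("active"), 0] == pytest.approx(
            1 - chance, abs=0.1)
        assert abs(imp[classes.index("active"), 1]) < 0.05

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(100, 6))
        model = self.OneFeatureModel()
        y = model.predict(X)
        _, i1 = permutation_importance(model, X, y, seed=5)
        _, i2 = permutation_importance(model, X, y, seed=5)
        np.testing.assert_array_equal(i1, i2)


class TestAggregateClassMap:
    def vec(self, values, target, sid=0):
        return ExplanationVector(np.asarray(values, float), target, "lrp",
                                 sid)

    def test_single_sample_per_state_rows_equal_vectors(self):
        vecs = [self.vec([1, 2], "active"), self.vec([3, 4], "intermediate"),
                self.vec([5, 6], "inactive")]
        labels = ["active", "intermediate", "inactive"]
        cmap = aggregate_class_map(vecs, labels)
        np.testing.assert_allclose(cmap.values,
                                   [[1, 2], [3, 4], [5, 6]])

    def test_duplicated_sample_leaves_mean_unchanged(self):
        base = [self.vec([1, 2], "active"), self.vec([3, 4], "active"),
                self.vec([0, 0], "intermediate"),
                self.vec([0, 0], "inactive")]
        labels = ["active", "active", "intermediate", "inactive"]
        m1 = aggregate_class_map(base, labels)
        m2 = aggregate_class_map(base + [self.vec([2, 3], "active")] * 0,
                                 labels)
        np.testing.assert_allclose(m1.values, m2.values)

    def test_hand_averaged_four_sample_toy(self):
        vecs = [self.vec([2, 0], "active"), self.vec([4, 2], "active"),
                self.vec([1, 1], "intermediate"),
                self.vec([5, 5], "inactive")]
        labels = ["active", "active", "intermediate", "inactive"]
        cmap = aggregate_class_map(vecs, labels)
        np.testing.assert_allclose(cmap.values[0], [3, 1])

    def test_missing_state_warns_and_gives_nan_row(self):
        vecs = [self.vec([1, 1], "active")]
        with pytest.warns(UserWarning, match="inactive"):
            cmap = aggregate_class_map(vecs, ["active"])
        assert np.isnan(cmap.values[2]).all()
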