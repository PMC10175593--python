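import numpy as np
import pytest

from midfuse import plsda
from midfuse.data_model import DataError


def _two_class_data(rng, n=24, p=6, delta=5.0):
    y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    X = rng.normal(size=(n, p))
    X[y == "B", 0] += delta
    return X, y


class TestEncoding:
    def test_two_class_coding(self):
        Y, classes = plsda.encode_classes(["A", "B", "A"])
        np.testing.assert_array_equal(Y, [[1, 0], [0, 1], [1, 0]])
        assert classes == ("A", "B")

    def test_four_class_rows_sum_to_one(self):
        Y, classes = plsda.encode_classes(list("ABCD"))
        assert Y.shape == (4, 4)
        np.testing.assert_array_equal(Y.sum(axis=1), 1)

    def test_round_trip(self, rng):
        labels = list(rng.choice(list("XYZ"), size=30))
        Y, classes = plsda.encode_classes(labels)
        assert plsda.decode_classes(Y, classes) == labels

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            plsda.encode_classes(["A", "A"])


class TestNipalsFit:
    def test_full_rank_equals_least_squares(self, rng):
        """At A = rank(X) the PLS solution collapses to multi-output OLS."""
        X = rng.normal(size=(20, 8))
        y = rng.choice(list("AB"), size=20)
        model = plsda.fit_plsda(X, y, 8)
        Y, _ = plsda.encode_classes(y)
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        B_ols = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        np.testing.assert_allclose(model.B, B_ols, atol=1e-6)

    def test_single_x_single_component_closed_form(self, rng):
        """One predictor: the coefficient is cov(x, y)/var(x)."""
        x = rng.normal(size=(30, 1))
        y = np.where(x.ravel() + 0.3 * rng.normal(size=30) > 0, "A", "B")
        model = plsda.fit_plsda(x, y, 1)
        Y, _ = plsda.encode_classes(list(y))
        xc = x.ravel() - x.mean()
        yc = Y[:, 0] - Y[:, 0].mean()
        np.testing.assert_allclose(model.B[0, 0], (xc @ yc) / (xc @ xc), atol=1e-10)

    def test_perfect_predictor_dominates_coefficients(self, rng):
        X, y = _two_class_data(rng, delta=50.0)
        model = plsda.fit_plsda(X, y, 1)
        assert np.argmax(np.abs(model.B[:, 0])) == 0
        assert model.predict(X) == list(y)

    def test_score_orthogonality_and_b_identity(self, rng):
        X = rng.normal(size=(25, 10))
        y = rng.choice(list("ABC"), size=25)
        model = plsda.fit_plsda(X, y, 5)
        G = model.T.T @ model.T
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8
        B = model.W @ np.linalg.solve(model.P.T @ model.W, model.Q.T)
        np.testing.assert_allclose(model.B, B, atol=1e-8)

    def test_explained_x_variance_reaches_one_at_full_rank(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.choice(list("AB"), size=15)
        model = plsda.fit_plsda(X, y, 6)
        assert np.all(model.explained_x >= 0)
        assert model.explained_x.sum() == pytest.approx(1.0, abs=1e-8)

    def test_zero_variance_x_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(DataError, match="zero variance"):
            plsda.fit_plsda(X, ["A"] * 5 + ["B"] * 5, 2)

    def test_excessive_n_lv_rejected(self, rng):
        X, y = _two_class_data(rng, n=10, p=4)
        with pytest.raises(DataError, match="n_lv"):
            plsda.fit_plsda(X, y, 9)


class TestPredict:
    def test_argmax_rule_and_column_check(self, rng):
        X, y = _two_class_data(rng)
        model = plsda.fit_plsda(X, y, 2)
        preds, scores = plsda.predict_plsda(model, X)
        assert preds == [model.classes[j] for j in scores.argmax(axis=1)]
        with pytest.raises(DataError, match="columns"):
            model.predict(X[:, :3])

    def test_separable_training_data_all_correct(self, rng):
        X, y = _two_class_data(rng, delta=5.0)
        model = plsda.fit_plsda(X, y, 2)
        assert model.predict(X) == list(y)


class TestVip:
    def test_single_variable_vip_is_one(self, rng):
        x = rng.normal(size=(20, 1))
        y = np.where(x.ravel() > 0, "A", "B")
        model = plsda.fit_plsda(x, y, 1)
        np.testing.assert_allclose(plsda.compute_vip(model).scores, [1.0])

    def test_mean_squared_vip_is_one(self, rng):
        X = rng.normal(size=(30, 12))
        y = rng.choice(list("ABCD"), size=30)
        model = plsda.fit_plsda(X, y, 4)
        vip = plsda.compute_vip(model)
        assert np.mean(vip.scores**2) == pytest.approx(1.0, abs=1e-6)
        assert np.all(vip.scores >= 0)

    def test_formula_against_step_by_step_oracle(self, rng):
        """Recompute VIP component-by-component from the stored model."""
        X = rng.normal(size=(18, 5))
        y = rng.choice(list("AB"), size=18)
        model = plsda.fit_plsda(X, y, 3)
        p = 5
        ssy = np.array([(model.T[:, a] @ model.T[:, a]) * (model.Q[:, a] @ model.Q[:, a])
                        for a in range(3)])
        expected = np.empty(p)
        for j in range(p):
            acc = 0.0
            for a in range(3):
                w = model.W[:, a] / np.linalg.norm(model.W[:, a])
                acc += ssy[a] * w[j] ** 2
            expected[j] = np.sqrt(p * acc / ssy.sum())
        np.testing.assert_allclose(plsda.compute_vip(model).scores, expected,
                                   atol=1e-8)

    def test_threshold_zero_selects_everything(self, rng):
        X, y = _two_class_data(rng)
        model = plsda.fit_plsda(X, y, 2)
        assert plsda.compute_vip(model, threshold=0.0).selected == tuple(range(6))


class TestSelectNLv:
    def test_max_lv_one(self, rng):
        X, y = _two_class_data(rng)
        chosen, curve = plsda.select_n_lv(X, y, 1)
        assert chosen == 1 and curve.shape == (1,)

    def test_curve_length_matches_max_lv(self, rng):
        X, y = _two_class_data(rng)
        chosen, curve = plsda.select_n_lv(X, y, 4)
        assert curve.shape == (4,)
        assert 1 <= chosen <= 4

    def test_cap_warning_above_n_minus_two(self, rng, caplog):
        X, y = _two_class_data(rng, n=10, p=20)
        with caplog.at_level("WARNING"):
            _, curve = plsda.select_n_lv(X, y, 15)
        assert curve.shape == (8,)
        assert "capped" in caplog.text

    def test_single_informative_variable_prefers_one_component(self):
        """Class = sign of x1, noise elsewhere: A=1 should win parsimony."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 5))
            y = np.where(X[:, 0] > 0, "A", "B")
            X[:, 0] += 2.0 * np.sign(X[:, 0])   # widen the margin
            chosen, _ = plsda.select_n_lv(X, y, 3)
            hits += chosen == 1
        assert hits >= 18
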