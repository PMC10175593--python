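import numpy as np
import pytest

from midfuse import evaluation as ev
from midfuse import pcada, plsda
from midfuse.data_model import DataError

SPECIES = ("FU", "FP", "FD", "FUS")


def species_confusion_enose():
    """Confusion counts from the reported e-nose species model:
    3 FU->FD; 3 FP->FD; 1 FP->FUS; 1 FD->FP; 1 FUS->FU; 2 FUS->FP;
    1 FUS->FD, out of 20 per class."""
    counts = np.diag([20, 20, 20, 20])
    mis = {("FU", "FD"): 3, ("FP", "FD"): 3, ("FP", "FUS"): 1,
           ("FD", "FP"): 1, ("FUS", "FU"): 1, ("FUS", "FP"): 2,
           ("FUS", "FD"): 1}
    idx = {c: k for k, c in enumerate(SPECIES)}
    for (t, p), k in mis.items():
        counts[idx[t], idx[p]] += k
        counts[idx[t], idx[t]] -= k
    return ev.ConfusionMatrix(classes=SPECIES, counts=counts)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        cm = ev.confusion(list("AABB"), list("AABB"))
        np.testing.assert_array_equal(cm.counts, [[2, 0], [0, 2]])

    def test_row_sums_equal_class_sizes(self, rng):
        true = rng.choice(list("XYZ"), size=60)
        pred = rng.choice(list("XYZ"), size=60)
        cm = ev.confusion(list(true), list(pred), class_order=("X", "Y", "Z"))
        for k, c in enumerate(cm.classes):
            assert cm.counts[k].sum() == (true == c).sum()
        assert cm.total == 60

    def test_reported_misclassification_list_off_diagonal_sum(self):
        cm = species_confusion_enose()
        assert cm.total == 80
        assert cm.counts.sum() - np.trace(cm.counts) == 12

    def test_unseen_label_rejected(self):
        with pytest.raises(DataError, match="not in class order"):
            ev.confusion(["A", "B"], ["A", "C"], class_order=("A", "B"))


class TestMetrics:
    def test_enose_species_accuracy_85_percent(self):
        rep = ev.metrics(species_confusion_enose())
        assert rep.accuracy == pytest.approx(68 / 80)

    def test_etongue_species_accuracy(self):
        # 7/6/5/5 misclassified of 20 per class
        counts = np.diag([13, 14, 15, 15])
        # destinations unreported; put errors in one off-diagonal cell each
        counts[0, 1], counts[1, 0], counts[2, 3], counts[3, 2] = 7, 6, 5, 5
        rep = ev.metrics(ev.ConfusionMatrix(classes=SPECIES, counts=counts))
        assert rep.accuracy == pytest.approx(57 / 80)

    def test_all_correct_matrix_gives_ones(self):
        cm = ev.ConfusionMatrix(classes=("A", "B"), counts=np.diag([5, 5]))
        rep = ev.metrics(cm, positive_class="A")
        assert (rep.accuracy, rep.sensitivity, rep.specificity,
                rep.precision) == (1.0, 1.0, 1.0, 1.0)

    def test_accuracy_is_one_minus_offdiagonal_rate(self, rng):
        counts = rng.integers(0, 10, size=(3, 3))
        counts[np.diag_indices(3)] += 1
        cm = ev.ConfusionMatrix(classes=("A", "B", "C"), counts=counts)
        rep = ev.metrics(cm)
        off = counts.sum() - np.trace(counts)
        assert rep.accuracy == pytest.approx(1 - off / counts.sum())

    def test_binary_positive_class_definitions(self):
        cm = ev.ConfusionMatrix(classes=("FC", "COUNTERFEIT"),
                                counts=np.array([[55, 2], [3, 20]]))
        rep = ev.metrics(cm, positive_class="FC")
        assert rep.sensitivity == pytest.approx(55 / 57)
        assert rep.specificity == pytest.approx(20 / 23)
        assert rep.precision == pytest.approx(55 / 58)

    def test_empty_class_row_warns_and_skips(self):
        cm = ev.ConfusionMatrix(classes=("A", "B", "C"),
                                counts=np.array([[4, 0, 0], [0, 4, 0], [0, 0, 0]]))
        with pytest.warns(UserWarning, match="empty class"):
            rep = ev.metrics(cm)
        assert rep.sensitivity == pytest.approx(1.0)


class TestRocAuc:
    def test_separated_scores_auc_one(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        truth = ["P", "P", "N", "N"]
        _, auc = ev.roc_auc(scores, truth, "P")
        assert auc == pytest.approx(1.0)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            n = 30
            scores = rng.normal(size=n)
            truth = rng.choice(["P", "N"], size=n)
            if len(set(truth)) < 2:
                continue
            _, auc = ev.roc_auc(scores, truth, "P")
            pos = scores[truth == "P"]
            neg = scores[truth == "N"]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        truth = rng.choice(["P", "N"], size=40)
        _, auc1 = ev.roc_auc(scores, truth, "P")
        _, auc2 = ev.roc_auc(np.exp(3 * scores), truth, "P")
        assert auc2 == pytest.approx(auc1, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DataError, match="both classes"):
            ev.roc_auc([0.1, 0.2], ["P", "P"], "P")


class TestGroupTtest:
    def test_identical_groups_t_zero(self):
        t, p = ev.group_ttest([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                              ["A"] * 3 + ["B"] * 3)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_welch_formula_on_hand_example(self):
        # groups {1,2} and {4,6}: means 1.5, 5; variances 0.5, 2
        t, p = ev.group_ttest([1.0, 2.0, 4.0, 6.0], ["A", "A", "B", "B"])
        se = np.sqrt(0.5 / 2 + 2.0 / 2)
        assert abs(t) == pytest.approx(3.5 / se, rel=1e-9)

    def test_power_against_three_sigma_shift(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            v = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
            g = ["A"] * 20 + ["B"] * 20
            _, p = ev.group_ttest(v, g)
            hits += p < 0.05
        assert hits >= 38

    def test_zero_variance_both_groups_rejected(self):
        with pytest.raises(DataError, match="zero variance"):
            ev.group_ttest([1.0, 1.0, 2.0, 2.0], ["A", "A", "B", "B"])


class TestLoocv:
    def test_disjoint_constant_features_perfect(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0], [0.1], [4.9]])
        y = ["A", "A", "B", "B", "A", "B"]
        fit = lambda Xt, yt: plsda.fit_plsda(Xt, yt, 1)
        preds, _ = ev.loocv(X, y, fit)
        assert preds == y

    def test_equals_independent_loo_loop(self, rng):
        X = rng.normal(size=(16, 4))
        y = list(rng.choice(["A", "B"], size=16))
        y[:2] = ["A", "B"]          # both classes guaranteed
        fit = lambda Xt, yt: pcada.fit_pcada(Xt, yt, 2)
        preds, _ = ev.loocv(X, y, fit)
        manual = []
        for i in range(16):
            keep = np.arange(16) != i
            m = pcada.fit_pcada(X[keep], [y[j] for j in range(16) if keep[j]], 2)
            manual.append(m.predict(X[i: i + 1])[0])
        assert preds == manual

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(12, 3))
        y = list(rng.choice(["A", "B"], size=12))
        y[:2] = ["A", "B"]
        fit = lambda Xt, yt: plsda.fit_plsda(Xt, yt, 2)
        preds, _ = ev.loocv(X, y, fit)
        perm = rng.permutation(12)
        preds_p, _ = ev.loocv(X[perm], [y[j] for j in perm], fit)
        assert [preds[j] for j in perm] == preds_p

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError, match="more samples"):
            ev.loocv(np.zeros((2, 1)), ["A", "B"], lambda X, y: None)
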