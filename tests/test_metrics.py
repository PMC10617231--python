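"""Multi-label metrics against brute-force oracles and library cross-checks."""

import numpy as np
import pytest
from sklearn.metrics import f1_score, matthews_corrcoef

from pepfunc import (FunctionVocabulary, DEFAULT_FUNCTIONS, acc_example,
                     attention_summaries, binary_metrics, compute_report,
                     f1_label, group_report, label_cooccurrence_pearson,
                     representation_pearson, rkcc)
from pepfunc.metrics import assign_shot_groups
from pepfunc.network import AttentionRecord


def jaccard_oracle(Y, Yhat):
    """Set-arithmetic oracle for the example-based accuracy."""
    scores = []
    for yi, pi in zip(Y, Yhat):
        L = {j for j, v in enumerate(yi) if v}
        P = {j for j, v in enumerate(pi) if v}
        scores.append(1.0 if not L | P else len(L & P) / len(L | P))
    return float(np.mean(scores))


def auc_pair_oracle(y, scores):
    """Exhaustive concordant-pair counting with half-credit for ties."""
    pos = [s for s, t in zip(scores, y) if t]
    neg = [s for s, t in zip(scores, y) if not t]
    total = wins = 0
    for p in pos:
        for n in neg:
            total += 1
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / total


class TestAccExample:
    def test_perfect_prediction(self):
        Y = np.eye(4, dtype=int)
        assert acc_example(Y, Y) == 1.0

    def test_partial_overlap_single_sample(self):
        vocab = list(DEFAULT_FUNCTIONS)
        Y = np.zeros((1, 15), dtype=int)
        Yhat = np.zeros((1, 15), dtype=int)
        Y[0, [vocab.index("AMP"), vocab.index("TXP")]] = 1
        Yhat[0, [vocab.index("AMP"), vocab.index("ACP")]] = 1
        assert acc_example(Y, Yhat) == pytest.approx(1 / 3)

    def test_mean_over_samples(self):
        Y = np.array([[1, 1, 0], [1, 1, 0]])
        Yhat = np.array([[1, 1, 0], [1, 0, 1]])
        assert acc_example(Y, Yhat) == pytest.approx((1.0 + 1 / 3) / 2)

    def test_both_empty_counts_as_one(self):
        assert acc_example(np.zeros((2, 3)), np.zeros((2, 3))) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            acc_example(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_matches_set_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            Y = rng.integers(0, 2, (20, 5))
            Yhat = rng.integers(0, 2, (20, 5))
            assert acc_example(Y, Yhat) == pytest.approx(
                jaccard_oracle(Y, Yhat), abs=1e-12)


class TestF1Label:
    def test_perfect(self):
        Y = np.eye(4, dtype=int)
        assert f1_label(Y, Y) == 1.0

    def test_half_right_functions(self):
        Y = np.array([[1, 1], [0, 0], [1, 1]])
        Yhat = np.array([[1, 0], [0, 1], [1, 0]])
        assert f1_label(Y, Yhat) == pytest.approx(0.5)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(1)
        Y = rng.integers(0, 2, (15, 6))
        Yhat = rng.integers(0, 2, (15, 6))
        perm = rng.permutation(6)
        assert f1_label(Y, Yhat) == pytest.approx(
            f1_label(Y[:, perm], Yhat[:, perm]))

    def test_matches_sklearn_macro(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            Y = rng.integers(0, 2, (25, 5))
            Yhat = rng.integers(0, 2, (25, 5))
            assert f1_label(Y, Yhat) == pytest.approx(
                f1_score(Y, Yhat, average="macro", zero_division=0))


class TestBinaryMetrics:
    def test_perfect_separation(self):
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.2, 0.1])
        m = binary_metrics(y, s)
        assert m["auc"] == 1.0 and m["mcc"] == 1.0 and m["f1"] == 1.0

    def test_constant_scores_auc_half(self):
        m = binary_metrics(np.array([1, 0, 1, 0]), np.full(4, 0.3))
        assert m["auc"] == pytest.approx(0.5)

    def test_one_discordant_pair(self):
        m = binary_metrics(np.array([1, 1, 0, 0]),
                           np.array([0.9, 0.4, 0.6, 0.1]))
        assert m["auc"] == pytest.approx(0.75)

    def test_single_class_auc_missing(self):
        m = binary_metrics(np.ones(4), np.linspace(0, 1, 4))
        assert m["auc"] is None

    def test_auc_equals_pair_counting_on_small_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(2, 9)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            assert binary_metrics(y, s)["auc"] == pytest.approx(
                auc_pair_oracle(y, s), abs=1e-12)


class TestRkCC:
    def test_diagonal_confusion_is_one(self):
        assert rkcc(np.diag([4, 7, 2])) == pytest.approx(1.0)

    def test_binary_case_equals_mcc(self):
        M = np.array([[5, 2], [1, 7]])
        y_true = [0] * 7 + [1] * 8
        y_pred = [0] * 5 + [1] * 2 + [0] * 1 + [1] * 7
        assert rkcc(M) == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_uniform_confusion_is_zero(self):
        assert rkcc(np.full((3, 3), 4)) == pytest.approx(0.0)

    def test_degenerate_matrix_returns_zero(self):
        M = np.zeros((2, 2))
        M[0, 0] = 5
        assert rkcc(M) == 0.0

    def test_multiclass_matches_sklearn(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            y_true = rng.integers(0, 3, 60)
            y_pred = rng.integers(0, 3, 60)
            M = np.zeros((3, 3))
            for t, p in zip(y_true, y_pred):
                M[t, p] += 1
            assert rkcc(M) == pytest.approx(matthews_corrcoef(y_true, y_pred),
                                            abs=1e-12)


class TestShotGroups:
    def test_thresholds(self, vocab4):
        Y = np.zeros((1500, 4), dtype=int)
        Y[:1200, 0] = 1   # many (>1000)
        Y[:500, 1] = 1    # medium
        Y[:150, 2] = 1    # few (<200)
        Y[:200, 3] = 1    # boundary: exactly 200 -> medium
        groups = assign_shot_groups(Y, vocab4)
        assert list(groups.values()) == ["many", "medium", "few", "medium"]

    def test_single_group_equals_global(self, vocab4):
        rng = np.random.default_rng(5)
        Y = rng.integers(0, 2, (30, 4))
        Yhat = rng.integers(0, 2, (30, 4))
        groups = {n: "many" for n in vocab4}
        rep = group_report(Y, Yhat, vocab4, groups)
        assert rep["many"] == pytest.approx(f1_label(Y, Yhat))
        assert rep["medium"] is None and rep["few"] is None

    def test_contrasting_groups(self, vocab4):
        Y = np.tile([1, 1, 1, 1], (10, 1))
        Yhat = np.tile([1, 1, 0, 0], (10, 1))  # perfect on 0/1, wrong on 2/3
        names = list(vocab4)
        groups = {names[0]: "many", names[1]: "many",
                  names[2]: "few", names[3]: "few"}
        rep = group_report(Y, Yhat, vocab4, groups)
        assert rep["many"] == 1.0 and rep["few"] == 0.0

    def test_unassigned_function_rejected(self, vocab4):
        with pytest.raises(ValueError, match="without a shot group"):
            group_report(np.zeros((3, 4)), np.zeros((3, 4)), vocab4,
                         {list(vocab4)[0]: "many"})


class TestCorrelations:
    def test_identical_and_complementary_columns(self):
        Y = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1], [1, 1, 0]])
        cm = label_cooccurrence_pearson(Y)
        assert cm.values[0, 1] == pytest.approx(1.0)
        assert cm.values[0, 2] == pytest.approx(-1.0)
        assert np.allclose(cm.values, cm.values.T)

    def test_independent_toy_is_zero(self):
        Y = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        assert label_cooccurrence_pearson(Y).values[0, 1] == pytest.approx(0.0)

    def test_zero_variance_column_flagged(self):
        Y = np.array([[1, 1], [1, 0], [1, 1]])
        cm = label_cooccurrence_pearson(Y)
        assert cm.undefined[0, 1] and cm.values[0, 1] == 0.0

    def test_representation_correlations(self):
        Z1 = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        cm = representation_pearson([Z1])
        assert cm.values[0, 1] == pytest.approx(-1.0)
        Z2 = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        cm2 = representation_pearson([Z1, Z2])
        assert cm2.values[0, 1] == pytest.approx(0.0)   # mean of -1 and +1
        assert np.allclose(np.diag(cm2.values), 1.0)


class TestAttentionSummaries:
    def _record(self, ff, fr):
        return AttentionRecord(residue_residue=[ff],
                               function_function=[ff],
                               function_residue=[fr])

    def test_uniform_attention(self):
        C, L = 4, 6
        ff = np.full((1, 2, C, C), 1 / C)
        fr = np.full((1, 2, C, L), 1 / L)
        out = attention_summaries([self._record(ff, fr)])
        assert np.allclose(out["function_received"], 1 / C)
        assert np.allclose(out["residue_received"], 1 / L)

    def test_hand_computed_column_means(self):
        ff = np.array([[[[0.9, 0.1], [0.3, 0.7]]]])
        fr = np.array([[[[0.5, 0.25, 0.25], [0.2, 0.3, 0.5]]]])
        out = attention_summaries([self._record(ff, fr)])
        assert np.allclose(out["function_received"], [0.6, 0.4])
        assert out["function_received"].sum() == pytest.approx(1.0)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            attention_summaries([])


def test_compute_report_is_complete(vocab4):
    rng = np.random.default_rng(6)
    Y = rng.integers(0, 2, (40, 4))
    probs = rng.random((40, 4))
    groups = {n: g for n, g in zip(vocab4, ("many", "medium", "few", "few"))}
    rep = compute_report(Y, probs, vocab4, groups=groups)
    assert set(rep.per_function) == set(vocab4)
    for vals in rep.per_function.values():
        assert set(vals) == {"auc", "mcc", "f1", "precision", "recall"}
    assert set(rep.per_group) == {"many", "medium", "few"}
    assert rep.acc_example == pytest.approx(
        jaccard_oracle(Y, (probs > 0.5).astype(int)))
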