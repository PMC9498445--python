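import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import mintruls as mt


class TestRocAuc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.9, 0.1], [1, 0], 1.0),
        ([0.5, 0.5], [1, 0], 0.5),                      # tie convention
        ([0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0], 0.75),     # 3 of 4 pairs won
    ])
    def test_examples(self, scores, labels, expected):
        assert mt.roc_auc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mt.roc_auc([0.1, 0.2], [1, 1])

    def test_agrees_with_sklearn(self, rng):
        s = rng.normal(size=200)
        y = rng.integers(0, 2, size=200)
        assert mt.roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.normal(size=100)
        y = rng.integers(0, 2, size=100)
        assert mt.roc_auc(np.exp(2 * s) + 3, y) == pytest.approx(
            mt.roc_auc(s, y), abs=1e-12)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        m = mt.confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert m == (1.0, 1.0, 1.0, 1.0)

    def test_all_predicted_positive(self):
        m = mt.confusion_metrics([0.9, 0.8, 0.7, 0.6], [1, 1, 0, 0], 0.0)
        assert m.sensitivity == 1.0 and m.specificity == 0.0 and m.mcc == 0.0

    def test_hand_computed_table(self):
        # TP=3 FP=1 TN=4 FN=2
        scores = [1, 1, 1, 1] + [0, 0, 0, 0, 0, 0]
        labels = [1, 1, 1, 0] + [0, 0, 0, 0, 1, 1]
        m = mt.confusion_metrics(scores, labels, threshold=0.5)
        assert m.accuracy == pytest.approx(0.7)
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)
        assert m.mcc == pytest.approx(10 / np.sqrt(4 * 5 * 5 * 6), abs=1e-9)


class TestChooseThreshold:
    def test_separable_pair(self):
        assert mt.choose_threshold([0.9, 0.1], [1, 0]) == 0.9

    def test_identical_scores_return_max(self):
        assert mt.choose_threshold([0.3, 0.3, 0.3], [1, 0, 1]) == 0.3

    def test_matches_exhaustive_sweep(self, rng):
        def sweep(s, y):
            s, y = np.asarray(s), np.asarray(y)
            best_t, best_j = None, -np.inf
            for t in np.unique(s):
                sens = ((s >= t) & (y == 1)).sum() / (y == 1).sum()
                spec = ((s < t) & (y == 0)).sum() / (y == 0).sum()
                if sens + spec - 1 >= best_j:
                    best_j, best_t = sens + spec - 1, t
            return best_t

        s6 = [0.1, 0.4, 0.35, 0.8, 0.65, 0.9]
        y6 = [0, 0, 1, 1, 0, 1]
        assert mt.choose_threshold(s6, y6) == sweep(s6, y6)
        for _ in range(20):
            s = rng.choice([0.1, 0.2, 0.5, 0.7, 0.9], size=12)
            y = rng.integers(0, 2, size=12)
            if len(np.unique(y)) == 2:
                assert mt.choose_threshold(s, y) == sweep(s, y)


class TestNormalizeScores:
    def test_affine_endpoints(self):
        out = mt.normalize_scores(np.array([[2.0, 4.0, 6.0]]))
        assert out.tolist() == [[0.0, 0.5, 1.0]]

    def test_hand_evaluated_row(self):
        out = mt.normalize_scores(np.array([[-1.0, 0.0, 3.0]]))
        assert out.tolist() == [[0.0, 0.25, 1.0]]

    def test_row_min_always_zero(self, rng):
        X = rng.normal(size=(8, 10))
        out = mt.normalize_scores(X)
        assert np.allclose(out.min(axis=1), 0.0)
        assert np.allclose(out.max(axis=1), 1.0)

    def test_constant_row_warns_half(self):
        with pytest.warns(UserWarning, match="constant"):
            out = mt.normalize_scores(np.array([[1.0, 1.0], [0.0, 2.0]]))
        assert out[0].tolist() == [0.5, 0.5]
        assert out[1].tolist() == [0.0, 1.0]


class TestQuantileClassify:
    def test_uniform_integers_match_enumeration_oracle(self):
        scores = np.arange(1, 101, dtype=float)
        q25, q75 = np.percentile(scores, [25, 75])  # 25.75, 75.25
        expected = np.where(scores < q25, "Weak",
                            np.where(scores > q75, "Strong", "Moderate"))
        got = mt.quantile_classify(scores)
        assert (got == expected).all()
        counts = pd.Series(got).value_counts()
        assert counts["Weak"] == 25 and counts["Moderate"] == 50 \
            and counts["Strong"] == 25

    def test_all_equal_all_moderate(self):
        assert set(mt.quantile_classify([2.0] * 6)) == {"Moderate"}

    def test_max_is_strong_when_above_q75(self, rng):
        s = rng.normal(size=50)
        got = mt.quantile_classify(s)
        if np.percentile(s, 75) < s.max():
            assert got[np.argmax(s)] == "Strong"

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            mt.quantile_classify([1.0, 2.0, 3.0])

    def test_invariant_under_positive_affine_rescaling(self, rng):
        X = rng.normal(size=(6, 9))
        scale = rng.uniform(0.5, 3.0, size=(6, 1))
        shift = rng.normal(size=(6, 1))
        a = mt.quantile_classify(mt.normalize_scores(X).ravel())
        b = mt.quantile_classify(mt.normalize_scores(X * scale + shift).ravel())
        assert (a == b).all()


class TestLoocv:
    def test_masked_positive_equals_never_labeled(self, small_dataset):
        """Leakage guard: identical training information, identical score."""
        cfg = mt.Config(max_positives=1, neg_per_pos=2, seed=5)
        rep = mt.loocv(small_dataset, cfg)
        pos_row = rep.records[rep.records.label == 1].iloc[0]
        i = [r.id for r in small_dataset.mirnas].index(pos_row.mirna_id)
        j = [r.id for r in small_dataset.sites].index(pos_row.site_id)
        A2 = small_dataset.interactions.A.copy()
        A2[i, j] = 0  # the same pair, never labeled
        ds2 = mt.Dataset(small_dataset.mirnas, small_dataset.sites,
                         mt.InteractionMatrix(
                             list(small_dataset.interactions.mirna_ids),
                             list(small_dataset.interactions.site_ids), A2))
        from mintruls.evaluation import _predict_full
        from mintruls.pipeline import build_static_kernels, prepare_dataset
        ds2p = prepare_dataset(ds2, cfg)
        static = build_static_kernels(ds2p, cfg)
        F = _predict_full(static, ds2p.interactions.A.astype(float), cfg)
        assert F[i, j] == pos_row.score  # bitwise

    def test_single_positive_masking_identity(self):
        # 3x3 dataset with one positive: masking it leaves an all-zero
        # training matrix, so the score equals the never-labeled score (0)
        rng = np.random.default_rng(3)
        mk = lambda n, p: ["".join(rng.choice(list("ACGU"), size=20))
                           for _ in range(n)]
        mirnas = [mt.SequenceRecord(f"m{i}", mt.Role.MIRNA, s)
                  for i, s in enumerate(mk(3, None))]
        sites = [mt.SequenceRecord(f"t{i}", mt.Role.TARGET_SITE, s)
                 for i, s in enumerate(mk(3, None))]
        A = np.zeros((3, 3), dtype=np.int8)
        A[1, 2] = 1
        ds = mt.Dataset(mirnas, sites,
                        mt.InteractionMatrix([m.id for m in mirnas],
                                             [t.id for t in sites], A))
        with pytest.raises(ValueError, match="at least 2"):
            mt.loocv(ds, mt.Config())

    def test_deterministic_under_seed(self, small_dataset):
        cfg = mt.Config(max_positives=5, neg_per_pos=3, seed=11)
        a = mt.loocv(small_dataset, cfg)
        b = mt.loocv(small_dataset, cfg)
        assert a.metrics == b.metrics
        assert a.records.equals(b.records)

    def test_no_positives_rejected(self, small_dataset):
        empty = mt.InteractionMatrix(
            list(small_dataset.interactions.mirna_ids),
            list(small_dataset.interactions.site_ids),
            np.zeros_like(small_dataset.interactions.A))
        ds = mt.Dataset(small_dataset.mirnas, small_dataset.sites, empty)
        with pytest.raises(ValueError):
            mt.loocv(ds, mt.Config())

    def test_report_contents(self, small_dataset):
        cfg = mt.Config(max_positives=4, neg_per_pos=2, seed=2)
        rep = mt.loocv(small_dataset, cfg)
        assert set(rep.records.klass) <= {"Weak", "Moderate", "Strong"}
        assert ((0 <= rep.records.normalized)
                & (rep.records.normalized <= 1)).all()
        assert 0 <= rep.metrics["auc"] <= 1
        assert -1 <= rep.metrics["mcc"] <= 1


class TestLmitocv:
    def test_ceiling_rule_on_holdout_count(self, small_dataset):
        rep = mt.lmitocv(small_dataset, mt.Config(seed=0), fraction=0.5,
                         iterations=1)
        n_t = len(small_dataset.sites)
        held_sites = rep.records.site_id.nunique()
        assert held_sites == int(np.ceil(0.5 * n_t))

    def test_deterministic_under_seed(self, small_dataset):
        a = mt.lmitocv(small_dataset, mt.Config(), seed=9, iterations=2)
        b = mt.lmitocv(small_dataset, mt.Config(), seed=9, iterations=2)
        assert a.metrics == b.metrics
        assert a.records.equals(b.records)

    def test_different_seeds_differ(self, small_dataset):
        a = mt.lmitocv(small_dataset, mt.Config(), seed=1, iterations=1)
        b = mt.lmitocv(small_dataset, mt.Config(), seed=2, iterations=1)
        assert not a.records.equals(b.records)

    def test_tiny_fraction_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            mt.lmitocv(small_dataset, mt.Config(), fraction=0.01, iterations=1)

    def test_per_iteration_metrics_present(self, small_dataset):
        rep = mt.lmitocv(small_dataset, mt.Config(), seed=4, iterations=3)
        assert len(rep.per_iteration) <= 3
        assert "mean_iteration_auc" in rep.metrics
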