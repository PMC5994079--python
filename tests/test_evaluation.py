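import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from drimpute import (
    ClusterAssignment,
    ClusteringConfig,
    ExpressionMatrix,
    adjusted_rand_index,
    classify_zeros,
    cross_ari,
    discrimination_scores,
    downsample_counts,
    ensemble_impute,
    imputation_concordance,
    kendall_tau,
)
from drimpute.evaluation import PRF1, gene_mean_impute


def pair_counting_ari(a, b):
    """Independent oracle: ARI from direct pair agreement counts."""
    n = len(a)
    ss = sd = ds = dd = 0  # same/different in a × same/different in b
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            if sa and sb:
                ss += 1
            elif sa:
                sd += 1
            elif sb:
                ds += 1
            else:
                dd += 1
    num = 2 * (ss * dd - sd * ds)
    den = (ss + sd) * (sd + dd) + (ss + ds) * (ds + dd)
    return 1.0 if den == 0 else num / den


def expr(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        tuple(f"g{i}" for i in range(values.shape[0])),
        tuple(f"c{j}" for j in range(values.shape[1])),
    )


class TestDownsample:
    def test_rate_one_is_identity(self, small_counts):
        assert downsample_counts(small_counts, 1.0, seed=0) == small_counts

    def test_zeros_stay_zero_and_counts_shrink(self, small_counts):
        thinned = downsample_counts(small_counts, 0.4, seed=1)
        full = small_counts.to_dense()
        down = thinned.to_dense()
        assert (down <= full).all()
        assert (down[full == 0] == 0).all()

    def test_deterministic_given_seed(self, small_counts):
        a = downsample_counts(small_counts, 0.3, seed=7)
        b = downsample_counts(small_counts, 0.3, seed=7)
        assert a == b

    @pytest.mark.parametrize("rate", [0.0, -0.1, 1.5])
    def test_invalid_rate_rejected(self, small_counts, rate):
        with pytest.raises(ValueError):
            downsample_counts(small_counts, rate, seed=0)

    def test_total_within_binomial_bound(self, default_dataset):
        """Thinned totals stay within 3 SE of the binomial expectation."""
        m = default_dataset.observed_counts
        total = m.values.sum()
        rate = 0.25
        se = np.sqrt(total * rate * (1 - rate))
        for seed in range(5):
            t = downsample_counts(m, rate, seed).values.sum()
            assert abs(t - rate * total) <= 3 * se


class TestClassifyZeros:
    def setup_method(self):
        # 2 clusters: cells 0,1 vs 2,3
        self.full = expr([[1.0, 2.0, 0.0, 0.0],   # zero across cluster B
                          [1.0, 0.0, 1.0, 1.0],   # expressed in both clusters
                          [0.0, 0.0, 3.0, 0.0]])  # zero across cluster A
        self.down = expr([[0.0, 2.0, 0.0, 0.0],
                          [1.0, 0.0, 1.0, 0.0],
                          [0.0, 0.0, 0.0, 0.0]])
        self.labels = [0, 0, 1, 1]

    def test_three_way_labeling(self):
        zl = classify_zeros(self.full, self.down, self.labels)
        assert zl.entries[(0, 0)] == "dropout_zero"   # positive in full
        assert zl.entries[(0, 2)] == "true_zero"      # gene 0 zero across B
        assert zl.entries[(1, 1)] == "unlabeled"      # cluster mate positive
        assert zl.entries[(2, 0)] == "true_zero"      # gene 2 zero across A
        assert zl.entries[(2, 2)] == "dropout_zero"
        assert zl.entries[(2, 3)] == "unlabeled"

    def test_keys_are_exactly_down_zeros(self):
        zl = classify_zeros(self.full, self.down, self.labels)
        assert set(zl.entries) == set(zip(*np.nonzero(self.down.X == 0)))

    def test_id_mismatch_rejected(self):
        other = ExpressionMatrix(self.down.X, self.down.gene_ids,
                                 ("x1", "x2", "x3", "x4"))
        with pytest.raises(Exception, match="share"):
            classify_zeros(self.full, other, self.labels)


class TestDiscriminationScores:
    def test_perfect_discrimination(self):
        full = expr([[2.0, 2.0, 0.0, 0.0]])
        down = expr([[0.0, 2.0, 0.0, 0.0]])
        zl = classify_zeros(full, down, [0, 0, 1, 1])
        imputed = np.array([[1.0, 2.0, 0.0, 0.0]])
        prf = discrimination_scores(imputed, zl)
        assert (prf.tp, prf.tn, prf.fp, prf.fn) == (1, 2, 0, 0)
        assert prf.f1 == 1.0

    def test_nothing_imputed_scores_zero(self):
        full = expr([[2.0, 2.0, 0.0, 0.0]])
        down = expr([[0.0, 2.0, 0.0, 0.0]])
        zl = classify_zeros(full, down, [0, 0, 1, 1])
        prf = discrimination_scores(down.X, zl)
        assert prf.recall == 0.0 and prf.f1 == 0.0

    def test_formula_arithmetic(self):
        prf = PRF1(tp=2, tn=0, fp=1, fn=1)
        assert prf.precision == pytest.approx(2 / 3)
        assert prf.recall == pytest.approx(2 / 3)
        assert prf.f1 == pytest.approx(2 / 3)

    def test_unlabeled_entries_ignored(self):
        full = expr([[2.0, 2.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])
        down = expr([[0.0, 2.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])
        zl = classify_zeros(full, down, [0, 0, 1, 1])
        base = discrimination_scores(down.X, zl)
        # imputing only unlabeled entries must not change any tally
        imputed = down.X.copy()
        imputed[zl.unlabeled] = 9.0
        after = discrimination_scores(imputed, zl)
        assert (base.tp, base.tn, base.fp, base.fn) == (
            after.tp, after.tn, after.fp, after.fn
        )


class TestAdjustedRandIndex:
    def test_identical_and_relabeled(self):
        assert adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert adjusted_rand_index([0, 0, 1, 1], [5, 5, 2, 2]) == 1.0

    def test_worked_instance(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_single_cluster_convention(self):
        assert adjusted_rand_index([0, 0, 0], [1, 1, 1]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([0, 1], [0, 1, 2])

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(st.integers(0, 3), min_size=2, max_size=8),
        st.data(),
    )
    def test_matches_pair_counting_and_sklearn(self, a, data):
        b = data.draw(
            st.lists(st.integers(0, 3), min_size=len(a), max_size=len(a))
        )
        ours = adjusted_rand_index(a, b)
        assert ours == pytest.approx(pair_counting_ari(a, b), abs=1e-12)
        if len(set(a)) > 1 or len(set(b)) > 1:
            assert ours == pytest.approx(adjusted_rand_score(a, b), abs=1e-12)


class TestCrossAri:
    def test_many_identical_runs(self):
        labelings = [np.array([0, 0, 1, 1, 2, 2])] * 100
        assert cross_ari(labelings) == 1.0  # 100·99/2 pairs, all perfect

    def test_partial_ari_on_overlap(self):
        a = (["c1", "c2", "c3", "c4"], [0, 0, 1, 1])
        b = (["c1", "c2", "c5", "c6"], [0, 0, 7, 8])
        # only c1, c2 overlap and agree there
        assert cross_ari([a, b]) == 1.0

    def test_null_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 5, size=1000)
        b = rng.integers(0, 5, size=1000)
        assert abs(cross_ari([a, b])) < 0.05

    def test_too_few_labelings_rejected(self):
        with pytest.raises(ValueError):
            cross_ari([np.array([0, 1])])


class TestKendallTau:
    def test_concordant_reversed_and_ties(self):
        assert kendall_tau([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert kendall_tau([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)
        # 6 pairs, 4 concordant, tie corrections tx=0? ty=2 → 4/sqrt(6·4)
        assert kendall_tau([1, 2, 3, 4], [1, 1, 2, 2]) == pytest.approx(
            4 / np.sqrt(24)
        )

    def test_constant_vector_returns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert kendall_tau([1, 1, 1], [1, 2, 3]) == 0.0
        assert "constant" in caplog.text


class TestImputationConcordance:
    def _result(self, X, labels):
        a = ClusterAssignment(
            np.asarray(labels), ClusteringConfig("pearson", 2, 0)
        )
        return ensemble_impute(np.asarray(X, float), [a])

    def test_identical_results(self):
        X = [[0.0, 1.0, 2.0], [3.0, 0.0, 1.0]]
        r = self._result(X, [0, 0, 1])
        assert imputation_concordance(r, r) == 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        X = np.where(rng.random((10, 8)) < 0.4, 0.0, rng.random((10, 8)))
        r1 = self._result(X, rng.integers(0, 2, 8))
        shifted = r1.X_imputed * 2.0 + 1.0
        r2 = type(r1)(shifted, r1.zero_mask, r1.configs)
        assert imputation_concordance(r1, r2) == pytest.approx(1.0)

    def test_mask_mismatch_rejected(self):
        r1 = self._result([[0.0, 1.0], [1.0, 1.0]], [0, 1])
        r2 = self._result([[1.0, 0.0], [1.0, 1.0]], [0, 1])
        with pytest.raises(ValueError):
            imputation_concordance(r1, r2)


def test_gene_mean_baseline_fills_zeros():
    X = np.array([[0.0, 2.0, 4.0], [0.0, 0.0, 0.0]])
    out = gene_mean_impute(X)
    assert out[0, 0] == pytest.approx(2.0)
    assert (out[1] == 0).all()
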