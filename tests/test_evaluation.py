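"""Splitting, balancing, AUC/Youden kernels, the repeated-split driver and
the paired sign-flip permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cogscreen as cs
from cogscreen.evaluation import EvalConfig, feature_matrix


def brute_force_auc(scores, labels):
    """O(n^2) pairwise-comparison oracle, ties half-credited."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Exhaustive cutpoint enumeration oracle; lowest threshold on ties.

    J is compared via the exact integer quantity tp*n_neg - fp*n_pos."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    best = (-np.inf, None)
    for t in np.unique(s):
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        j_scaled = tp * n_neg - fp * n_pos
        if j_scaled > best[0]:
            best = (j_scaled, t)
    return best[0] / (n_pos * n_neg), best[1]


class TestStratifiedSplit:
    def test_per_class_arithmetic(self):
        y = np.array([0] * 60 + [1] * 40)
        train, test = cs.stratified_split(y, 0.7, seed=3)
        assert (y[train] == 0).sum() == 42
        assert (y[train] == 1).sum() == 28

    def test_disjoint_exhaustive_partition(self):
        y = np.random.default_rng(0).integers(0, 2, 137)
        train, test = cs.stratified_split(y, 0.7, seed=1)
        assert set(train) | set(test) == set(range(137))
        assert set(train) & set(test) == set()

    def test_seeded_determinism(self):
        y = np.array([0, 1] * 30)
        a = cs.stratified_split(y, 0.7, seed=9)
        b = cs.stratified_split(y, 0.7, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            cs.stratified_split(np.array([0, 0, 0, 1]), 0.7, seed=0)


class TestUpsample:
    def test_minority_matched_to_majority(self):
        y = np.array(["A"] * 30 + ["B"] * 70)
        pos = cs.upsample_to_balance(y, seed=2)
        vals, counts = np.unique(y[pos], return_counts=True)
        assert dict(zip(vals, counts)) == {"A": 70, "B": 70}

    def test_already_balanced_identity(self):
        y = np.array([0] * 25 + [1] * 25)
        pos = cs.upsample_to_balance(y, seed=4)
        assert sorted(pos) == list(range(50))

    def test_superset_and_closure(self):
        """Every original record is kept; every added position points at an
        existing minority record (1000 randomized cases)."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = rng.integers(4, 60)
            y = rng.integers(0, rng.integers(2, 4), n)
            if len(np.unique(y)) < 2:
                continue
            pos = cs.upsample_to_balance(y, seed=int(rng.integers(2**31)))
            assert set(range(n)) <= set(pos)  # originals kept
            assert set(pos) <= set(range(n))  # closure
            _, counts = np.unique(y[pos], return_counts=True)
            assert len(set(counts)) == 1  # balanced


class TestRocAuc:
    def test_perfect_ordering(self):
        assert cs.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert cs.roc_auc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            cs.roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle_and_sklearn(self):
        """200 random instances (n <= 50, heavy ties) against the O(n^2)
        pair-counting oracle to 1e-12 and sklearn as a second opinion."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            scores = rng.choice(np.round(rng.normal(size=8), 2), size=n)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            got = cs.roc_auc(scores, labels)
            assert got == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestYouden:
    def test_perfect_separation(self):
        t, m = cs.youden_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert m.sensitivity == m.specificity == 1.0
        assert m.balanced_accuracy == 1.0
        assert t == 0.8

    def test_degenerate_all_ties(self):
        t, m = cs.youden_threshold([0.3] * 8, [0, 1] * 4)
        assert m.sensitivity + m.specificity - 1 == 0.0

    def test_matches_exhaustive_oracle(self):
        """100 random instances against full cutpoint enumeration."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(6, 60))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            t, m = cs.youden_threshold(scores, labels)
            j_oracle, t_oracle = brute_force_youden(scores, labels)
            j_got = m.sensitivity + m.specificity - 1
            assert j_got == pytest.approx(j_oracle, abs=1e-12)
            assert t == t_oracle  # lowest-threshold tie-break
            assert m.balanced_accuracy == pytest.approx((j_got + 1) / 2, abs=1e-12)


class TestFitClassifier:
    def _toy(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X = np.column_stack([y * 4.0 + rng.normal(size=n) * 0.2,
                             rng.normal(size=n)])
        return X, y

    def test_separable_training_auc(self):
        X, y = self._toy()
        model = cs.fit_classifier(X, y, EvalConfig(tree_chunk=50, n_trees_max=100))
        assert cs.roc_auc(model.score(X), y) == 1.0

    def test_seeded_determinism(self):
        X, y = self._toy()
        cfg = EvalConfig(tree_chunk=50, n_trees_max=100)
        a = cs.fit_classifier(X, y, cfg, seed=5).score(X)
        b = cs.fit_classifier(X, y, cfg, seed=5).score(X)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        X, _ = self._toy()
        with pytest.raises(ValueError, match="single class"):
            cs.fit_classifier(X, np.ones(len(X)), EvalConfig())

    def test_permuted_labels_give_chance_auc(self):
        """With labels shuffled, held-out AUC stays near 0.5 across 50
        seeds (null-distribution simulation)."""
        X, y = self._toy(n=120)
        cfg = EvalConfig(tree_chunk=50, n_trees_max=100)
        aucs = []
        rng = np.random.default_rng(21)
        for seed in range(50):
            yp = rng.permutation(y)
            tr, te = cs.stratified_split(yp, 0.5, seed=seed)
            model = cs.fit_classifier(X[tr], yp[tr], cfg, seed=seed)
            aucs.append(cs.roc_auc(model.score(X[te]), yp[te]))
        assert 0.35 <= float(np.mean(aucs)) <= 0.65

    def test_tuning_respects_tree_cap(self):
        X, y = self._toy(n=80)
        model = cs.fit_classifier(X, y, EvalConfig(tree_chunk=40, n_trees_max=80))
        assert model.n_trees_ <= 80


class _RecordingStub:
    """Deterministic pluggable classifier: scores by the first feature and
    records the training labels it saw (for pairing checks)."""

    calls: list = []

    def __init__(self, X, y, seed):
        type(self).calls.append((np.asarray(y).copy(), seed))
        self._dummy = None

    def score(self, X):
        x = np.asarray(X, dtype=float)[:, 0]
        rng = x.max() - x.min()
        return (x - x.min()) / rng if rng else np.full(len(x), 0.5)


class TestEvaluateFeatureSets:
    def test_single_iteration_shape(self, analyzable):
        cfg = EvalConfig(n_iterations=1, seed=0)
        res = cs.evaluate_feature_sets(
            analyzable, analyzable["impairment"], cfg,
            classifier_factory=_RecordingStub,
        )
        for name in cfg.feature_sets:
            assert len(res.per_iteration[name]) == 1

    def test_pairing_integrity(self, analyzable):
        """All feature sets see the identical balanced training labels and
        the identical seed within an iteration (paired design)."""
        _RecordingStub.calls = []
        cfg = EvalConfig(n_iterations=3, seed=4)
        cs.evaluate_feature_sets(
            analyzable, analyzable["impairment"], cfg,
            classifier_factory=_RecordingStub,
        )
        k = len(cfg.feature_sets)
        assert len(_RecordingStub.calls) == 3 * k
        for it in range(3):
            group = _RecordingStub.calls[it * k:(it + 1) * k]
            ref_y, ref_seed = group[0]
            for y, seed in group[1:]:
                assert np.array_equal(y, ref_y)
                assert seed == ref_seed

    def test_summary_recomputable_from_iterations(self, analyzable):
        cfg = EvalConfig(n_iterations=5, seed=8)
        res = cs.evaluate_feature_sets(
            analyzable, analyzable["impairment"], cfg,
            classifier_factory=_RecordingStub,
        )
        s = res.summary()
        for name in cfg.feature_sets:
            aucs = res.aucs(name)
            assert s.loc[name, "auc_median"] == pytest.approx(np.median(aucs))
            assert s.loc[name, "auc_sd"] == pytest.approx(np.std(aucs, ddof=1))

    def test_feature_matrix_contents(self, analyzable):
        dcr = feature_matrix(analyzable, "dcr_features")
        assert list(dcr.columns)[-1] == "delayed_recall"
        assert dcr.shape[1] == 23  # 22 subscores + recall
        assert list(feature_matrix(analyzable, "mmse_total").columns) == ["mmse"]
        assert feature_matrix(analyzable, "demographics").shape[1] == 3
        assert feature_matrix(analyzable, "all").shape[1] == 27
        with pytest.raises(KeyError):
            feature_matrix(analyzable, "nope")


class TestPairedPermutation:
    def test_identical_vectors(self):
        a = np.linspace(0.6, 0.8, 20)
        res = cs.paired_permutation_median_diff(a, a, 500, seed=0)
        assert res.observed_median_diff == 0.0
        assert res.p_value == 1.0

    def test_p_floor_invariant(self):
        rng = np.random.default_rng(3)
        b = rng.uniform(0.5, 0.6, 100)
        res = cs.paired_permutation_median_diff(b + rng.uniform(0.2, 0.3, 100),
                                                b, 999, seed=1)
        assert res.p_value >= 1.0 / (999 + 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cs.paired_permutation_median_diff([1.0, 2.0], [1.0], 10, 0)

    @pytest.mark.parametrize("kind", ["random", "constant"])
    def test_matches_exhaustive_enumeration_at_length_10(self, kind):
        """MC p agrees with the full 2^10 sign-flip enumeration, including
        the degenerate constant-difference case where flips preserve the
        median's magnitude."""
        rng = np.random.default_rng(17)
        if kind == "random":
            d = rng.normal(0.05, 0.05, 10)
        else:
            d = np.full(10, 0.1)
        obs = np.median(d)
        count = 0
        for signs in itertools.product([-1.0, 1.0], repeat=10):
            if abs(np.median(d * np.array(signs))) >= abs(obs):
                count += 1
        p_exact = count / 2**10
        res = cs.paired_permutation_median_diff(d, np.zeros(10), 20000, seed=2)
        mc_se = np.sqrt(p_exact * (1 - p_exact) / 20000)
        assert res.p_value == pytest.approx(p_exact, abs=max(4 * mc_se, 2e-4))

    def test_null_p_values_uniform(self):
        """Under exchangeable a/b the permutation p-values over 200
        replicate runs are approximately uniform (KS at alpha=0.01)."""
        rng = np.random.default_rng(23)
        pvals = []
        for r in range(200):
            a = rng.normal(0.7, 0.03, 30)
            b = rng.normal(0.7, 0.03, 30)
            pvals.append(
                cs.paired_permutation_median_diff(a, b, 400, seed=r).p_value
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
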