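"""Confusion-matrix metrics, protocols, and paired statistics."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from eegstage.evaluate import (
    ClassCounts,
    LeakageError,
    UndefinedMetricError,
    confusion,
    kfold_split,
    macro_metrics,
    metrics,
    paired_ttest,
    per_class_counts,
    pooled_accuracy,
    roc_auc,
    run_kfold,
    run_loocv,
    summarize_folds,
    wilcoxon_exact,
)
from eegstage.montage import LABELS


def brute_force_wilcoxon(a, b):
    """Exhaustive 2**n enumeration of the signed-rank null."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    r = stats.rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    ws = np.array([
        sum(ri for ri, s in zip(r, signs) if s)
        for signs in itertools.product([False, True], repeat=d.size)
    ])
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        y = np.repeat(LABELS, 10)
        assert np.array_equal(confusion(y, y), np.diag([10, 10, 10]))

    def test_empty_input_gives_zero_matrix(self):
        assert confusion([], []).sum() == 0

    def test_random_pair_matches_bruteforce_tally(self):
        rng = np.random.default_rng(0)
        a = rng.choice(LABELS, 100)
        p = rng.choice(LABELS, 100)
        cm = confusion(a, p)
        for i, la in enumerate(LABELS):
            for j, lp in enumerate(LABELS):
                assert cm[i, j] == sum((a == la) & (p == lp))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion(["HS"], ["XY"])


class TestPerClassCounts:
    def test_worked_cell_map(self):
        cm = np.array([[8, 1, 1], [2, 6, 2], [0, 1, 9]])
        c = per_class_counts(cm, "MCI")
        assert (c.tp, c.fn, c.fp, c.tn) == (6, 4, 2, 18)

    def test_diagonal_matrix_has_no_errors(self):
        cm = np.diag([5, 7, 3])
        for label in LABELS:
            c = per_class_counts(cm, label)
            assert c.fp == 0 and c.fn == 0

    def test_partition_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            cm = rng.integers(0, 30, (3, 3))
            for label in LABELS:
                assert per_class_counts(cm, label).total == cm.sum()


class TestMetrics:
    def test_direct_substitution(self):
        m = metrics(ClassCounts(tp=6, tn=18, fp=2, fn=4))
        assert (m.acc, m.sen, m.spe, m.fpr) == (80.0, 60.0, 90.0, 10.0)

    def test_perfect_counts(self):
        m = metrics(ClassCounts(tp=10, tn=20, fp=0, fn=0))
        assert (m.acc, m.sen, m.spe, m.fpr) == (100.0, 100.0, 100.0, 0.0)

    def test_spe_plus_fpr_identity_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 500, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = metrics(ClassCounts(int(tp), int(tn), int(fp), int(fn)))
            assert m.spe + m.fpr == 100.0

    def test_empty_denominator_is_named(self):
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            metrics(ClassCounts(tp=0, tn=5, fp=5, fn=0))
        with pytest.raises(UndefinedMetricError, match="specificity"):
            metrics(ClassCounts(tp=5, tn=0, fp=0, fn=5))

    def test_macro_average_is_mean_of_per_class(self):
        cm = np.array([[8, 1, 1], [2, 6, 2], [0, 1, 9]])
        per_class, acc, sen, spe = macro_metrics(cm)
        assert acc == pytest.approx(np.mean([m.acc for m in per_class.values()]), abs=1e-9)
        assert set(per_class) == set(LABELS)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([[0.9, 0.05, 0.05]] * 5 + [[0.1, 0.7, 0.2]] * 5)
        actual = ["HS"] * 5 + ["MCI"] * 5
        auc, curve = roc_auc(scores, actual, "HS")
        assert auc == 1.0
        assert curve.shape[1] == 2

    def test_matches_mann_whitney_statistic(self):
        rng = np.random.default_rng(3)
        scores = rng.random((60, 3))
        actual = rng.choice(LABELS, 60)
        for target in LABELS:
            pos = actual == target
            auc, _ = roc_auc(scores, actual, target)
            u = stats.mannwhitneyu(
                scores[pos, LABELS.index(target)],
                scores[~pos, LABELS.index(target)],
            ).statistic
            assert auc == pytest.approx(u / (pos.sum() * (~pos).sum()), abs=1e-12)

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.random((2000, 3))
        actual = rng.choice(LABELS, 2000)
        auc, _ = roc_auc(scores, actual, "AD")
        assert abs(auc - 0.5) <= 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.random.rand(4, 3), ["HS"] * 4, "HS")


class TestKfoldSplit:
    def test_partition_properties(self):
        folds = kfold_split(100, k=10, seed=0)
        assert [len(f) for f in folds] == [10] * 10
        flat = np.concatenate(folds)
        assert sorted(flat) == list(range(100))

    def test_seed_reproducibility(self):
        a = kfold_split(57, k=10, seed=42)
        b = kfold_split(57, k=10, seed=42)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(5, k=10)

    def test_unstratified_fold_composition_is_hypergeometric(self):
        """Class counts per fold fluctuate as sampling without replacement
        predicts — i.e. the split is shuffled but NOT stratified."""
        n, k, n_class0 = 100, 10, 40
        is0 = np.zeros(n, bool)
        is0[:n_class0] = True
        counts = []
        for seed in range(200):
            for fold in kfold_split(n, k=k, seed=seed):
                counts.append(is0[fold].sum())
        counts = np.asarray(counts)
        m = n // k
        expected_var = m * (n_class0 / n) * (1 - n_class0 / n) * (n - m) / (n - 1)
        assert counts.mean() == pytest.approx(m * n_class0 / n, abs=0.05)
        assert counts.var() == pytest.approx(expected_var, rel=0.15)
        # a stratified split would put exactly 4 in every fold
        assert counts.var() > 0.5


def majority_fit_predict(xtr, ytr, xte):
    """Memorizing dummy: always predicts the training majority class."""
    winner = np.bincount(ytr.astype(int) if ytr.dtype.kind in "iu"
                         else [LABELS.index(v) for v in ytr], minlength=3).argmax()
    proba = np.zeros((len(xte), 3))
    proba[:, winner] = 1.0
    return proba


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(0)
    n = 300
    y = np.array(["HS"] * 180 + ["MCI"] * 75 + ["AD"] * 45)
    X = rng.random((n, 4, 4))
    return X, y


class TestRunKfold:

    def test_each_sample_tested_once_and_majority_accuracy(self, toy):
        X, y = toy
        reports, summary = run_kfold(X, y, majority_fit_predict, k=10, seed=3)
        assert len(reports) == 10
        total = np.sum([r.cm for r in reports], axis=0)
        assert total.sum() == len(y)
        # the dummy always answers the global majority (HS)
        assert pooled_accuracy(reports) == pytest.approx(100 * 180 / 300, abs=1e-9)
        for r in reports:
            assert r.per_class["HS"].sen == 100.0
            for other in ("MCI", "AD"):
                if other in r.per_class:
                    assert r.per_class[other].sen == 0.0

    def test_summary_mean_equals_fold_mean(self, toy):
        X, y = toy
        reports, summary = run_kfold(X, y, majority_fit_predict, k=10, seed=3)
        assert summary["acc"]["mean"] == pytest.approx(
            np.mean([r.acc for r in reports]), abs=1e-9)

    def test_duplicate_sample_ids_raise_leakage_error(self, toy):
        X, y = toy
        ids = np.zeros(len(y), dtype=int)  # every sample shares one id
        with pytest.raises(LeakageError):
            run_kfold(X, y, majority_fit_predict, k=10, seed=0, sample_ids=ids)


@pytest.fixture(scope="module")
def toy_subjects():
    rng = np.random.default_rng(1)
    images, labels, subjects = [], [], []
    for c, label in enumerate(LABELS):
        for s in range(3):
            sid = f"{label}{s}"
            for _ in range(4):  # 4 segments per subject
                img = rng.random((6, 5)) + 2.0 * c
                images.append(img)
                labels.append(label)
                subjects.append(sid)
    return np.stack(images), np.array(labels), np.array(subjects)


class TestRunLoocv:

    @staticmethod
    def mean_level_fit_predict(xtr, ytr, xte):
        """Classify by nearest class-mean intensity — enough for the toy set."""
        levels = [xtr[ytr == c].mean() if (ytr == c).any() else np.inf
                  for c in range(3)]
        proba = np.zeros((len(xte), 3))
        for i, x in enumerate(xte):
            proba[i, int(np.argmin([abs(x.mean() - l) for l in levels]))] = 1.0
        return proba

    def test_nine_subjects_nine_iterations_no_overlap(self, toy_subjects):
        X, y, subjects = toy_subjects
        seen_train_ids = []

        def spy(xtr, ytr, xte):
            seen_train_ids.append(len(xtr))
            return self.mean_level_fit_predict(xtr, ytr, xte)

        scores = run_loocv(X, y, subjects, spy)
        assert len(scores) == 9
        assert all(n == len(y) - 4 for n in seen_train_ids)  # 4 segments held out

    def test_separable_subjects_scored_high(self, toy_subjects):
        X, y, subjects = toy_subjects
        scores = run_loocv(X, y, subjects, self.mean_level_fit_predict)
        assert np.mean(list(scores.values())) >= 90.0


class TestPairedTtest:
    def test_closed_form_n2(self):
        t, p = paired_ttest([2.0, 4.0], [1.0, 1.0])  # d = (1, 3)
        assert t == pytest.approx(2.0, abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(2.0, df=1), abs=1e-12)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=10)
            b = rng.normal(size=10)
            t, p = paired_ttest(a, b)
            ref = stats.ttest_rel(a, b)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate|variance"):
            paired_ttest([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestWilcoxonExact:
    def test_uniform_sign_n10_is_two_in_1024(self):
        a = np.arange(10.0) + 1.0
        b = a - np.linspace(0.5, 1.5, 10)
        _, p = wilcoxon_exact(a, b)
        assert p == pytest.approx(2 / 1024, abs=1e-15)

    def test_matches_exhaustive_enumeration_n6(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            _, p = wilcoxon_exact(a, b)
            assert p == pytest.approx(brute_force_wilcoxon(a, b), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            _, p = wilcoxon_exact(a, b)
            ref = stats.wilcoxon(a, b, mode="exact")
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_handles_ties_and_zeros(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.array([1.0, 1.0, 2.0, 3.0, 6.0, 4.0])  # one zero diff, ties in |d|
        _, p = wilcoxon_exact(a, b)
        assert p == pytest.approx(brute_force_wilcoxon(a, b), abs=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_exact([1.0, 2.0], [1.0, 2.0])


class TestSummarizeFolds:
    def test_constant_vector(self):
        s = summarize_folds([5.0] * 10)
        assert s["sd"] == 0.0 and s["ci95_low"] == s["ci95_high"] == 5.0

    def test_one_two_three(self):
        s = summarize_folds([1.0, 2.0, 3.0])
        assert s["mean"] == 2.0 and s["sd"] == 1.0

    def test_matches_two_pass_bruteforce(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=10)
        s = summarize_folds(v)
        mean = sum(v) / len(v)
        sd = (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5
        half = stats.t.ppf(0.975, 9) * sd / len(v) ** 0.5
        assert s["mean"] == pytest.approx(mean, rel=1e-12)
        assert s["sd"] == pytest.approx(sd, rel=1e-12)
        assert s["ci95_high"] - s["mean"] == pytest.approx(half, rel=1e-9)
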