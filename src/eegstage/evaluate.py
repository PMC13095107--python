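"""Multiclass evaluation: per-class counts and rates, ROC/AUC, shuffled
k-fold and leave-one-subject-out protocols, and paired model comparison.

Conventions
-----------
* Class order is fixed (HS, MCI, AD); confusion matrices are row = actual,
  column = predicted.
* For one target class, TP is its diagonal cell, FN its off-diagonal row
  sum, FP its off-diagonal column sum, and TN everything else; accuracy,
  sensitivity, specificity and false-positive rate are the familiar
  count ratios scaled to percent, so ``spe + fpr == 100`` identically.
* "Multiclass" metrics are unweighted macro averages over the three
  per-class values.
* The k-fold split is shuffled but deliberately NOT stratified, and the
  subject-wise protocol holds out every segment of one subject at a time;
  both assert train/test disjointness rather than assuming it.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, sqrt

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold

from .montage import LABELS

__all__ = [
    "ClassCounts",
    "ClassMetrics",
    "FoldReport",
    "confusion",
    "per_class_counts",
    "metrics",
    "macro_metrics",
    "roc_auc",
    "kfold_split",
    "pooled_accuracy",
    "run_kfold",
    "run_loocv",
    "paired_ttest",
    "wilcoxon_exact",
    "summarize_folds",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator is empty for the given counts."""


class LeakageError(AssertionError):
    """Train and test sets share sample identities."""


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest counts for a single target class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassMetrics:
    """Accuracy / sensitivity / specificity / false-positive rate, in percent."""

    acc: float
    sen: float
    spe: float
    fpr: float


@dataclass
class FoldReport:
    """Row unit of a cross-validation report table."""

    fold_index: int  # 1-based
    per_class: dict[str, ClassMetrics]
    acc: float  # macro averages over defined classes
    sen: float
    spe: float
    epochs_run: int = 0
    cm: np.ndarray | None = None  # this fold's 3x3 confusion matrix


def _encode(labels) -> np.ndarray:
    lut = {name: i for i, name in enumerate(LABELS)}
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        out = arr.astype(int)
        if out.size and (out.min() < 0 or out.max() >= len(LABELS)):
            raise ValueError("integer labels out of range")
        return out
    try:
        return np.array([lut[str(v)] for v in arr], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from None


def confusion(actual, predicted) -> np.ndarray:
    """3x3 confusion matrix; rows actual, columns predicted, order HS/MCI/AD."""
    a = _encode(actual)
    p = _encode(predicted)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    k = len(LABELS)
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (a, p), 1)
    return cm


def per_class_counts(cm: np.ndarray, target: str | int) -> ClassCounts:
    """Collapse the 3x3 matrix to one-vs-rest counts for ``target``."""
    cm = np.asarray(cm)
    t = target if isinstance(target, (int, np.integer)) else LABELS.index(target)
    tp = int(cm[t, t])
    fn = int(cm[t].sum() - cm[t, t])
    fp = int(cm[:, t].sum() - cm[t, t])
    tn = int(cm.sum() - tp - fn - fp)
    return ClassCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: ClassCounts) -> ClassMetrics:
    """Percent ACC/SEN/SPE/FPR from one-vs-rest counts.

    Raises :class:`UndefinedMetricError` when a denominator is empty,
    naming the metric; values are never silently reported as 0.
    """
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no actual positives")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity/FPR undefined: no actual negatives")
    spe = 100.0 * c.tn / (c.tn + c.fp)
    return ClassMetrics(
        acc=100.0 * (c.tp + c.tn) / c.total,
        sen=100.0 * c.tp / (c.tp + c.fn),
        spe=spe,
        # the complement form keeps spe + fpr == 100 exact in floating point
        fpr=100.0 - spe,
    )


def macro_metrics(cm: np.ndarray) -> tuple[dict[str, ClassMetrics], float, float, float]:
    """Per-class metrics plus unweighted macro ACC/SEN/SPE.

    Classes absent from the fold (empty denominator) are skipped and the
    macro average runs over the defined classes only.
    """
    per_class: dict[str, ClassMetrics] = {}
    for name in LABELS:
        try:
            per_class[name] = metrics(per_class_counts(cm, name))
        except UndefinedMetricError:
            continue
    if not per_class:
        raise UndefinedMetricError("no class has defined metrics")
    accs = [m.acc for m in per_class.values()]
    sens = [m.sen for m in per_class.values()]
    spes = [m.spe for m in per_class.values()]
    return per_class, float(np.mean(accs)), float(np.mean(sens)), float(np.mean(spes))


def roc_auc(scores: np.ndarray, actual, target: str | int):
    """One-vs-rest ROC curve and trapezoid AUC for ``target``.

    ``scores`` is the (n, 3) class-probability matrix; the target class's
    column is the decision score. Ties cross thresholds simultaneously.
    """
    a = _encode(actual)
    t = target if isinstance(target, (int, np.integer)) else LABELS.index(target)
    pos = a == t
    if pos.all() or not pos.any():
        raise ValueError("ROC needs at least one positive and one negative sample")
    fpr, tpr, _ = roc_curve(pos.astype(int), np.asarray(scores)[:, t])
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# protocols


def kfold_split(n_items: int, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Uniformly shuffled, non-stratified partition into k index sets.

    Sizes differ by at most one; no class balancing is applied.
    """
    if n_items < k:
        raise ValueError(f"cannot split {n_items} items into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.arange(n_items))]


def _check_disjoint(train_ids, test_ids) -> None:
    shared = set(train_ids) & set(test_ids)
    if shared:
        raise LeakageError(f"train/test share {len(shared)} sample id(s)")


def run_kfold(
    images: np.ndarray,
    labels,
    fit_predict,
    k: int = 10,
    seed: int = 0,
    sample_ids=None,
) -> tuple[list[FoldReport], dict]:
    """Shuffled k-fold protocol.

    ``fit_predict(train_x, train_y, test_x)`` returns per-sample class
    probabilities (n, 3) — typically a closure over the CNN's train/predict,
    but any classifier honouring the signature works. Returns per-fold
    reports plus a summary with mean, sample SD and 95% t-CI per metric.
    """
    y = np.asarray(labels)
    if np.unique(y).size < len(LABELS):
        raise ValueError("dataset must cover all three classes")
    n = len(y)
    ids = np.asarray(sample_ids if sample_ids is not None else np.arange(n))
    folds = kfold_split(n, k=k, seed=seed)
    reports: list[FoldReport] = []
    for fold_index, test_idx in enumerate(folds, start=1):
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        train_idx = np.flatnonzero(~mask)
        _check_disjoint(ids[train_idx], ids[test_idx])
        proba = np.asarray(fit_predict(images[train_idx], y[train_idx], images[test_idx]))
        pred = proba.argmax(axis=1)
        cm = confusion(y[test_idx], pred)
        per_class, acc, sen, spe = macro_metrics(cm)
        epochs = getattr(fit_predict, "last_epochs_run", 0)
        reports.append(FoldReport(fold_index, per_class, acc, sen, spe, epochs, cm))
    summary = {
        name: summarize_folds([getattr(r, name) for r in reports])
        for name in ("acc", "sen", "spe")
    }
    return reports, summary


def run_loocv(
    images: np.ndarray,
    labels,
    subject_ids,
    fit_predict,
) -> dict[str, float]:
    """Leave-one-subject-out protocol.

    Every segment of one subject is withheld together; the subject's score
    is the fraction of their own segments predicted with their true label.
    Returns ``{subject_id: accuracy_percent}`` with one entry per subject
    that has at least one segment.
    """
    y = _encode(labels)
    subj = np.asarray([str(s) for s in subject_ids])
    out: dict[str, float] = {}
    for sid in dict.fromkeys(subj):  # preserves first-seen order
        test_mask = subj == sid
        if not test_mask.any():  # pragma: no cover - defensive
            continue
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        _check_disjoint(subj[train_idx], subj[test_idx])
        proba = np.asarray(fit_predict(images[train_idx], y[train_idx], images[test_idx]))
        pred = proba.argmax(axis=1)
        out[sid] = float(100.0 * np.mean(pred == y[test_idx]))
    return out


def pooled_accuracy(reports: list[FoldReport]) -> float:
    """Percent of all test samples across folds predicted correctly."""
    total_cm = np.sum([r.cm for r in reports if r.cm is not None], axis=0)
    return float(100.0 * np.trace(total_cm) / total_cm.sum())


# ---------------------------------------------------------------------------
# paired statistics over fold values


def paired_ttest(a, b) -> tuple[float, float]:
    """Classical paired t-test; returns (t, two-sided p) with n-1 df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("paired t-test degenerate: zero difference variance")
    t = d.mean() / (sd / sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), df=d.size - 1)
    return float(t), float(p)


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Exact null distribution of W+ over doubled ranks, by convolution.

    ``ranks2`` are midranks times two (integers even with ties). Returns
    counts[s] = number of sign assignments with sum of positive doubled
    ranks equal to s; equivalent to enumerating all 2**n sign vectors.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; tied absolute differences get midranks.
    The p-value is exact, conditional on the observed ranks: the null
    distribution is built over all 2**n sign assignments (by convolution,
    which enumerates the same space). Returns (W = min one-sided statistic,
    two-sided p). Limited to n <= 25 after zero removal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length vectors")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n > 25:
        raise ValueError("exact enumeration supported for n <= 25")
    ranks = stats.rankdata(np.abs(d))  # midranks for ties
    ranks2 = np.rint(2.0 * ranks).astype(int)
    w_pos2 = int(ranks2[d > 0].sum())
    total2 = int(ranks2.sum())
    dist = _signed_rank_distribution(ranks2)
    denom = 2.0**n
    cdf_le = dist[: w_pos2 + 1].sum() / denom
    cdf_ge = dist[w_pos2:].sum() / denom
    p = min(1.0, 2.0 * min(cdf_le, cdf_ge))
    w = min(w_pos2, total2 - w_pos2) / 2.0
    return float(w), float(p)


def summarize_folds(values) -> dict[str, float]:
    """Mean, sample SD and 95% t-interval of per-fold values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two fold values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = float(stats.t.ppf(0.975, df=v.size - 1) * sd / sqrt(v.size)) if sd > 0 else 0.0
    return {"mean": mean, "sd": sd, "ci95_low": mean - half, "ci95_high": mean + half}
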