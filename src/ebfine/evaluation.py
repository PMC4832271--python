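"""Replicate-level filtering performance: threshold-averaged ROC curves.

Filtering ranks all SNPs in a region by a statistic (Bayes factor,
posterior probability, p-value) and retains those at-or-above a threshold.
Across many simulated replicates with one known causal SNP each, the
true-positive rate at a threshold is the fraction of causal SNPs retained
and the false-positive rate the fraction of non-causal SNPs retained.
Replicates are combined by "threshold averaging": a common descending grid
of score thresholds is taken from the pooled score distribution, the
per-replicate (FPR, TPR) points are computed at each threshold, and the
mean over replicates is reported per threshold.

Also provided: trapezoid AUC, the number of SNPs retained at a target TPR
(with retained-set intersections between two statistics), replicate-level
bootstrap standard errors for AUCs, and the train/test protocol that guards
the empirical-Bayes prior variance against overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import summarize_all
from .bayes import surrogate_w_eb, wakefield_bf

__all__ = [
    "Replicate",
    "RocCurve",
    "RetentionSummary",
    "roc_threshold_average",
    "auc",
    "bootstrap_auc",
    "retained_at_tpr",
    "train_test_web",
    "DEFAULT_N_THRESHOLDS",
]

DEFAULT_N_THRESHOLDS = 512


@dataclass(frozen=True)
class Replicate:
    """Per-SNP scores and causal flags for one simulated dataset."""

    scores: np.ndarray
    causal: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        c = np.asarray(self.causal, dtype=bool)
        if s.shape != c.shape or s.ndim != 1:
            raise ValueError("scores and causal flags must be 1-D and equal length")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "causal", c)


@dataclass(frozen=True)
class RocCurve:
    """Threshold-averaged ROC curve.

    thresholds descend from +inf to -inf so the curve runs from (0, 0) to
    (1, 1); mean_fpr and mean_tpr are averages over replicates at each
    threshold.
    """

    thresholds: np.ndarray
    mean_fpr: np.ndarray
    mean_tpr: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        for arr in (self.mean_fpr, self.mean_tpr):
            if np.any((arr < 0) | (arr > 1)) or np.any(np.diff(arr) < 0):
                raise ValueError("rates must lie in [0, 1] and be non-decreasing")


def _coerce_replicates(replicates) -> list[Replicate]:
    out = []
    for i, rep in enumerate(replicates):
        if not isinstance(rep, Replicate):
            rep = Replicate(*rep)
        if not rep.causal.any():
            raise ValueError(f"replicate {i} has no causal SNP flagged")
        if rep.causal.all():
            raise ValueError(f"replicate {i} has no non-causal SNP")
        out.append(rep)
    if not out:
        raise ValueError("need at least one replicate")
    return out


def _rates_matrix(reps: list[Replicate], thresholds: np.ndarray):
    """Per-replicate TPR and FPR at each threshold ("at-or-above" retention)."""
    n_rep, n_thr = len(reps), thresholds.size
    tpr = np.empty((n_rep, n_thr))
    fpr = np.empty((n_rep, n_thr))
    # thresholds descend; count scores >= t via searchsorted on sorted scores
    for i, rep in enumerate(reps):
        pos = np.sort(rep.scores[rep.causal])
        neg = np.sort(rep.scores[~rep.causal])
        tpr[i] = 1.0 - np.searchsorted(pos, thresholds, side="left") / pos.size
        fpr[i] = 1.0 - np.searchsorted(neg, thresholds, side="left") / neg.size
    return tpr, fpr


def _threshold_grid(reps: list[Replicate], n_thresholds: int) -> np.ndarray:
    pooled = np.concatenate([r.scores for r in reps])
    qs = np.quantile(pooled, np.linspace(0.0, 1.0, n_thresholds))
    grid = np.unique(qs)[::-1]
    return np.concatenate([[np.inf], grid, [-np.inf]])


def roc_threshold_average(replicates, n_thresholds: int = DEFAULT_N_THRESHOLDS) -> RocCurve:
    """Average per-replicate ROC points on a common pooled-quantile grid.

    The grid is ``n_thresholds`` quantiles of the pooled score distribution
    (plus +/-inf sentinels).  With a single replicate this reproduces the
    ordinary empirical ROC curve evaluated on that grid.
    """
    reps = _coerce_replicates(replicates)
    if n_thresholds < 2:
        raise ValueError("need at least 2 thresholds")
    thresholds = _threshold_grid(reps, n_thresholds)
    tpr, fpr = _rates_matrix(reps, thresholds)
    return RocCurve(
        thresholds=thresholds,
        mean_fpr=fpr.mean(axis=0),
        mean_tpr=tpr.mean(axis=0),
        n_replicates=len(reps),
    )


def auc(curve: RocCurve) -> float:
    """Trapezoid-rule area under a threshold-averaged ROC curve."""
    if curve.mean_fpr.size < 2:
        raise ValueError("need at least two curve points")
    return float(np.trapezoid(curve.mean_tpr, curve.mean_fpr))


def bootstrap_auc(
    replicates,
    n_boot: int = 1000,
    seed: int = 0,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
) -> tuple[float, float]:
    """AUC with a replicate-level bootstrap standard error.

    Replicates (not SNPs) are resampled with replacement; the threshold grid
    is held fixed at the full-data pooled quantiles.
    """
    reps = _coerce_replicates(replicates)
    thresholds = _threshold_grid(reps, n_thresholds)
    tpr, fpr = _rates_matrix(reps, thresholds)
    point = float(np.trapezoid(tpr.mean(axis=0), fpr.mean(axis=0)))
    rng = np.random.default_rng(seed)
    n_rep = len(reps)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_rep, n_rep)
        aucs[b] = np.trapezoid(tpr[idx].mean(axis=0), fpr[idx].mean(axis=0))
    return point, float(aucs.std(ddof=1))


@dataclass(frozen=True)
class RetentionSummary:
    """SNPs retained when thresholding a statistic at a target mean TPR."""

    threshold: float
    mean_tpr: float
    mean_retained: float
    sd_retained: float
    counts: np.ndarray
    intersection_mean: float | None = None
    intersection_sd: float | None = None


def retained_at_tpr(replicates, target_tpr: float, secondary=None) -> RetentionSummary:
    """Retained-SNP counts at the largest threshold whose mean TPR meets target.

    Candidate thresholds are the causal-SNP scores (mean TPR only changes
    there); the largest threshold with mean TPR >= ``target_tpr`` is chosen,
    i.e. the fewest SNPs compatible with the target.  ``secondary``, if
    given, is a second statistic's replicate list over the same SNPs; the
    per-replicate intersection counts of the two retained sets (each at its
    own threshold meeting the target) are then also summarised.
    """
    if not 0 < target_tpr <= 1:
        raise ValueError("target_tpr must be in (0, 1]")
    reps = _coerce_replicates(replicates)
    causal_scores = np.sort(np.concatenate([r.scores[r.causal] for r in reps]))[::-1]
    mean_tpr_at = lambda t: float(np.mean([(r.scores[r.causal] >= t).mean() for r in reps]))
    threshold = None
    for t in np.unique(causal_scores)[::-1]:
        if mean_tpr_at(t) >= target_tpr:
            threshold = float(t)
            break
    if threshold is None:
        raise ValueError(f"mean TPR {target_tpr} unreachable")
    counts = np.array([(r.scores >= threshold).sum() for r in reps])
    summary = dict(
        threshold=threshold,
        mean_tpr=mean_tpr_at(threshold),
        mean_retained=float(counts.mean()),
        sd_retained=float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
        counts=counts,
    )
    if secondary is not None:
        sec = _coerce_replicates(secondary)
        if len(sec) != len(reps):
            raise ValueError("secondary statistic must cover the same replicates")
        other = retained_at_tpr(sec, target_tpr)
        inter = np.array(
            [
                ((r.scores >= threshold) & (s.scores >= other.threshold)).sum()
                for r, s in zip(reps, sec)
            ]
        )
        summary["intersection_mean"] = float(inter.mean())
        summary["intersection_sd"] = float(inter.std(ddof=1)) if inter.size > 1 else 0.0
    return RetentionSummary(**summary)


def _causal_flags(dataset) -> np.ndarray:
    flags = np.zeros(dataset.n_snps, dtype=bool)
    if dataset.causal_index is None:
        raise ValueError("dataset has no causal_index")
    flags[dataset.causal_index] = True
    return flags


def _bf_replicate(summaries, W, causal) -> Replicate:
    beta = np.array([s.beta_hat for s in summaries])
    V = np.array([s.V if s.usable else np.nan for s in summaries])
    scores = np.where(np.isnan(V), -np.inf, 0.0)
    ok = ~np.isnan(V)
    scores[ok] = np.log(wakefield_bf(beta[ok], V[ok], W))
    # unusable SNPs sink to the bottom of every ranking
    scores[~ok] = scores[ok].min() - 1.0 if ok.any() else 0.0
    return Replicate(scores=scores, causal=causal)


def train_test_web(pairs, p_percent: float = 30.0, n_thresholds: int = DEFAULT_N_THRESHOLDS):
    """Overfitting check for the empirical-Bayes prior variance.

    For each (train, test) dataset pair, W_EB is estimated from the train
    member's summaries and applied to Bayes factors in the test member;
    the comparison curve re-estimates W_EB on the test data itself
    ("same-data").  Returns ``(same_data_curve, train_test_curve)``.
    """
    same_reps: list[Replicate] = []
    cross_reps: list[Replicate] = []
    for train, test in pairs:
        if train.n_snps != test.n_snps or list(train.snp_ids) != list(test.snp_ids):
            raise ValueError("train/test pair covers different SNP sets")
        s_train = summarize_all(train)
        s_test = summarize_all(test)
        w_train = surrogate_w_eb(s_train, p_percent).W
        w_test = surrogate_w_eb(s_test, p_percent).W
        causal = _causal_flags(test)
        same_reps.append(_bf_replicate(s_test, w_test, causal))
        cross_reps.append(_bf_replicate(s_test, w_train, causal))
    same_curve = roc_threshold_average(same_reps, n_thresholds)
    cross_curve = roc_threshold_average(cross_reps, n_thresholds)
    return same_curve, cross_curve
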