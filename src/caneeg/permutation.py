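"""Permutation inference for decoding accuracies.

Null distributions are built by re-running the full cross-validation after
seeded label permutations (200 by default). Family-wise error across all
time intervals and category pairs of one subject is controlled with the
maximum-statistics device: per permutation index the maximum accuracy over
every classifier in the family is taken, and the observed accuracies are
thresholded at an upper quantile of those maxima, Bonferroni-corrected for
the number of subjects.

Alignment matters: permutation index ``r`` must mean the same relabelling
across every classifier of a subject. Classifiers that share trials (the
intervals of one task) literally reuse the permuted label vector; distinct
tasks draw their permutation from seed substreams spawned per index ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import (
    DecodingTask,
    _binary_data,
    cv_accuracy_folds,
    make_folds,
    pair_name,
)
from .epochs import EpochsSet
from .preprocessing import FeatureMatrix, vectorize_features


@dataclass
class PermutationNull:
    """Label-shuffled accuracy distribution for one classifier."""

    task: DecodingTask
    accuracies: np.ndarray
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=np.float64)
        if self.accuracies.shape != (self.n_perm,):
            raise ValueError("null length must equal the permutation count")
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("null accuracies must lie in [0, 1]")


def _perm_children(seed: int, n_perm: int) -> list:
    return np.random.SeedSequence(seed).spawn(n_perm)


def permutation_null(
    features: FeatureMatrix,
    pair,
    n_perm: int = 200,
    n_folds: int = 10,
    classifier: str = "svm",
    C: float = 1.0,
    standardize: bool = True,
    seed: int = 0,
    task_index: int = 0,
) -> PermutationNull:
    """Whole-dataset label-permutation null for one task.

    Labels are shuffled once per permutation before the CV loop (fold
    assignment is re-drawn from the permuted labels), and the mean CV
    accuracy recorded. Deterministic for a fixed seed; ``task_index``
    selects the task's substream so families stay aligned by permutation
    index.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pair = pair_name(*pair)
    X, y, _ = _binary_data(features, pair)
    children = _perm_children(seed, n_perm)
    accs = np.empty(n_perm)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child.spawn(task_index + 1)[task_index])
        y_perm = rng.permutation(y)
        fold_seed = int(rng.integers(2**31 - 1))
        folds = make_folds(y_perm, n_folds, fold_seed)
        accs[r] = cv_accuracy_folds(
            X, y_perm, folds, classifier, C, standardize
        ).mean()
    task = DecodingTask(pair=pair, subject=features.subject)
    return PermutationNull(task=task, accuracies=accs, n_perm=n_perm, seed=seed)


def permutation_null_timecourse(
    binned: EpochsSet,
    pair,
    intervals=None,
    n_perm: int = 200,
    n_folds: int = 10,
    classifier: str = "svm",
    C: float = 1.0,
    standardize: bool = True,
    seed: int = 0,
    task_index: int = 0,
) -> list:
    """Aligned per-interval nulls for one task.

    One label permutation per index ``r`` is shared by every interval
    classifier of the task, as the maximum statistic requires.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pair = pair_name(*pair)
    if intervals is None:
        intervals = list(range(binned.n_samples))
    Xs = []
    y = None
    for k in intervals:
        fm = vectorize_features(binned, "single-interval", k)
        X, y, _ = _binary_data(fm, pair)
        Xs.append(X)
    children = _perm_children(seed, n_perm)
    accs = np.empty((len(intervals), n_perm))
    for r, child in enumerate(children):
        rng = np.random.default_rng(child.spawn(task_index + 1)[task_index])
        y_perm = rng.permutation(y)
        fold_seed = int(rng.integers(2**31 - 1))
        folds = make_folds(y_perm, n_folds, fold_seed)
        for j, X in enumerate(Xs):
            accs[j, r] = cv_accuracy_folds(
                X, y_perm, folds, classifier, C, standardize
            ).mean()
    out = []
    for j, k in enumerate(intervals):
        task = DecodingTask(pair=pair, mode="single-interval",
                            interval_index=int(k), subject=binned.subject)
        out.append(PermutationNull(task=task, accuracies=accs[j],
                                   n_perm=n_perm, seed=seed))
    return out


def empirical_chance_interval(nulls: list, coverage: float = 0.95) -> tuple:
    """Central coverage interval of the pooled null accuracies, in percent.

    The device behind the reported empirical chance level: pooled over the
    supplied classifiers' nulls, the (1-coverage)/2 and 1-(1-coverage)/2
    quantiles, scaled to percent.
    """
    if not nulls:
        raise ValueError("need at least one null distribution")
    if not (0 < coverage <= 1):
        raise ValueError("coverage must lie in (0, 1]")
    pooled = np.concatenate([n.accuracies for n in nulls])
    tail = (1.0 - coverage) / 2.0
    lo, hi = np.quantile(pooled, [tail, 1.0 - tail])
    return float(lo * 100.0), float(hi * 100.0)


def maxstat_threshold(
    nulls: list, alpha: float = 0.05, bonferroni_n: int = 1
) -> float:
    """Family-wise accuracy threshold from aligned null maxima.

    Per permutation index ``r`` the maximum accuracy over all supplied
    classifiers is taken; the threshold is the ``m``-th largest maximum with
    ``m = floor(alpha / bonferroni_n * (n_perm + 1))``, significance being
    strictly above it. This bounds the family-wise error at
    ``m / (n_perm + 1) <= alpha / bonferroni_n`` under exchangeability; when
    the corrected level is below the permutation resolution (``m < 1``) the
    largest maximum is used.
    """
    if not nulls:
        raise ValueError("need at least one null distribution")
    if not (0 < alpha < 1) or bonferroni_n < 1:
        raise ValueError("alpha must be in (0,1) and bonferroni_n >= 1")
    n_perm = nulls[0].n_perm
    if any(n.n_perm != n_perm for n in nulls):
        raise ValueError("misaligned permutation counts across the family")
    maxima = np.max(np.stack([n.accuracies for n in nulls]), axis=0)
    m = int(np.floor(alpha / bonferroni_n * (n_perm + 1)))
    if m < 1:
        return float(maxima.max())
    return float(np.sort(maxima)[::-1][m - 1])


@dataclass
class SignificanceMatrix:
    """Subject x task x interval significance after max-stat + Bonferroni."""

    significant: np.ndarray  # bool (n_subjects, n_tasks, n_intervals)
    subjects: list
    task_names: list
    interval_starts_ms: np.ndarray
    thresholds: np.ndarray  # per subject
    alpha: float
    bonferroni_n: int

    def __post_init__(self) -> None:
        self.significant = np.asarray(self.significant, dtype=bool)
        ns, nt, ni = self.significant.shape
        if (
            len(self.subjects) != ns
            or len(self.task_names) != nt
            or len(self.interval_starts_ms) != ni
            or len(self.thresholds) != ns
        ):
            raise ValueError("significance tensor does not match the analysis grid")


def significance_mask(observed: np.ndarray, threshold: float) -> np.ndarray:
    """Cells strictly above the family threshold."""
    return np.asarray(observed, dtype=np.float64) > threshold


def build_significance_matrix(
    observed_by_subject: dict,
    nulls_by_subject: dict,
    task_names: list,
    interval_starts_ms: np.ndarray,
    alpha: float = 0.05,
    bonferroni_n: int | None = None,
) -> SignificanceMatrix:
    """Assemble the full matrix from per-subject observations and nulls.

    ``observed_by_subject[s]`` is ``(n_tasks, n_intervals)`` accuracy;
    ``nulls_by_subject[s]`` the flat list of that subject's aligned
    :class:`PermutationNull` (every task and interval). ``bonferroni_n``
    defaults to the number of subjects.
    """
    subjects = list(observed_by_subject)
    if bonferroni_n is None:
        bonferroni_n = len(subjects)
    sig, thresholds = [], []
    for s in subjects:
        thr = maxstat_threshold(nulls_by_subject[s], alpha, bonferroni_n)
        thresholds.append(thr)
        sig.append(significance_mask(observed_by_subject[s], thr))
    return SignificanceMatrix(
        significant=np.stack(sig),
        subjects=subjects,
        task_names=list(task_names),
        interval_starts_ms=np.asarray(interval_starts_ms, dtype=np.float64),
        thresholds=np.asarray(thresholds),
        alpha=alpha,
        bonferroni_n=int(bonferroni_n),
    )
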