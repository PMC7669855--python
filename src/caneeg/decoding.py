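"""Binary decoding of single-trial feature vectors.

One linear-kernel SVM per unordered category pair — 28 classifiers for the
eight categories — evaluated with stratified 10-fold cross-validation,
either on the whole-epoch feature vector (301 dimensions by default) or on
each 20-ms interval separately (7 dimensions, one per channel). Feature
standardization statistics are estimated on the training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .epochs import EpochsSet
from .labels import as_label
from .preprocessing import FeatureMatrix, vectorize_features


@dataclass(frozen=True)
class DecodingTask:
    """One binary classification task."""

    pair: tuple  # two distinct category codes, canonical order
    mode: str = "whole-epoch"
    interval_index: int | None = None
    subject: str = ""

    def __post_init__(self) -> None:
        if len(self.pair) != 2 or self.pair[0] == self.pair[1]:
            raise ValueError("task pair must hold two distinct categories")
        if self.mode == "single-interval" and self.interval_index is None:
            raise ValueError("single-interval task needs an interval index")

    @property
    def name(self) -> str:
        return f"{self.pair[0]}_vs_{self.pair[1]}"


@dataclass
class ClassificationResult:
    """Cross-validated accuracy for one task."""

    task: DecodingTask
    accuracy: float
    fold_accuracies: np.ndarray
    n_per_class: dict
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


def pair_name(a, b) -> tuple:
    """Canonical ordering of a category pair (category-list order)."""
    from .labels import ALL_CATEGORIES

    order = [c.value for c in ALL_CATEGORIES]
    a, b = as_label(a).value, as_label(b).value
    return (a, b) if order.index(a) <= order.index(b) else (b, a)


def enumerate_tasks(categories, subject: str = "", mode: str = "whole-epoch") -> list:
    """One task per unordered category pair: C(k, 2) tasks, 28 for k = 8."""
    cats = [as_label(c).value for c in categories]
    if len(set(cats)) < 2:
        raise ValueError("need at least 2 categories to enumerate tasks")
    return [
        DecodingTask(pair=pair_name(a, b), mode=mode, subject=subject)
        for a, b in combinations(dict.fromkeys(cats), 2)
    ]


def scrambled_tasks(categories=None, subject: str = "") -> list:
    """The seven tasks discriminating scrambled images from each other
    category; the task family behind the time-resolved analysis."""
    from .labels import ALL_CATEGORIES

    cats = [as_label(c).value for c in (categories or ALL_CATEGORIES)]
    return [
        DecodingTask(pair=pair_name(c, "S"), subject=subject)
        for c in cats
        if c != "S"
    ]


# --------------------------------------------------------------------------
# Cross-validation core
# --------------------------------------------------------------------------

def _binary_data(features: FeatureMatrix, pair) -> tuple:
    codes = [as_label(c).value for c in pair]
    mask = np.isin(np.asarray([str(lb) for lb in features.labels]), codes)
    X = features.X[mask]
    y = (np.asarray([str(lb) for lb in features.labels])[mask] == codes[1]).astype(int)
    counts = {codes[0]: int((y == 0).sum()), codes[1]: int((y == 1).sum())}
    return X, y, counts


def make_folds(y: np.ndarray, n_folds: int, seed: int) -> list:
    """Seeded stratified fold assignment: list of (train_idx, test_idx)."""
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        lacking = classes[np.argmin(counts)]
        raise ValueError(
            f"class {lacking!r} has {counts.min()} trials < {n_folds} folds; "
            f"reduce the number of folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def _make_classifier(classifier: str, C: float):
    if classifier == "svm":
        return SVC(kernel="linear", C=C)
    if classifier == "lasso-logistic":
        return LogisticRegression(penalty="l1", solver="liblinear", C=C)
    raise ValueError("classifier must be 'svm' or 'lasso-logistic'")


try:  # low-level libsvm binding: same solver as SVC without estimator overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - fall back to the public estimator
    _libsvm = None


def _linear_svm_predict(Xtr, ytr, Xte, C: float) -> np.ndarray:
    """Linear-kernel C-SVC predictions for binary 0/1 labels.

    Calls libsvm directly and evaluates the linear decision function
    ``w.x + b`` in numpy (libsvm's sign convention assigns class 1 to
    non-positive decisions here); prediction equivalence with
    ``SVC(kernel='linear')`` is asserted in the test suite.
    """
    out = _libsvm.fit(
        np.ascontiguousarray(Xtr), ytr.astype(np.float64),
        svm_type=0, kernel="linear", C=C,
    )
    w = out[3][0] @ out[1]
    dec = Xte @ w + out[4][0]
    return (dec <= 0).astype(int)


def cv_accuracy_folds(
    X: np.ndarray, y: np.ndarray, folds: list,
    classifier: str = "svm", C: float = 1.0, standardize: bool = True,
) -> np.ndarray:
    """Per-fold test accuracies with train-fold-only standardization."""
    accs = np.empty(len(folds))
    for i, (tr, te) in enumerate(folds):
        Xtr, Xte = X[tr], X[te]
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        if classifier == "svm" and _libsvm is not None:
            pred = _linear_svm_predict(Xtr, y[tr], Xte, C)
        else:
            clf = _make_classifier(classifier, C)
            clf.fit(Xtr, y[tr])
            pred = clf.predict(Xte)
        accs[i] = float(np.mean(pred == y[te]))
    return accs


def crossval_accuracy(
    features: FeatureMatrix,
    pair,
    n_folds: int = 10,
    classifier: str = "svm",
    C: float = 1.0,
    standardize: bool = True,
    seed: int = 0,
    mode: str = "whole-epoch",
    interval_index: int | None = None,
) -> ClassificationResult:
    """Mean cross-validated accuracy of one binary task.

    Stratified, seeded fold assignment; the classifier (and any
    standardization statistics) sees training folds only.
    """
    pair = pair_name(*pair)
    X, y, counts = _binary_data(features, pair)
    folds = make_folds(y, n_folds, seed)
    accs = cv_accuracy_folds(X, y, folds, classifier, C, standardize)
    task = DecodingTask(pair=pair, mode=mode, interval_index=interval_index,
                        subject=features.subject)
    return ClassificationResult(
        task=task,
        accuracy=float(accs.mean()),
        fold_accuracies=accs,
        n_per_class=counts,
        hyperparameters={"classifier": classifier, "C": C,
                         "standardize": standardize, "n_folds": n_folds},
        seed=seed,
    )


def timecourse_accuracies(
    binned: EpochsSet,
    pair,
    n_folds: int = 10,
    classifier: str = "svm",
    C: float = 1.0,
    standardize: bool = True,
    seed: int = 0,
    intervals: "list | None" = None,
) -> list:
    """One single-interval classifier per 20-ms bin for one task.

    The fold assignment is drawn once from the task's labels and reused
    across intervals, so the temporal profile reflects the features, not
    fold resampling noise.
    """
    pair = pair_name(*pair)
    if intervals is None:
        intervals = list(range(binned.n_samples))
    first = vectorize_features(binned, "single-interval", intervals[0])
    _, y, counts = _binary_data(first, pair)
    folds = make_folds(y, n_folds, seed)
    results = []
    for k in intervals:
        fm = vectorize_features(binned, "single-interval", k)
        X, _, _ = _binary_data(fm, pair)
        accs = cv_accuracy_folds(X, y, folds, classifier, C, standardize)
        task = DecodingTask(pair=pair, mode="single-interval",
                            interval_index=int(k), subject=binned.subject)
        results.append(
            ClassificationResult(
                task=task,
                accuracy=float(accs.mean()),
                fold_accuracies=accs,
                n_per_class=counts,
                hyperparameters={"classifier": classifier, "C": C,
                                 "standardize": standardize, "n_folds": n_folds},
                seed=seed,
            )
        )
    return results
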