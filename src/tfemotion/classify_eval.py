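"""Subject-specific one-vs-one RBF-SVM training and 10-fold evaluation.

Each subject gets their own classifier per labeling scheme.  Multiclass
problems use the one-against-one decomposition (k(k-1)/2 binary machines
with voting), which is the SVC default internally.  Hyperparameters (C and
the RBF width gamma) come from a deterministic two-dimensional grid search
scored by stratified inner cross-validation on the training portion only;
ties go to the smaller C, then the smaller gamma.

Outer evaluation is stratified 10-fold cross-validation at the
feature-vector (window) level.  Within every fold, standardization and --
by default -- mRMR selection are fitted on the training split only.  Two
leakage-related switches exist because the underlying protocol is commonly
left unstated in the field: ``pooled_selection`` fits the selector once on all of
a subject's data, and ``groups`` (trial identifiers) keeps all windows of a
trial in the same fold, preventing overlap between near-duplicate windows
in train and test.

Accuracy is (tp + tn) / total in percent; the F1-measure is
2 tp / (2 tp + fp + fn) for binary problems (positive class = the "high"
class) and the unweighted macro average of per-class one-vs-rest F1 scores
for multiclass problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import selection as _selection

__all__ = [
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "SVMHyperParams",
    "ConfusionCounts",
    "CVReport",
    "compute_metrics",
    "confusion_matrix_metrics",
    "grid_search",
    "cross_validate_subject",
]

#: Powers-of-two grids for the regularization and RBF-width parameters.
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class SVMHyperParams:
    C: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.C > 0 and self.gamma > 0):
            raise ValueError("C and gamma must be positive")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts (positive = the designated positive class)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class CVReport:
    """Per-fold and aggregated results for one evaluation cell."""

    subject_id: str
    scheme: str
    channel_config: str
    scenario: str
    per_fold_acc: list[float]
    per_fold_f1: list[float]
    chosen_params: list[SVMHyperParams] = field(default_factory=list)

    @property
    def mean_acc(self) -> float:
        return float(np.mean(self.per_fold_acc))

    @property
    def std_acc(self) -> float:
        return float(np.std(self.per_fold_acc, ddof=1))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.per_fold_f1))


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float]:
    """Binary accuracy and F1-measure, both in percent."""
    if counts.total <= 0:
        raise ValueError("confusion counts are empty")
    acc = 100.0 * (counts.tp + counts.tn) / counts.total
    denom = 2 * counts.tp + counts.fp + counts.fn
    f1 = 100.0 * 2 * counts.tp / denom if denom > 0 else 0.0
    return acc, f1


def _positive_class_index(classes: np.ndarray) -> int:
    """Index of the 'high' class in a binary problem (HA, HV, ...)."""
    high = [i for i, c in enumerate(classes) if str(c).startswith("H")]
    return high[0] if len(high) == 1 else 1


def confusion_matrix_metrics(matrix: np.ndarray, classes) -> tuple[float, float]:
    """Accuracy and F1 (percent) from a class x class confusion matrix.

    Binary problems reduce exactly to the tp/tn/fp/fn formulas with the
    "high" class positive; multiclass problems report macro-averaged F1.
    """
    matrix = np.asarray(matrix, dtype=float)
    classes = np.asarray(classes)
    total = matrix.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    if matrix.shape[0] == 2:
        p = _positive_class_index(classes)
        n = 1 - p
        counts = ConfusionCounts(
            tp=int(matrix[p, p]), tn=int(matrix[n, n]),
            fp=int(matrix[n, p]), fn=int(matrix[p, n]),
        )
        return compute_metrics(counts)
    acc = 100.0 * np.trace(matrix) / total
    f1s = []
    for i in range(matrix.shape[0]):
        tp = matrix[i, i]
        fp = matrix[:, i].sum() - tp
        fn = matrix[i, :].sum() - tp
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom > 0 else 0.0)
    return float(acc), float(100.0 * np.mean(f1s))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    matrix = np.zeros((classes.size, classes.size), dtype=int)
    for t, p in zip(y_true, y_pred):
        matrix[index[t], index[p]] += 1
    return matrix


def _fit_svc(X: np.ndarray, y: np.ndarray, params: SVMHyperParams) -> SVC:
    return SVC(C=params.C, gamma=params.gamma, kernel="rbf",
               decision_function_shape="ovo").fit(X, y)


def grid_search(
    train_features: np.ndarray,
    train_labels,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    inner_folds: int = 5,
    seed: int = 0,
) -> SVMHyperParams:
    """Pick (C, gamma) maximizing stratified inner-CV accuracy.

    The grid is scanned in ascending C then ascending gamma with a strict
    improvement rule, so ties resolve to the smallest C, then gamma.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("grid search needs at least two classes in the training labels")
    n_splits = int(min(inner_folds, counts.min()))
    if n_splits < 2:
        raise ValueError("every class needs at least two training samples for the inner CV")
    splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(splitter.split(X, y))
    best: tuple[float, SVMHyperParams] | None = None
    for C in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            params = SVMHyperParams(C=C, gamma=gamma)
            correct = 0
            for train_idx, test_idx in folds:
                model = _fit_svc(X[train_idx], y[train_idx], params)
                correct += int(np.sum(model.predict(X[test_idx]) == y[test_idx]))
            score = correct / X.shape[0]
            if best is None or score > best[0]:
                best = (score, params)
    return best[1]


def cross_validate_subject(
    features: np.ndarray,
    labels,
    scheme: str,
    seed: int,
    subject_id: str = "",
    channel_config: str = "",
    selection_scenario: str | None = None,
    n_folds: int = 10,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    inner_folds: int = 5,
    pooled_selection: bool = False,
    groups=None,
) -> CVReport:
    """Stratified 10-fold cross-validation of one subject's feature vectors.

    Every vector is tested exactly once.  Standardization, mRMR selection
    (if a scenario is given) and the hyperparameter search are fitted on
    each fold's training split; ``pooled_selection`` instead fits the selector
    once on all data before splitting.  ``groups`` switches to group-aware
    stratified folding at trial granularity.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("cross-validation needs at least two classes")
    if counts.min() < n_folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has only {counts.min()} samples, fewer than the "
            f"{n_folds} folds; merge or exclude it, or reduce n_folds"
        )
    global_selection = None
    if selection_scenario is not None and pooled_selection:
        global_selection = _selection.select_top_fraction(X, y, selection_scenario)

    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = splitter.split(X, y, groups=np.asarray(groups))
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = splitter.split(X, y)

    per_fold_acc: list[float] = []
    per_fold_f1: list[float] = []
    chosen: list[SVMHyperParams] = []
    for fold_index, (train_idx, test_idx) in enumerate(folds):
        X_train, X_test = X[train_idx], X[test_idx]
        y_train, y_test = y[train_idx], y[test_idx]
        if selection_scenario is not None:
            sel = global_selection or _selection.select_top_fraction(
                X_train, y_train, selection_scenario
            )
            keep = list(sel.ranked_indices)
            X_train, X_test = X_train[:, keep], X_test[:, keep]
        scaler = StandardScaler().fit(X_train)
        X_train = scaler.transform(X_train)
        X_test = scaler.transform(X_test)
        params = grid_search(
            X_train, y_train, c_grid=c_grid, gamma_grid=gamma_grid,
            inner_folds=inner_folds, seed=seed + fold_index,
        )
        model = _fit_svc(X_train, y_train, params)
        matrix = _confusion(y_test, model.predict(X_test), classes)
        acc, f1 = confusion_matrix_metrics(matrix, classes)
        per_fold_acc.append(acc)
        per_fold_f1.append(f1)
        chosen.append(params)
    return CVReport(
        subject_id=subject_id,
        scheme=scheme,
        channel_config=channel_config,
        scenario=selection_scenario or "all",
        per_fold_acc=per_fold_acc,
        per_fold_f1=per_fold_f1,
        chosen_params=chosen,
    )
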