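"""Greedy mRMR feature ranking and top-fraction selection scenarios.

Minimum-redundancy-maximum-relevance ranks feature columns incrementally:
the next column is the one maximizing

    I(x; y)  -  mean over already-selected s of I(x; s),

the mutual-information difference (MID) criterion.  Continuous features are
discretized into three states at mean +/- one standard deviation before the
mutual informations are estimated by contingency counting; ties are broken
toward the lower column index, so the ranking is deterministic.

Selection scenarios keep the top 5, 25, 50 or 75 percent (ceiling) of the
ranked columns, or all of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log

import numpy as np

from .features import feature_kind, FEATURE_NAMES

__all__ = [
    "SCENARIO_FRACTIONS",
    "SelectionResult",
    "discretize_features",
    "mutual_information",
    "mrmr_rank",
    "select_top_fraction",
    "selection_ratios",
]

SCENARIO_FRACTIONS: dict[str, float] = {
    "top5": 0.05,
    "top25": 0.25,
    "top50": 0.50,
    "top75": 0.75,
    "all": 1.0,
}


@dataclass(frozen=True)
class SelectionResult:
    """Ranked column indices with per-step criterion scores."""

    ranked_indices: tuple[int, ...]
    scores: tuple[float, ...]
    fraction: float = 1.0
    scenario: str = "all"


def discretize_features(X: np.ndarray) -> np.ndarray:
    """Map each column to {0, 1, 2}: below mean-std, within, above mean+std.

    Constant columns map to the middle state everywhere.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return (X > mu - sd).astype(np.int8) + (X > mu + sd).astype(np.int8)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information in bits between two discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def _encode_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes, encoded = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("mRMR requires at least two classes in the labels")
    return encoded


def mrmr_rank(features: np.ndarray, labels, n_select: int | None = None) -> SelectionResult:
    """Greedy MID ranking of feature columns against the class labels."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a (samples x features) matrix")
    n_samples, n_features = X.shape
    if n_select is None:
        n_select = n_features
    if not (1 <= n_select <= n_features):
        raise ValueError("n_select must be in [1, n_features]")
    y = _encode_labels(labels)
    D = discretize_features(X)

    relevance = np.array([mutual_information(D[:, j], y) for j in range(n_features)])
    redundancy_sum = np.zeros(n_features)
    selected: list[int] = []
    scores: list[float] = []
    remaining = np.ones(n_features, dtype=bool)
    for step in range(n_select):
        if step == 0:
            criterion = relevance.copy()
        else:
            criterion = relevance - redundancy_sum / step
        criterion[~remaining] = -np.inf
        best = int(np.argmax(criterion))  # argmax returns the lowest tied index
        selected.append(best)
        scores.append(float(criterion[best]))
        remaining[best] = False
        if step < n_select - 1:
            for j in np.nonzero(remaining)[0]:
                redundancy_sum[j] += mutual_information(D[:, j], D[:, best])
    return SelectionResult(tuple(selected), tuple(scores))


def select_top_fraction(features: np.ndarray, labels, scenario: str) -> SelectionResult:
    """Rank with mRMR and keep the top fraction named by ``scenario``."""
    try:
        fraction = SCENARIO_FRACTIONS[scenario]
    except KeyError:
        valid = ", ".join(SCENARIO_FRACTIONS)
        raise KeyError(f"unknown scenario {scenario!r}; valid: {valid}") from None
    n_features = np.asarray(features).shape[1]
    keep = n_features if scenario == "all" else ceil(fraction * n_features)
    ranked = mrmr_rank(features, labels, n_select=keep)
    return SelectionResult(ranked.ranked_indices, ranked.scores, fraction, scenario)


def selection_ratios(
    per_subject_selections: list[SelectionResult], feature_names: tuple[str, ...]
) -> dict[str, float]:
    """Average, over subjects, of each descriptor kind's share of selections.

    For each subject the ratio of a kind is the number of selected columns of
    that kind over the total selected; per-subject ratios sum to one.
    """
    if not per_subject_selections:
        raise ValueError("need at least one selection result")
    totals = {kind: 0.0 for kind in FEATURE_NAMES}
    for result in per_subject_selections:
        kinds = [feature_kind(feature_names[j]) for j in result.ranked_indices]
        n = len(kinds)
        for kind in FEATURE_NAMES:
            totals[kind] += kinds.count(kind) / n
    n_subjects = len(per_subject_selections)
    return {kind: total / n_subjects for kind, total in totals.items()}
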