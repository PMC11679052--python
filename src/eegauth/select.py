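"""Mutual-information feature selection.

Each band-power feature is scored by its mutual information with the user
labels, estimated with a plug-in estimator on an equal-frequency (quantile
edge) discretisation of the feature, and the Q highest-scoring features are
kept. The binning is rank-based, so scores are invariant under strictly
monotone transforms of a feature; the log is natural (nats), which is
irrelevant for ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix


@dataclass
class SelectionResult:
    """MI scores and the retained column subset (in MI-rank order)."""

    mi_scores: np.ndarray           # (P,) nats
    selected_indices: np.ndarray    # (Q,) column indices, descending MI
    q: int
    n_bins: int
    columns: list[str] = field(default_factory=list)  # full column names

    def selected_columns(self) -> list[str]:
        return [self.columns[i] for i in self.selected_indices]


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of n_bins equal-frequency bins.

    Edges are the empirical quantiles at i/n_bins; because quantile edges
    transform along with the data under any strictly increasing map, the
    binning (hence the MI estimate) depends only on ranks.
    """
    edges = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def estimate_mi(feature_column: np.ndarray, labels: np.ndarray,
                n_bins: int = 10) -> float:
    """Plug-in MI (nats) between a discretised feature and the labels.

    MI = sum over (bin, label) cells of p(x,y) * ln(p(x,y) / (p(x) p(y))),
    with 0 * ln(0/q) := 0. Features with fewer than two distinct values carry
    no information and return 0 with a warning.
    """
    x = np.asarray(feature_column, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if x.size != y.size:
        raise ValueError("feature and labels must have equal length")
    if x.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} samples")
    if np.unique(x).size < 2:
        warnings.warn("feature column has fewer than 2 distinct values; MI = 0",
                      stacklevel=2)
        return 0.0
    bins = _equal_frequency_bins(x, n_bins)
    _, y_codes = np.unique(y, return_inverse=True)
    n_y = y_codes.max() + 1
    joint = np.zeros((n_bins, n_y))
    np.add.at(joint, (bins, y_codes), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def select_top_q(features: FeatureMatrix, q: int = 10, n_bins: int = 10
                 ) -> tuple[SelectionResult, FeatureMatrix]:
    """Keep the q columns with largest MI against the labels (training rows
    only — callers must pass the training portion).

    Ties are broken toward the smaller column index. Returns the selection
    and the column-reduced FeatureMatrix (columns in MI-rank order).
    """
    p = features.n_features
    if not (1 <= q <= p):
        raise ValueError(f"q must be in [1, {p}], got {q}")
    scores = np.array([
        estimate_mi(features.values[:, j], features.labels, n_bins=n_bins)
        for j in range(p)
    ])
    # stable sort on -score => ties resolve to the smaller index
    order = np.argsort(-scores, kind="stable")
    selected = order[:q]
    result = SelectionResult(mi_scores=scores, selected_indices=selected,
                             q=q, n_bins=n_bins, columns=list(features.columns))
    return result, features.take_columns(selected)


def apply_selection(features: FeatureMatrix, result: SelectionResult) -> FeatureMatrix:
    """Apply a fitted selection to new rows (e.g. the test split)."""
    if features.n_features != len(result.mi_scores):
        raise ValueError(
            f"feature matrix has {features.n_features} columns; selection was "
            f"fitted on {len(result.mi_scores)}")
    return features.take_columns(result.selected_indices)
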