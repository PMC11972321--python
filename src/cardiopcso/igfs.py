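"""Information-Gain-based Feature Selection (IGFS).

A feature's information gain is the reduction in label entropy obtained by
conditioning on it,

    IG(X, Y) = H(Y) - H(Y | X),

with H in bits (log base 2).  Numeric features are discretized first
(equal-width by default); features whose gain exceeds a threshold — the mean
gain, a fixed value, or an implicit top-k cutoff — are selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from cardiopcso.synthetic import TabularDataset

__all__ = [
    "entropy",
    "conditional_entropy",
    "information_gain",
    "Discretizer",
    "FeatureScoreTable",
    "select_features",
]

log = logging.getLogger(__name__)


def entropy(labels) -> float:
    """Shannon entropy -sum p_i log2 p_i in bits; 0*log0 := 0."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(feature_values, labels) -> float:
    """H(Y|X) = sum_v P(X=v) H(Y | X=v) in bits, X discrete."""
    x = np.asarray(feature_values)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError("feature and label lengths differ")
    total = 0.0
    for v in np.unique(x):
        sel = x == v
        total += sel.mean() * entropy(y[sel])
    return float(total)


def information_gain(feature_values, labels) -> float:
    """IG(X, Y) = H(Y) - H(Y|X); tiny negatives from rounding clip to 0."""
    ig = entropy(labels) - conditional_entropy(feature_values, labels)
    return 0.0 if -1e-12 < ig < 0 else float(ig)


@dataclass
class Discretizer:
    """Bin a numeric column into ``bins`` codes 0..bins-1.

    ``equal_width`` splits the fitted range evenly; ``equal_frequency`` uses
    empirical quantiles.  Fitted edges are reused on held-out data, with
    out-of-range values clipped into the end bins.
    """

    bins: int = 10
    strategy: str = "equal_width"
    edges: np.ndarray | None = None  # interior edges, len bins-1

    def __post_init__(self):
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.strategy not in ("equal_width", "equal_frequency"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    def fit(self, column) -> "Discretizer":
        col = np.asarray(column, dtype=float)
        if self.strategy == "equal_width":
            lo, hi = col.min(), col.max()
            if lo == hi:
                # constant column: single bin, no interior edges
                self.edges = np.array([])
                return self
            self.edges = np.linspace(lo, hi, self.bins + 1)[1:-1]
        else:
            if col.min() == col.max():
                raise ValueError("constant column with equal_frequency binning")
            q = np.linspace(0, 1, self.bins + 1)[1:-1]
            self.edges = np.quantile(col, q)
        return self

    def transform(self, column) -> np.ndarray:
        if self.edges is None:
            raise RuntimeError("Discretizer not fitted")
        col = np.asarray(column, dtype=float)
        return np.searchsorted(self.edges, col, side="right")

    def fit_transform(self, column) -> np.ndarray:
        return self.fit(column).transform(column)


@dataclass
class FeatureScoreTable:
    """Per-feature information gain with selection flags and rank order."""

    names: list[str]
    gains: np.ndarray
    selected: np.ndarray
    threshold: float
    rank: np.ndarray = field(default=None)  # feature indices, best first

    def __post_init__(self):
        if self.rank is None:
            # stable descending sort keeps original order on ties
            self.rank = np.argsort(-np.asarray(self.gains), kind="stable")

    @property
    def ranked_names(self) -> list[str]:
        return [self.names[i] for i in self.rank]

    @property
    def selected_names(self) -> list[str]:
        return [n for n, s in zip(self.names, self.selected) if s]

    def to_dict(self) -> dict:
        return {
            "threshold": float(self.threshold),
            "features": [
                {"name": n, "information_gain": float(g), "selected": bool(s)}
                for n, g, s in zip(self.names, self.gains, self.selected)
            ],
            "ranked": self.ranked_names,
        }


def select_features(
    dataset: TabularDataset,
    bins: int = 10,
    threshold_rule="mean_ig",
    strategy: str = "equal_width",
) -> FeatureScoreTable:
    """Score every feature by information gain and apply the threshold rule.

    ``threshold_rule`` is ``"mean_ig"`` (default), ``("fixed", value)`` or
    ``("top_k", k)``.  Numeric columns are discretized with ``bins`` bins;
    categorical columns are used as-is.  Ties keep original feature order.
    """
    X, y, schema = dataset.X, dataset.y, dataset.schema
    if len(schema) < 2:
        raise ValueError("need at least 2 features")
    gains = np.empty(len(schema))
    for j, spec in enumerate(schema):
        col = X[:, j]
        if spec.kind == "numeric":
            col = Discretizer(bins=bins, strategy=strategy).fit_transform(col)
        gains[j] = information_gain(col, y)

    rank = np.argsort(-gains, kind="stable")
    if threshold_rule == "mean_ig":
        threshold = float(gains.mean())
        selected = gains > threshold
    elif isinstance(threshold_rule, tuple) and threshold_rule[0] == "fixed":
        threshold = float(threshold_rule[1])
        selected = gains > threshold
    elif isinstance(threshold_rule, tuple) and threshold_rule[0] == "top_k":
        k = int(threshold_rule[1])
        if np.all(gains == 0) and k > 0:
            log.warning("all information gains are zero; top_k falls back to feature order")
        selected = np.zeros(len(schema), dtype=bool)
        selected[rank[:k]] = True
        threshold = float(gains[rank[k - 1]]) if 0 < k <= len(schema) else float("inf")
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")

    return FeatureScoreTable([s.name for s in schema], gains, selected, threshold, rank)
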