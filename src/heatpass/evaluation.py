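"""Clustering performance indices: accuracy (AI), Rand (RI), quality (QI).

All three are normalized to [0, 1].  AI matches predicted clusters to
truth classes by an optimal one-to-one assignment on the contingency
table; RI counts pair agreements; QI is the silhouette on a distance
matrix mapped from [-1, 1] to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .graph_core import HeatDistanceMatrix

__all__ = ["LabeledPartition", "accuracy_index", "rand_index", "quality_index"]


@dataclass(frozen=True)
class LabeledPartition:
    """A flat partition given as an arbitrary-valued label per element."""

    labels: tuple

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_sequence(cls, seq) -> "LabeledPartition":
        return cls(labels=tuple(seq))

    def codes(self) -> np.ndarray:
        _, codes = np.unique(np.asarray(self.labels, dtype=object), return_inverse=True)
        return codes


def _as_partition(x) -> LabeledPartition:
    return x if isinstance(x, LabeledPartition) else LabeledPartition.from_sequence(x)


def _contingency(pred: LabeledPartition, truth: LabeledPartition) -> np.ndarray:
    p, t = pred.codes(), truth.codes()
    table = np.zeros((p.max() + 1, t.max() + 1), dtype=np.int64)
    np.add.at(table, (p, t), 1)
    return table


def accuracy_index(pred, truth) -> float:
    """Fraction of elements whose matched cluster equals their true class.

    Clusters are matched to classes one-to-one so as to maximize the total
    matched count (Hungarian assignment on the contingency table), making
    the index invariant to label renaming.  Note AI(pred, truth) is not
    symmetric in general.
    """
    pred, truth = _as_partition(pred), _as_partition(truth)
    if pred.n != truth.n:
        raise ValueError(f"partition lengths differ: {pred.n} vs {truth.n}")
    table = _contingency(pred, truth)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum()) / pred.n


def rand_index(pred, truth) -> float:
    """Pair-agreement fraction: pairs co-clustered in both partitions or
    separated in both, over all unordered pairs."""
    pred, truth = _as_partition(pred), _as_partition(truth)
    if pred.n != truth.n:
        raise ValueError(f"partition lengths differ: {pred.n} vs {truth.n}")
    if pred.n < 2:
        raise ValueError("Rand index needs at least 2 elements")
    table = _contingency(pred, truth)
    n = pred.n
    total = n * (n - 1) // 2

    def pairs(x):
        return int((x * (x - 1) // 2).sum())

    both_same = pairs(table)
    same_pred = pairs(table.sum(axis=1))
    same_truth = pairs(table.sum(axis=0))
    # concordant = co-clustered in both + separated in both
    concordant = both_same + (total - same_pred - same_truth + both_same)
    return concordant / total


def quality_index(distances, pred, normalize: bool = True) -> float:
    """Mean silhouette over all points, computed on a distance matrix.

    ``a(i)`` is the mean within-cluster distance (self excluded), ``b(i)``
    the smallest mean distance to another cluster; singleton clusters
    contribute 0.  With ``normalize`` (default) the [-1, 1] silhouette is
    mapped to [0, 1] via ``(QI + 1) / 2``.
    """
    if isinstance(distances, HeatDistanceMatrix):
        D = distances.D
    else:
        D = np.asarray(distances, dtype=float)
    pred = _as_partition(pred)
    n = pred.n
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match partition length")
    codes = pred.codes()
    k = codes.max() + 1
    if k < 2:
        raise ValueError("silhouette undefined for fewer than 2 clusters")
    sizes = np.bincount(codes, minlength=k)
    # mean distance from each point to each cluster (including its own)
    sums = np.zeros((n, k))
    for c in range(k):
        sums[:, c] = D[:, codes == c].sum(axis=1)
    s = np.zeros(n)
    for i in range(n):
        c = codes[i]
        if sizes[c] == 1:
            continue  # singleton convention: s(i) = 0
        a = sums[i, c] / (sizes[c] - 1)
        other = [sums[i, d] / sizes[d] for d in range(k) if d != c]
        b = min(other)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    qi = float(s.mean())
    return (qi + 1.0) / 2.0 if normalize else qi
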