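"""Clustering-quality metrics and small utilities.

Pair-based scores (F1, Rand index, adjusted Rand index) are computed from
the confusion counts over all unordered gene pairs; silhouette and
completeness delegate to scikit-learn. All metrics are invariant to gene
ordering and cluster relabeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import comb
from sklearn.metrics import completeness_score, silhouette_score

from .datamodel import TimeSeriesMatrix

__all__ = [
    "PairConfusion",
    "pair_confusion",
    "pair_f1",
    "rand_index",
    "adjusted_rand",
    "silhouette",
    "completeness",
    "stem_profile_count",
]


@dataclass(frozen=True)
class PairConfusion:
    """Counts over all unordered pairs of points.

    TP: same cluster in truth and prediction; FP: different in truth, same
    in prediction; FN: same in truth, different in prediction; TN: rest.
    """

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _check_labels(truth: Sequence, pred: Sequence) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth)
    p = np.asarray(pred)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("truth and pred must be equal-length 1-D label arrays")
    if t.size < 2:
        raise ValueError("need at least two points")
    return t, p


def pair_confusion(truth: Sequence, pred: Sequence) -> PairConfusion:
    """Pair confusion counts via the contingency table (no O(n^2) pair loop)."""
    t, p = _check_labels(truth, pred)
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    n = t.size
    cont = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ti, pi), 1)
    same_both = int(comb(cont, 2).sum())
    same_truth = int(comb(cont.sum(axis=1), 2).sum())
    same_pred = int(comb(cont.sum(axis=0), 2).sum())
    total = n * (n - 1) // 2
    tp = same_both
    fn = same_truth - tp
    fp = same_pred - tp
    tn = total - tp - fn - fp
    return PairConfusion(TP=tp, FP=fp, TN=tn, FN=fn)


def pair_f1(truth: Sequence, pred: Sequence) -> float:
    """Pairwise F1: harmonic mean of pair precision and recall."""
    c = pair_confusion(truth, pred)
    denom_p = c.TP + c.FP
    denom_r = c.TP + c.FN
    precision = c.TP / denom_p if denom_p else 0.0
    recall = c.TP / denom_r if denom_r else 0.0
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def rand_index(truth: Sequence, pred: Sequence) -> float:
    c = pair_confusion(truth, pred)
    return (c.TP + c.TN) / c.total


def adjusted_rand(truth: Sequence, pred: Sequence) -> float:
    """Chance-corrected Rand index under the permutation model.

    Equivalent closed form in pair counts:
    ``2 (TP*TN - FN*FP) / ((TP+FN)(FN+TN) + (TP+FP)(FP+TN))``.
    """
    c = pair_confusion(truth, pred)
    num = 2.0 * (c.TP * c.TN - c.FN * c.FP)
    den = (c.TP + c.FN) * (c.FN + c.TN) + (c.TP + c.FP) * (c.FP + c.TN)
    if den == 0:
        return 1.0  # both partitions trivial (all-same or all-singletons)
    return num / den


def silhouette(m: TimeSeriesMatrix, pred: Sequence) -> float:
    """Mean silhouette coefficient on averaged profiles (Euclidean distance).

    Singleton clusters contribute s(i) = 0.
    """
    labels = np.asarray(pred)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    x = m.averaged_values()
    if labels.size != m.n_genes:
        raise ValueError("one label per gene required")
    return float(silhouette_score(x, labels, metric="euclidean"))


def completeness(truth: Sequence, pred: Sequence) -> float:
    """Entropy-based completeness: 1 - H(pred | truth) / H(pred)
    (1.0 when H(pred) = 0). All members of a truth class falling into a
    single predicted cluster gives 1."""
    t, p = _check_labels(truth, pred)
    return float(completeness_score(t, p))


def stem_profile_count(n_timepoints: int) -> int:
    """Number of distinct up/down/flat step profiles over N time points:
    3**(N - 1) - 1 (the all-flat profile excluded)."""
    if int(n_timepoints) != n_timepoints or n_timepoints < 2:
        raise ValueError("n_timepoints must be an integer >= 2")
    return 3 ** (int(n_timepoints) - 1) - 1
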