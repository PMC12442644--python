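"""Clustering agreement metrics: ARI, NMI and per-domain Jaccard overlap.

Implemented from the contingency table with exact integer binomial
arithmetic (ARI) and natural-log entropies (NMI), so large label vectors
cannot overflow and the values are reproducible to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log

import numpy as np

__all__ = ["ContingencyTable", "contingency", "ari", "nmi", "jaccard",
           "per_domain_jaccard"]


@dataclass
class ContingencyTable:
    """Cross-tabulation of two labelings with its marginals."""

    counts: np.ndarray  # predicted clusters x truth clusters
    a: np.ndarray  # predicted-cluster sizes (row sums)
    b: np.ndarray  # truth-cluster sizes (column sums)
    n: int


def contingency(pred, truth) -> ContingencyTable:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be 1-D arrays of equal length")
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(truth, return_inverse=True)
    counts = np.zeros((pi.max() + 1, ti.max() + 1), dtype=np.int64)
    np.add.at(counts, (pi, ti), 1)
    return ContingencyTable(
        counts=counts,
        a=counts.sum(axis=1),
        b=counts.sum(axis=0),
        n=int(pred.size),
    )


def ari(pred, truth) -> float:
    """Adjusted Rand index between two partitions.

    1 iff the partitions are identical up to relabeling; ~0 for independent
    labelings. Uses exact integer binomial coefficients.
    """
    t = contingency(pred, truth)
    if t.n < 2:
        raise ValueError("need at least 2 samples")
    sum_ij = sum(comb(int(nij), 2) for nij in t.counts.ravel())
    sum_a = sum(comb(int(ai), 2) for ai in t.a)
    sum_b = sum(comb(int(bj), 2) for bj in t.b)
    total = comb(t.n, 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both partitions trivial (all singletons or a single cluster)
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy(sizes: np.ndarray, n: int) -> float:
    p = sizes[sizes > 0] / n
    return float(-(p * np.log(p)).sum())


def nmi(pred, truth) -> float:
    """Normalized mutual information 2 I(Y;C) / (H(Y) + H(C)).

    Natural-log entropies (the base cancels). Degenerate conventions: 1 if
    both partitions are single-cluster, 0 if exactly one is.
    """
    t = contingency(pred, truth)
    h_pred = _entropy(t.a, t.n)
    h_truth = _entropy(t.b, t.n)
    if h_pred == 0.0 and h_truth == 0.0:
        return 1.0
    if h_pred == 0.0 or h_truth == 0.0:
        return 0.0
    mi = 0.0
    for i in range(t.counts.shape[0]):
        for j in range(t.counts.shape[1]):
            nij = t.counts[i, j]
            if nij:
                mi += (nij / t.n) * log(t.n * nij / (t.a[i] * t.b[j]))
    return float(2.0 * mi / (h_pred + h_truth))


def jaccard(domain_pred, domain_true) -> float:
    """|intersection| / |union| of two spot sets; 0 if both are empty."""
    a, b = set(domain_pred), set(domain_true)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def per_domain_jaccard(pred, truth, spot_ids=None) -> dict:
    """Best-matching Jaccard overlap for each ground-truth domain.

    For every truth label, reports the maximum Jaccard index between its
    spot set and any predicted cluster's spot set.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    ids = np.arange(len(pred)) if spot_ids is None else np.asarray(spot_ids)
    out = {}
    pred_sets = {c: set(ids[pred == c]) for c in np.unique(pred)}
    for d in np.unique(truth):
        true_set = set(ids[truth == d])
        out[str(d)] = max(
            (jaccard(ps, true_set) for ps in pred_sets.values()), default=0.0
        )
    return out
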