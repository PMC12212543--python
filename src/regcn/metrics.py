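"""Partition-agreement metrics: ACC, NMI and ARI.

All three are computed from the contingency table N_{a,b} counting
nodes shared between ground-truth community a and predicted community
b.  ACC maximizes the fraction of correctly labeled nodes over
injective mappings of predicted onto truth labels (solved as a
maximum-weight assignment); NMI uses the arithmetic-mean entropy
normalization 2·I/(H_P + H_C); ARI is the pair-counting Rand index
adjusted for chance.  ARI can be negative for worse-than-random
agreement and is deliberately not clipped.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import linear_sum_assignment

from regcn.errors import ShapeError

logger = logging.getLogger(__name__)


def _as_codes(labels) -> np.ndarray:
    labels = np.asarray(labels).ravel()
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def contingency(truth, pred) -> np.ndarray:
    """A x K table N_{a,b} = |truth community a ∩ predicted community b|."""
    t = _as_codes(truth)
    p = _as_codes(pred)
    if t.shape[0] != p.shape[0]:
        raise ShapeError("partitions cover different node counts")
    table = np.zeros((t.max() + 1, p.max() + 1), dtype=np.int64)
    np.add.at(table, (t, p), 1)
    return table


def accuracy(truth, pred) -> float:
    """Best-mapping accuracy: fraction correct under the optimal
    injective relabeling of predicted communities."""
    table = contingency(truth, pred)
    n = table.sum()
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum() / n)


def nmi(truth, pred) -> float:
    """Normalized mutual information, arithmetic-mean normalization.

    Degenerate cases: both partitions a single cluster -> 1.0 (they are
    identical); only one single-cluster -> 0.0 (no information shared).
    """
    table = contingency(truth, pred).astype(np.float64)
    n = table.sum()
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    h_t = -np.sum(a[a > 0] / n * np.log(a[a > 0] / n))
    h_p = -np.sum(b[b > 0] / n * np.log(b[b > 0] / n))
    if h_t == 0.0 and h_p == 0.0:
        logger.debug("both partitions single-cluster; NMI defined as 1")
        return 1.0
    if h_t == 0.0 or h_p == 0.0:
        logger.debug("one partition single-cluster; NMI defined as 0")
        return 0.0
    nz = table > 0
    outer = np.outer(a, b)
    mi = np.sum(table[nz] / n * np.log(n * table[nz] / outer[nz]))
    return float(2.0 * mi / (h_t + h_p))


def ari(truth, pred) -> float:
    """Adjusted Rand index over node pairs (not clipped below 0)."""
    table = contingency(truth, pred).astype(np.float64)
    n = table.sum()
    if n < 2:
        raise ShapeError("ARI requires at least two nodes")

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ab = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both partitions trivial (all singletons or one cluster)
        return 1.0 if sum_ab == expected else 0.0
    return float((sum_ab - expected) / (max_index - expected))


def score_partition(truth, pred, as_percent: bool = False) -> dict:
    """ACC/NMI/ARI bundle; percentages when ``as_percent`` (for reports)."""
    scores = {
        "acc": accuracy(truth, pred),
        "nmi": nmi(truth, pred),
        "ari": ari(truth, pred),
    }
    if as_percent:
        scores = {k: 100.0 * v for k, v in scores.items()}
    return scores
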