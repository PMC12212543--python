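"""Pseudo-labeled set construction around the refined structure centers.

A shallow (two-layer) graph convolution propagates label information
only two hops, so training on K single centers under-supervises large
graphs.  The affinity strategy expands each community's supervision to
the tau nodes of that community whose affiliation strength is closest
to the center's own; the alternative top-k strategy takes the tau nodes
of globally largest affiliation per community.  The lower bound for tau
solves K · tau · d̄^L ≈ N, i.e. enough supervised nodes that their
L-hop neighborhoods can tile the graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from regcn.errors import ParameterError
from regcn.seeding import SeedSet

logger = logging.getLogger(__name__)


@dataclass
class PseudoLabelSet:
    """K disjoint node lists; nodes in ``sets[k]`` carry pseudo-label k+1."""

    sets: list

    def __post_init__(self) -> None:
        all_nodes = [v for s in self.sets for v in s]
        if len(set(all_nodes)) != len(all_nodes):
            raise ParameterError("pseudo-label sets must be disjoint")

    @property
    def k(self) -> int:
        return len(self.sets)

    @property
    def total(self) -> int:
        return sum(len(s) for s in self.sets)


def tau_lower_bound(n: int, k: int, mean_degree: float, layers: int = 2) -> int:
    """Smallest useful supervision size per community.

    Solves K·tau·d̄^L ≈ N for tau and rounds up, flooring at 1.  An
    edgeless graph (d̄ = 0) degenerates to tau = N.
    """
    if n < 1 or k < 1 or layers < 1:
        raise ParameterError("n, k and layers must be positive")
    if mean_degree < 0:
        raise ParameterError("mean degree must be non-negative")
    if mean_degree == 0:
        logger.warning("edgeless graph: tau lower bound degenerates to N")
        return n
    return max(1, math.ceil(n / (k * mean_degree**layers)))


def expand_affinity(
    z: np.ndarray,
    partition: np.ndarray,
    seeds: SeedSet,
    tau: int,
) -> PseudoLabelSet:
    """Select, per community, the tau members closest in affiliation to
    its center.

    For community k the candidates are the nodes the partition assigns
    to k; they are ranked by |z_{x,k} − z_{c_k,k}| ascending, ties by
    larger z_{x,k} then smaller index.  The center has difference 0 and
    maximal z among ties, so it always makes the cut; tau is clipped to
    the community size.  A center stranded outside its own community is
    force-included (and logged).
    """
    if tau < 1:
        raise ParameterError("tau must be >= 1")
    z = np.asarray(z)
    partition = np.asarray(partition)
    # centers stranded outside their own community are force-included
    # there, and withdrawn from every candidate pool
    stranded = {
        int(c) for j, c in enumerate(seeds.centers) if partition[c] != j + 1
    }
    sets = []
    for j, c in enumerate(seeds.centers):
        members = np.flatnonzero(partition == j + 1)
        members = members[~np.isin(members, list(stranded))]
        forced = []
        if int(c) in stranded:
            logger.warning(
                "center %d of community %d is outside its community; "
                "force-including it", c, j + 1,
            )
            forced = [int(c)]
        diff = np.abs(z[members, j] - z[c, j])
        order = np.lexsort((members, -z[members, j], diff))
        take = members[order[: max(0, tau - len(forced))]]
        sets.append(forced + [int(v) for v in take])
    return PseudoLabelSet(sets=sets)


def expand_topk(z: np.ndarray, tau: int) -> PseudoLabelSet:
    """Per community, the tau nodes of largest affiliation strength.

    Candidates are ranked over *all* nodes by z_{·,k} descending (ties
    toward the smaller index).  A node wanted by several communities is
    kept where its affiliation is largest (its argmax column, ties to
    the smaller community); the losers backfill from their next-ranked
    unclaimed nodes.
    """
    if tau < 1:
        raise ParameterError("tau must be >= 1")
    z = np.asarray(z)
    n, k = z.shape
    tau = min(tau, n)
    rankings = [
        np.lexsort((np.arange(n), -z[:, j])) for j in range(k)
    ]
    owner = np.full(n, -1, dtype=np.int64)

    # first pass: tentative top-tau picks; contested nodes go to their
    # argmax community
    tentative = [set(int(v) for v in rankings[j][:tau]) for j in range(k)]
    for v in range(n):
        claimants = [j for j in range(k) if v in tentative[j]]
        if not claimants:
            continue
        if len(claimants) == 1:
            owner[v] = claimants[0]
        else:
            best = max(claimants, key=lambda j: (z[v, j], -j))
            owner[v] = best

    sets = [[] for _ in range(k)]
    for v in range(n):
        if owner[v] >= 0:
            sets[owner[v]].append(v)

    # backfill communities that lost contested nodes
    cursors = [tau] * k
    for j in range(k):
        while len(sets[j]) < tau and cursors[j] < n:
            v = int(rankings[j][cursors[j]])
            cursors[j] += 1
            if owner[v] == -1:
                owner[v] = j
                sets[j].append(v)
    return PseudoLabelSet(sets=[sorted(s) for s in sets])
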