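"""Synthetic benchmarks: planted-partition graphs with block features.

The generator emulates the regime the method targets — assortative
block structure (communities denser inside than between) with
homophilous 0/1 attribute vectors, the binary bag-of-words style of
citation-network features.  The attribute space is split into K salient
groups; a node's own block's coordinates fire with probability
``attr_on_in`` and the rest with ``attr_on_out``, so the attribute
signal strength is controlled by the gap between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from regcn.errors import ParameterError
from regcn.graph_core import Network


@dataclass
class SBMSpec:
    """Planted-partition specification.

    ``block_sizes`` lists the K community sizes; ``p_in``/``p_out`` are
    the within/between-block edge probabilities; ``attr_dim`` binary
    attributes (0 disables features) fire at rate ``attr_on_in`` on the
    node's own salient group and ``attr_on_out`` elsewhere.
    """

    block_sizes: tuple = (50, 50, 50)
    p_in: float = 0.25
    p_out: float = 0.02
    attr_dim: int = 60
    attr_on_in: float = 0.3
    attr_on_out: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_sizes) < 1 or any(s < 1 for s in self.block_sizes):
            raise ParameterError("block sizes must be positive")
        for p in (self.p_in, self.p_out, self.attr_on_in, self.attr_on_out):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"probability {p} outside [0, 1]")
        if not self.p_out < self.p_in:
            raise ParameterError("require p_out < p_in (assortative blocks)")
        if self.attr_dim < 0:
            raise ParameterError("attr_dim must be >= 0")

    @property
    def n_nodes(self) -> int:
        return int(sum(self.block_sizes))

    @property
    def k(self) -> int:
        return len(self.block_sizes)


def generate_sbm(spec: SBMSpec) -> Network:
    """Draw a planted-partition graph with block-correlated attributes.

    Edges are independent Bernoulli draws on the upper triangle with
    probability ``p_in`` inside blocks and ``p_out`` between them.
    Truth labels are the block ids (1..K).  Reproducible for a fixed
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    blocks = np.repeat(np.arange(spec.k), spec.block_sizes)

    same = blocks[:, None] == blocks[None, :]
    p = np.where(same, spec.p_in, spec.p_out)
    draw = rng.random((n, n))
    upper = np.triu(draw < p, k=1)
    A = (upper | upper.T).astype(np.float64)

    X = None
    if spec.attr_dim > 0:
        # split the attribute space into K near-equal salient groups
        group_sizes = np.full(spec.k, spec.attr_dim // spec.k)
        group_sizes[: spec.attr_dim % spec.k] += 1
        attr_group = np.repeat(np.arange(spec.k), group_sizes)
        salient = blocks[:, None] == attr_group[None, :]
        p_attr = np.where(salient, spec.attr_on_in, spec.attr_on_out)
        X = (rng.random((n, spec.attr_dim)) < p_attr).astype(np.float64)

    return Network(
        node_ids=list(range(n)),
        adjacency=A,
        features=X,
        truth_labels=blocks + 1,
    )


def easy_sbm_spec(seed: int = 0) -> SBMSpec:
    """Strongly separable benchmark: 3 blocks of 50, p_in 0.25,
    p_out 0.02, informative attributes."""
    return SBMSpec(seed=seed)


def hard_sbm_spec(seed: int = 0) -> SBMSpec:
    """Weakly separable benchmark: 3 blocks of 50, p_in 0.12,
    p_out 0.04, weak attributes."""
    return SBMSpec(
        block_sizes=(50, 50, 50),
        p_in=0.12,
        p_out=0.04,
        attr_dim=60,
        attr_on_in=0.15,
        attr_on_out=0.10,
        seed=seed,
    )


def sparse_sbm_spec(seed: int = 0) -> SBMSpec:
    """Sparse separable benchmark where the tau lower bound exceeds 1.

    Three blocks of 100 at p_in 0.045 / p_out 0.005 give a mean degree
    around 5.5, so K·d̄² < N and expanding the pseudo-labeled set is
    actually required to tile the graph with 2-hop neighborhoods.
    """
    return SBMSpec(
        block_sizes=(100, 100, 100),
        p_in=0.045,
        p_out=0.005,
        attr_dim=60,
        attr_on_in=0.2,
        attr_on_out=0.08,
        seed=seed,
    )


def toy_three_communities() -> Network:
    """Deterministic 24-node graph: three 8-cliques joined by bridges.

    Nodes 0-7, 8-15 and 16-23 each form a clique; single bridge edges
    (0, 8), (8, 16) and (16, 0) join the cliques through one hub node
    each, so every clique has a unique local density peak.  Truth
    labels are the clique ids.  Used as a small, fully understood
    instance for seeding and refinement behavior.
    """
    n = 24
    A = np.zeros((n, n))
    for start in (0, 8, 16):
        for i in range(start, start + 8):
            for j in range(i + 1, start + 8):
                A[i, j] = A[j, i] = 1.0
    for u, v in ((0, 8), (8, 16), (16, 0)):
        A[u, v] = A[v, u] = 1.0
    labels = np.repeat([1, 2, 3], 8)
    return Network(node_ids=list(range(n)), adjacency=A, truth_labels=labels)
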