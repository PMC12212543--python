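"""Density-peak seeding: structural centrality and initial center choice.

Each node gets a local density rho (how many nodes lie within the
cutoff distance d_c), a relative distance delta (hop distance to the
nearest node of strictly higher density) and a structural centrality
phi = rho * delta.  Only density peaks — locally dense nodes far from
any denser node — obtain a large phi, so the K nodes of largest phi
serve as one structure center per community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from regcn.errors import ParameterError, ShapeError

logger = logging.getLogger(__name__)


@dataclass
class CentralityProfile:
    """Per-node density-peak quantities: rho, delta and phi = rho*delta."""

    rho: np.ndarray
    delta: np.ndarray
    phi: np.ndarray


@dataclass
class SeedSet:
    """Ordered structure centers; position k carries pseudo-label k+1.

    ``centers`` holds internal node indices (0-based); ``round`` is the
    refinement iteration that produced them (0 = initial selection).
    """

    centers: list
    round: int = 0

    def __post_init__(self) -> None:
        # duplicates only arise through the empty-community fallback of
        # refinement; the run continues but the state is degenerate
        if len(set(self.centers)) != len(self.centers):
            logger.warning("structure centers are not all distinct: %s", self.centers)

    @property
    def k(self) -> int:
        return len(self.centers)


def local_density(distances: np.ndarray, d_c: int = 1) -> np.ndarray:
    """Number of *other* nodes within d_c hops of each node.

    With d_c = 1 this is exactly the degree sequence.  The node itself
    (distance 0) is excluded from the count.
    """
    if d_c < 1:
        raise ParameterError(f"cutoff distance d_c must be >= 1, got {d_c}")
    D = np.asarray(distances)
    within = (D <= d_c)
    np.fill_diagonal(within, False)
    return within.sum(axis=1).astype(np.int64)


def _density_order(rho: np.ndarray) -> np.ndarray:
    """Strict total order on nodes: descending rho, ascending index.

    Returns node indices from densest to sparsest.  The strict order
    ensures exactly one node (the first) takes the max-distance rule
    for delta even when densities tie.
    """
    n = rho.shape[0]
    return np.lexsort((np.arange(n), -rho))


def relative_distance(distances: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Hop distance from each node to the nearest effectively-denser node.

    A node j is effectively denser than i when rho_j > rho_i, with ties
    broken by smaller index so the order is total.  The single top node
    instead receives the maximum of its distance row.
    """
    D = np.asarray(distances)
    rho = np.asarray(rho)
    if D.shape[0] != rho.shape[0]:
        raise ShapeError("distance matrix and rho disagree on N")
    n = rho.shape[0]
    order = _density_order(rho)
    delta = np.empty(n, dtype=np.int64)
    top = order[0]
    delta[top] = D[top].max() if n > 1 else 0
    # prefix of `order` before position p = all nodes denser than order[p]
    for p in range(1, n):
        i = order[p]
        delta[i] = D[i, order[:p]].min()
    return delta


def structural_centrality(rho: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Elementwise product phi = rho * delta."""
    rho = np.asarray(rho)
    delta = np.asarray(delta)
    if rho.shape != delta.shape:
        raise ShapeError("rho and delta must have equal length")
    return (rho * delta).astype(np.float64)


def centrality_profile(distances: np.ndarray, d_c: int = 1) -> CentralityProfile:
    """Compute rho, delta and phi in one pass from a distance matrix."""
    rho = local_density(distances, d_c)
    delta = relative_distance(distances, rho)
    return CentralityProfile(rho=rho, delta=delta, phi=structural_centrality(rho, delta))


def select_initial_centers(phi: np.ndarray, k: int) -> SeedSet:
    """Pick the K nodes of largest structural centrality as seeds.

    Ties break toward the smaller node index; the returned centers are
    ordered by descending phi, and position k carries pseudo-label k+1.
    """
    phi = np.asarray(phi)
    n = phi.shape[0]
    if not 1 <= k <= n:
        raise ParameterError(f"K must be in [1, {n}], got {k}")
    order = np.lexsort((np.arange(n), -phi))
    return SeedSet(centers=[int(i) for i in order[:k]], round=0)
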