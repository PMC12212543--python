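"""Graph, attribute and label I/O plus basic matrix machinery.

A :class:`Network` holds the undirected simple graph as a dense 0/1
adjacency matrix with zero diagonal, an optional non-negative node
feature matrix (rows in graph node order) and optional ground-truth
community labels.  All downstream stages (seeding, GCN training,
refinement, expansion) consume the derived quantities computed here:
the symmetrically normalized adjacency with self-connections
``Â = D̃^{-1/2}(A+I)D̃^{-1/2}`` and the all-pairs hop-distance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from regcn.errors import InputError, ParameterError, ParseError, ShapeError

logger = logging.getLogger(__name__)


@dataclass
class Network:
    """An undirected simple graph with optional attributes and labels.

    Attributes
    ----------
    node_ids:
        Original node identifiers, in the order used by every matrix.
    adjacency:
        N x N symmetric 0/1 matrix, zero diagonal.
    features:
        Optional N x F non-negative feature matrix, or ``None``.
    truth_labels:
        Optional length-N integer array of ground-truth communities.
    """

    node_ids: list
    adjacency: np.ndarray
    features: Optional[np.ndarray] = None
    truth_labels: Optional[np.ndarray] = None
    index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ShapeError(f"adjacency must be square, got {A.shape}")
        if A.shape[0] != len(self.node_ids):
            raise ShapeError(
                f"{len(self.node_ids)} node ids but adjacency is {A.shape}"
            )
        if not np.array_equal(A, A.T):
            raise ShapeError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ShapeError("adjacency diagonal must be zero")
        self.adjacency = A.astype(np.float64)
        if self.features is not None:
            X = np.asarray(self.features, dtype=np.float64)
            if X.shape[0] != self.n_nodes:
                raise ShapeError(
                    f"feature rows ({X.shape[0]}) != number of nodes "
                    f"({self.n_nodes})"
                )
            self.features = X
        if self.truth_labels is not None:
            y = np.asarray(self.truth_labels)
            if y.shape[0] != self.n_nodes:
                raise ShapeError("truth label count != number of nodes")
            self.truth_labels = y.astype(np.int64)
        self.index = {v: i for i, v in enumerate(self.node_ids)}
        iso = int(np.sum(self.adjacency.sum(axis=1) == 0))
        if iso:
            logger.warning("network contains %d isolated node(s)", iso)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def mean_degree(self) -> float:
        if self.n_nodes == 0:
            return 0.0
        return float(self.adjacency.sum() / self.n_nodes)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)


def read_edge_list(path, id_policy: str = "as-given") -> Network:
    """Read an undirected graph from a whitespace/TSV edge list.

    Lines starting with ``#`` are ignored.  Duplicate edges are
    collapsed, self-loops dropped (with a logged count) and directed
    inputs symmetrized: an edge exists if it is listed in either
    direction.

    Parameters
    ----------
    path:
        Edge-list file; each data line ``src dst`` (extra tokens ignored).
    id_policy:
        ``"as-given"`` keeps first-appearance node order, ``"reindex"``
        sorts node identifiers (numerically when all are integral).
    """
    if id_policy not in ("as-given", "reindex"):
        raise ParameterError(f"unknown id_policy {id_policy!r}")
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read edge list {path}: {exc}") from exc

    order: list = []
    seen: set = set()
    edges: set = set()
    self_loops = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(
                f"{path}:{lineno}: expected two tokens, got {len(tokens)}"
            )
        u, v = tokens[0], tokens[1]
        for w in (u, v):
            if w not in seen:
                seen.add(w)
                order.append(w)
        if u == v:
            self_loops += 1
            continue
        edges.add((u, v) if u <= v else (v, u))
    if not order:
        raise InputError(f"{path}: no edges or nodes found")
    if self_loops:
        logger.info("dropped %d self-loop(s) while reading %s", self_loops, path)

    if id_policy == "reindex":
        try:
            order = sorted(order, key=lambda t: (0, int(t)))
        except ValueError:
            order = sorted(order)
    idx = {v: i for i, v in enumerate(order)}
    A = np.zeros((len(order), len(order)))
    for u, v in edges:
        A[idx[u], idx[v]] = 1.0
        A[idx[v], idx[u]] = 1.0
    return Network(node_ids=order, adjacency=A)


def read_graph(path, id_policy: str = "as-given") -> Network:
    """Read a graph from an edge list, GML or GraphML file.

    Dispatches on the file suffix; anything that is not ``.gml`` /
    ``.graphml`` is treated as an edge list.  Directed graphs are
    symmetrized and self-loops dropped, as in :func:`read_edge_list`.
    """
    suffix = Path(path).suffix.lower()
    if suffix not in (".gml", ".graphml"):
        return read_edge_list(path, id_policy=id_policy)
    import networkx as nx

    try:
        if suffix == ".gml":
            g = nx.read_gml(path, label="id")
        else:
            g = nx.read_graphml(path)
    except Exception as exc:  # networkx raises many concrete types
        raise InputError(f"cannot read graph {path}: {exc}") from exc
    g = nx.Graph(g)  # symmetrize / collapse multiedges
    g.remove_edges_from(nx.selfloop_edges(g))
    order = list(g.nodes())
    if id_policy == "reindex":
        try:
            order = sorted(order, key=lambda t: (0, int(t)))
        except (ValueError, TypeError):
            order = sorted(order, key=str)
    A = nx.to_numpy_array(g, nodelist=order, dtype=np.float64)
    A[A > 0] = 1.0
    return Network(node_ids=order, adjacency=A)


def read_attributes(path, network: Network) -> Network:
    """Attach a node attribute matrix read from TSV or MatrixMarket.

    Dense TSV files must have one row per node in graph node order;
    MatrixMarket coordinate files must declare N rows.  Returns a new
    :class:`Network` sharing the graph with features attached.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".mtx", ".mm"):
            X = np.asarray(scipy.io.mmread(path).todense(), dtype=np.float64)
        else:
            X = np.loadtxt(path, dtype=np.float64, ndmin=2)
    except OSError as exc:
        raise InputError(f"cannot read attributes {path}: {exc}") from exc
    if X.shape[0] != network.n_nodes:
        raise ShapeError(
            f"attribute matrix has {X.shape[0]} rows, expected "
            f"{network.n_nodes}"
        )
    zero_rows = int(np.sum(~X.any(axis=1)))
    if zero_rows:
        logger.warning("%d node(s) have all-zero attribute rows", zero_rows)
    return Network(
        node_ids=network.node_ids,
        adjacency=network.adjacency,
        features=X,
        truth_labels=network.truth_labels,
    )


def write_attributes(path, X: np.ndarray) -> None:
    """Write a dense attribute matrix as TSV (one row per node)."""
    np.savetxt(path, np.asarray(X), fmt="%.10g", delimiter="\t")


def read_labels(path, network: Network) -> Network:
    """Attach ground-truth labels from a ``node_id<TAB>label`` TSV."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read labels {path}: {exc}") from exc
    raw: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'node label'")
        raw[tokens[0]] = tokens[1]
    missing = [v for v in network.node_ids if str(v) not in raw]
    if missing:
        raise InputError(
            f"{path}: no label for {len(missing)} node(s), e.g. {missing[0]!r}"
        )
    values = [raw[str(v)] for v in network.node_ids]
    distinct = {lab: k for k, lab in enumerate(sorted(set(values)), start=1)}
    y = np.array([distinct[lab] for lab in values], dtype=np.int64)
    return Network(
        node_ids=network.node_ids,
        adjacency=network.adjacency,
        features=network.features,
        truth_labels=y,
    )


def write_membership(path, network: Network, assignment: Sequence[int]) -> None:
    """Write a ``node_id<TAB>community`` TSV (communities 1..K)."""
    assignment = np.asarray(assignment)
    if assignment.shape[0] != network.n_nodes:
        raise ShapeError("assignment length != number of nodes")
    with open(path, "w") as fh:
        for v, k in zip(network.node_ids, assignment):
            fh.write(f"{v}\t{int(k)}\n")


def one_hot_features(network: Network) -> Network:
    """Fall back to one-hot node features for non-attributed graphs.

    Row i of the resulting N x N feature matrix has a single 1 at
    column i, so the first graph convolution reads the structure alone.
    """
    if network.features is not None:
        raise ParameterError("network already carries an attribute matrix")
    return Network(
        node_ids=network.node_ids,
        adjacency=network.adjacency,
        features=np.eye(network.n_nodes),
        truth_labels=network.truth_labels,
    )


def normalize_adjacency(network: Network) -> np.ndarray:
    """Symmetrically normalized adjacency with self-connections.

    Computes ``Â = D̃^{-1/2} (A + I) D̃^{-1/2}`` with
    ``D̃_ii = Σ_j (A + I)_ij``.  An isolated node has D̃_ii = 1, so the
    result is always well defined and its diagonal strictly positive.
    """
    A_tilde = network.adjacency + np.eye(network.n_nodes)
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def shortest_path_distances(network: Network) -> np.ndarray:
    """All-pairs hop distances; disconnected pairs get sentinel N.

    Hop counts come from breadth-first traversal on the unweighted
    graph.  The sentinel N exceeds any achievable hop distance (max
    N-1), keeping the relative-distance computation finite and maximal
    across components.
    """
    n = network.n_nodes
    D = _csgraph_shortest_path(
        sp.csr_matrix(network.adjacency), method="D", unweighted=True
    )
    D[np.isinf(D)] = n
    return D.astype(np.int64)
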