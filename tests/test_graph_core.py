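import numpy as np
import pytest

from regcn.errors import InputError, ParseError, ShapeError
from regcn.graph_core import (
    Network,
    normalize_adjacency,
    one_hot_features,
    read_attributes,
    read_edge_list,
    read_graph,
    read_labels,
    shortest_path_distances,
    write_attributes,
    write_membership,
)

from conftest import network_from_adjacency, path_graph, random_adjacency


class TestReadEdgeList:
    def test_basic_parse(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text("a\tb\nb\tc\n")
        net = read_edge_list(f)
        assert net.node_ids == ["a", "b", "c"]
        assert net.n_edges == 2
        assert net.adjacency[0, 1] == 1 and net.adjacency[0, 2] == 0

    def test_dedupe_selfloops_and_symmetrize(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text("a b\nb a\na a\n")
        net = read_edge_list(f)
        assert net.n_nodes == 2
        assert net.n_edges == 1
        assert np.all(np.diag(net.adjacency) == 0)

    def test_comments_and_reindex(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text("# header\n10 2\n2 1\n")
        net = read_edge_list(f, id_policy="reindex")
        assert net.node_ids == ["1", "2", "10"]

    def test_random_file_matches_set_oracle(self, tmp_path, rng):
        nodes = [f"n{i}" for i in range(20)]
        lines, oracle = [], set()
        for _ in range(100):
            u, v = rng.choice(nodes, size=2, replace=True)
            lines.append(f"{u}\t{v}")
            if u != v:
                oracle.add(frozenset((u, v)))
        f = tmp_path / "g.tsv"
        f.write_text("\n".join(lines) + "\n")
        net = read_edge_list(f)
        got = {
            frozenset((net.node_ids[i], net.node_ids[j]))
            for i, j in zip(*np.nonzero(np.triu(net.adjacency)))
        }
        assert got == oracle

    def test_symmetrization_idempotent(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text("a b\nb c\nc a\n")
        first = read_edge_list(f)
        g = tmp_path / "g2.tsv"
        with open(g, "w") as fh:
            for i, j in zip(*np.nonzero(np.triu(first.adjacency))):
                fh.write(f"{first.node_ids[i]}\t{first.node_ids[j]}\n")
        second = read_edge_list(g)
        assert np.array_equal(first.adjacency, second.adjacency)

    def test_errors(self, tmp_path):
        with pytest.raises(InputError):
            read_edge_list(tmp_path / "missing.tsv")
        f = tmp_path / "bad.tsv"
        f.write_text("a b\nlonely\n")
        with pytest.raises(ParseError, match="2"):
            read_edge_list(f)


class TestGraphFormats:
    def test_graphml_round(self, tmp_path):
        import networkx as nx

        g = nx.path_graph(4)
        p = tmp_path / "g.graphml"
        nx.write_graphml(g, p)
        net = read_graph(p)
        assert net.n_nodes == 4 and net.n_edges == 3

    def test_gml_directed_symmetrized(self, tmp_path):
        import networkx as nx

        g = nx.DiGraph([(0, 1), (1, 0), (1, 2)])
        p = tmp_path / "g.gml"
        nx.write_gml(g, p)
        net = read_graph(p)
        assert net.n_edges == 2
        assert np.array_equal(net.adjacency, net.adjacency.T)


class TestAttributes:
    def test_dense_tsv(self, tmp_path):
        net = path_graph(3)
        f = tmp_path / "x.tsv"
        f.write_text("0\t0\n0\t0\n0\t0\n")
        net2 = read_attributes(f, net)
        assert net2.features.shape == (3, 2)

    def test_matrix_market(self, tmp_path):
        import scipy.io
        import scipy.sparse as sp

        net = path_graph(3)
        X = sp.coo_matrix(([1.0, 2.0, 3.0], ([0, 1, 2], [0, 1, 0])), shape=(3, 2))
        f = tmp_path / "x.mtx"
        scipy.io.mmwrite(f, X)
        net2 = read_attributes(f, net)
        assert net2.features[1, 1] == 2.0 and net2.features[2, 0] == 3.0

    def test_round_trip(self, tmp_path, rng):
        net = network_from_adjacency(random_adjacency(rng, 10))
        X = rng.random((10, 5))
        f = tmp_path / "x.tsv"
        write_attributes(f, X)
        net2 = read_attributes(f, net)
        assert np.allclose(net2.features, X, atol=0, rtol=1e-9)

    def test_row_mismatch(self, tmp_path):
        net = path_graph(3)
        f = tmp_path / "x.tsv"
        f.write_text("0\t0\n0\t0\n")
        with pytest.raises(ShapeError, match="3"):
            read_attributes(f, net)


class TestLabelsAndMembership:
    def test_labels_attach(self, tmp_path):
        net = path_graph(3)
        f = tmp_path / "y.tsv"
        f.write_text("0\tx\n1\tx\n2\ty\n")
        net2 = read_labels(f, net)
        assert list(net2.truth_labels) == [1, 1, 2]

    def test_membership_write(self, tmp_path):
        net = path_graph(3)
        out = tmp_path / "m.tsv"
        write_membership(out, net, [1, 1, 2])
        assert out.read_text() == "0\t1\n1\t1\n2\t2\n"


class TestOneHot:
    def test_identity_pattern(self):
        net = one_hot_features(path_graph(3))
        assert np.array_equal(net.features, np.eye(3))
        assert np.array_equal(net.features.sum(axis=0), np.ones(3))

    def test_single_node(self):
        net = one_hot_features(network_from_adjacency(np.zeros((1, 1))))
        assert net.features.tolist() == [[1.0]]


class TestNormalizeAdjacency:
    def test_single_node(self):
        a_hat = normalize_adjacency(network_from_adjacency(np.zeros((1, 1))))
        assert np.allclose(a_hat, [[1.0]])

    def test_two_connected_nodes(self):
        a_hat = normalize_adjacency(path_graph(2))
        assert np.allclose(a_hat, 0.5 * np.ones((2, 2)))

    def test_matches_dense_oracle(self, rng):
        A = random_adjacency(rng, 15)
        a_hat = normalize_adjacency(network_from_adjacency(A))
        A_t = A + np.eye(15)
        D = np.diag(1.0 / np.sqrt(A_t.sum(axis=1)))
        assert np.allclose(a_hat, D @ A_t @ D, atol=1e-12)
        assert np.allclose(a_hat, a_hat.T, atol=1e-12)
        assert np.all(np.diag(a_hat) > 0)


class TestDistances:
    def test_path_hops(self):
        D = shortest_path_distances(path_graph(3))
        assert D[0, 2] == 2 and D[0, 0] == 0

    def test_disconnected_sentinel(self):
        D = shortest_path_distances(network_from_adjacency(np.zeros((2, 2))))
        assert D[0, 1] == 2

    def test_matches_bfs_oracle(self, rng):
        from collections import deque

        A = random_adjacency(rng, 12, p=0.2)
        net = network_from_adjacency(A)
        D = shortest_path_distances(net)

        def bfs(src):
            dist = {src: 0}
            q = deque([src])
            while q:
                u = q.popleft()
                for v in np.nonzero(A[u])[0]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        q.append(v)
            return dist

        for i in range(12):
            d = bfs(i)
            for j in range(12):
                assert D[i, j] == d.get(j, 12)
        assert np.array_equal(D, D.T)
        finite = D[D < 12]
        assert np.all(finite <= 11)


class TestNetworkValidation:
    def test_asymmetric_rejected(self):
        A = np.zeros((2, 2))
        A[0, 1] = 1
        with pytest.raises(ShapeError):
            Network(node_ids=[0, 1], adjacency=A)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ShapeError):
            Network(node_ids=[0], adjacency=np.ones((1, 1)))
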