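"""PCIT: partial correlations, the trio-tolerance scan, GCN construction."""

import math

import networkx as nx
import numpy as np
import pytest

from fibreggp import (
    CorrelationMatrix,
    build_gcn,
    first_order_partial,
    pcit_significant_edges,
    pearson_correlations,
)
from fibreggp.simulate import ExpressionMatrix


def pcit_bruteforce(c):
    """Literal triple loop over every pair and every conditioning gene."""
    c = np.asarray(c, dtype=float)
    n = c.shape[0]
    keep = (c != 0.0) & ~np.eye(n, dtype=bool)
    for x in range(n):
        for y in range(x + 1, n):
            if c[x, y] == 0:
                continue
            for z in range(n):
                if z in (x, y):
                    continue
                rxy, rxz, ryz = c[x, y], c[x, z], c[y, z]
                if any(r == 0 or abs(r) >= 1 for r in (rxy, rxz, ryz)):
                    continue  # degenerate trio: skipped
                pxy = (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))
                pxz = (rxz - rxy * ryz) / math.sqrt((1 - rxy**2) * (1 - ryz**2))
                pyz = (ryz - rxy * rxz) / math.sqrt((1 - rxy**2) * (1 - rxz**2))
                eps = (pxy / rxy + pxz / rxz + pyz / ryz) / 3.0
                if abs(rxy) <= abs(eps * rxz) and abs(rxy) <= abs(eps * ryz):
                    keep[x, y] = keep[y, x] = False
                    break
    return keep


def random_correlation(n, rng):
    data = rng.normal(size=(n, n + 4))
    c = np.corrcoef(data)
    np.fill_diagonal(c, 1.0)
    return (c + c.T) / 2.0


def make_expr(values, gene_ids=None):
    values = np.asarray(values)
    g, s = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    return ExpressionMatrix(gene_ids, [f"7DPA_r{j + 1}" for j in range(s)],
                            np.repeat(7, s), np.arange(1, s + 1), values)


class TestCorrelations:
    def test_duplicated_genes_fully_correlated(self):
        rng = np.random.default_rng(0)
        row = rng.poisson(100, size=6)
        expr = make_expr(np.vstack([row, row, rng.poisson(100, size=6)]))
        corr = pearson_correlations(expr, transform="none")
        assert corr.matrix[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        expr = make_expr(np.vstack([a, a[::-1], a**2]).astype(int))
        corr = pearson_correlations(expr, transform="none")
        assert corr.matrix[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        vals = rng.poisson(80, size=(5, 6))
        corr = pearson_correlations(make_expr(vals), transform="none")
        v = vals.astype(float)
        for i in range(5):
            for j in range(5):
                xi, xj = v[i] - v[i].mean(), v[j] - v[j].mean()
                r = (xi @ xj) / math.sqrt((xi @ xi) * (xj @ xj))
                assert corr.matrix[i, j] == pytest.approx(r, abs=1e-12)

    def test_too_few_samples_rejected(self):
        expr = make_expr(np.ones((3, 4), dtype=int))
        with pytest.raises(ValueError):
            pearson_correlations(expr, sample_subset=np.array([0, 1]))


class TestFirstOrderPartial:
    def test_hand_worked_value(self):
        assert first_order_partial(0.9, 0.8, 0.72) == pytest.approx(0.778, abs=1e-3)

    def test_no_conditioning_effect(self):
        assert first_order_partial(0.63, 0.0, 0.0) == pytest.approx(0.63)

    def test_perfect_mediation(self):
        assert first_order_partial(0.4 * 0.5, 0.4, 0.5) == pytest.approx(0.0)

    def test_degenerate_denominator_flagged(self):
        with pytest.raises(ValueError):
            first_order_partial(0.5, 1.0, 0.5)


class TestTrioScan:
    def test_worked_trio_discards_weak_indirect_edge(self):
        c = np.array([[1.0, 0.25, 0.5],
                      [0.25, 1.0, 0.5],
                      [0.5, 0.5, 1.0]])
        net = pcit_significant_edges(CorrelationMatrix(["x", "y", "z"], c))
        assert not net.adjacency[0, 1]          # x-y mediated by z
        assert net.adjacency[0, 2] and net.adjacency[1, 2]
        assert net.n_edges == 2

    def test_two_genes_no_trio_edge_retained(self):
        c = np.array([[1.0, 0.9], [0.9, 1.0]])
        net = pcit_significant_edges(CorrelationMatrix(["a", "b"], c))
        assert net.n_edges == 1 and net.weights[0, 1] == pytest.approx(0.9)

    @pytest.mark.parametrize("n", [3, 5, 8, 12])
    def test_matches_bruteforce_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(25):
            c = random_correlation(n, rng)
            ids = [f"g{i}" for i in range(n)]
            fast = pcit_significant_edges(CorrelationMatrix(ids, c)).adjacency
            assert np.array_equal(fast, pcit_bruteforce(c))

    def test_gene_permutation_only_permutes_edges(self):
        rng = np.random.default_rng(17)
        c = random_correlation(9, rng)
        ids = [f"g{i}" for i in range(9)]
        base = pcit_significant_edges(CorrelationMatrix(ids, c)).adjacency
        perm = rng.permutation(9)
        permuted = pcit_significant_edges(
            CorrelationMatrix([ids[i] for i in perm], c[np.ix_(perm, perm)])).adjacency
        assert np.array_equal(permuted, base[np.ix_(perm, perm)])

    def test_retained_edges_subset_of_nonzero(self):
        rng = np.random.default_rng(23)
        c = random_correlation(10, rng)
        net = pcit_significant_edges(CorrelationMatrix([f"g{i}" for i in range(10)], c))
        assert not (net.adjacency & (c == 0)).any()
        assert np.array_equal(net.adjacency, net.adjacency.T)

    def test_independent_genes_yield_sparser_network_with_more_samples(self):
        densities = []
        for n_samples in (10, 60):
            dens = []
            for seed in range(8):
                rng = np.random.default_rng(seed)
                data = rng.normal(size=(15, n_samples))
                c = np.corrcoef(data)
                np.fill_diagonal(c, 1.0)
                net = pcit_significant_edges(
                    CorrelationMatrix([f"g{i}" for i in range(15)], (c + c.T) / 2))
                dens.append(net.n_edges / (15 * 14 / 2))
            densities.append(np.mean(dens))
        assert densities[1] <= densities[0]

    def test_invalid_matrix_rejected(self):
        bad = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ValueError):
            CorrelationMatrix(["a", "b"], bad)
        with pytest.raises(ValueError):
            CorrelationMatrix(["a", "b"], np.array([[0.5, 0.2], [0.2, 0.5]]))


class TestBuildGcn:
    def test_empty_adjacency_keeps_all_nodes(self):
        from fibreggp.pcit import CoexpressionNetwork
        net = CoexpressionNetwork(["a", "b", "c"], np.zeros((3, 3), bool),
                                  np.zeros((3, 3)))
        g = build_gcn(net)
        assert set(g.nodes) == {"a", "b", "c"} and g.number_of_edges() == 0

    def test_worked_trio_gives_path_graph(self):
        c = np.array([[1.0, 0.25, 0.5], [0.25, 1.0, 0.5], [0.5, 0.5, 1.0]])
        g = build_gcn(pcit_significant_edges(CorrelationMatrix(["x", "y", "z"], c)))
        assert nx.is_isomorphic(g, nx.path_graph(3))
        assert set(g["z"]) == {"x", "y"}

    def test_edge_list_round_trip(self):
        rng = np.random.default_rng(5)
        c = random_correlation(8, rng)
        net = pcit_significant_edges(CorrelationMatrix([f"g{i}" for i in range(8)], c))
        g = build_gcn(net)
        rebuilt = nx.Graph()
        rebuilt.add_nodes_from(net.gene_ids)
        rebuilt.add_weighted_edges_from(net.edge_list())
        assert nx.utils.graphs_equal(g, rebuilt)
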