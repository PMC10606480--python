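"""Similarity indices: worked examples, series/enumeration oracles, invariants."""

from __future__ import annotations

import numpy as np
import pytest

import hemlink as hl
from hemlink import Graph, IndexConfig
from hemlink.errors import ConfigurationError, ConvergenceError, WalkOverflowError
from hemlink.indices import WalkCache, score_matrix, spectral_radius

from .conftest import count_walks, random_simple_graph


def one_score(ps):
    assert ps.scores.shape == (1,)
    return float(ps.scores[0])


class TestLocalIndices:
    @pytest.mark.parametrize(
        "name,expected",
        [("cn", 1.0), ("salton", 0.5), ("ra", 0.5), ("pa", 4.0), ("ch", 1.0)],
    )
    def test_triangle_pair(self, triangle, name, expected):
        assert one_score(hl.local_score(triangle, [(0, 1)], name)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "name,expected",
        [("cn", 1.0), ("salton", 1.0), ("ra", 0.5), ("pa", 1.0), ("ch", 1.0)],
    )
    def test_path_endpoints(self, path3, name, expected):
        assert one_score(hl.local_score(path3, [(0, 2)], name)) == pytest.approx(expected)

    def test_ch_worked_example(self, ch_example):
        # z1 (node 2): kzi=1 (z2), kze=1 (w) -> 2/2; z2 (node 3): kzi=1, kze=0 -> 2/1.
        assert one_score(hl.local_score(ch_example, [(0, 1)], "ch")) == pytest.approx(3.0)

    def test_ch_matches_brute_force_definition(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            g = random_simple_graph(rng, 12, 0.3)
            S = score_matrix(g, IndexConfig("ch"))
            for x in range(g.n_nodes):
                for y in range(x + 1, g.n_nodes):
                    common = g.neighbors(x) & g.neighbors(y)
                    expected = 0.0
                    for z in common:
                        inside = {x, y} | common
                        kzi = sum(1 for u in g.neighbors(z) if u in common)
                        kze = sum(1 for u in g.neighbors(z) if u not in inside)
                        expected += (1 + kzi) / (1 + kze)
                    assert S[x, y] == pytest.approx(expected)

    def test_salton_zero_degree_scores_zero(self):
        g = Graph(3, [(0, 1)])  # node 2 isolated
        assert one_score(hl.local_score(g, [(0, 2)], "salton")) == 0.0

    def test_unknown_name_rejected(self, triangle):
        with pytest.raises(ConfigurationError):
            hl.local_score(triangle, [(0, 1)], "jaccard")


class TestDegreeIndices:
    def test_reg_values(self, path4):
        # degrees: k0=1, k1=2, k2=2, k3=1
        assert one_score(hl.reg_score(path4, [(1, 2)])) == pytest.approx(1 / 4)
        assert one_score(hl.reg_score(path4, [(0, 3)])) == pytest.approx(1.0)

    def test_reg_zero_degree_clamp(self):
        g = Graph(6, [(0, 1), (0, 2), (0, 3), (0, 4)])  # node 5 isolated, k0=4... use leaf
        # hub degree 4, isolated node clamped to 1 -> 1/4
        assert one_score(hl.reg_score(g, [(0, 5)])) == pytest.approx(1 / 4)

    def test_reg_constant_on_regular_graph(self):
        g = hl.random_regular(30, 4, seed=2)
        ps = hl.reg_score(g, [(i, j) for i in range(10) for j in range(i + 1, 10)])
        assert np.allclose(ps.scores, 1 / 16)

    def test_dfpa_values(self, star5):
        assert one_score(hl.dfpa_score(star5, [(0, 1)])) == pytest.approx(4.0)
        assert one_score(hl.dfpa_score(star5, [(1, 2)])) == pytest.approx(1.0)

    def test_dfpa_equal_degrees_floor(self, triangle):
        assert one_score(hl.dfpa_score(triangle, [(0, 1)])) == pytest.approx(1.0)

    def test_dfpa_ratio(self):
        g = Graph(12, [(0, i) for i in range(1, 9)] + [(9, 10), (9, 11), (10, 11)])
        # k0=8 vs k9=2 -> 4
        assert one_score(hl.dfpa_score(g, [(0, 9)])) == pytest.approx(4.0)


class TestWalkCounts:
    def test_branch_graph_walks(self, branch_graph):
        w = hl.walk_counts(branch_graph, orders=(2, 3, 4))
        x, y = 0, 2
        assert w[2][x, y] == 1
        assert w[3][x, y] == 0
        assert w[4][x, y] == 3  # x-z-{x,y,w}-z-y round trips

    def test_triangle_cube(self, triangle):
        w = hl.walk_counts(triangle, orders=(2, 3))
        assert w[2][0, 1] == 1
        assert w[3][0, 1] == 3

    def test_diagonal_of_square_is_degree(self):
        g = hl.ba(40, 2, seed=3)
        w2 = hl.walk_counts(g, orders=(2,))[2]
        assert np.array_equal(np.diag(w2), g.degrees())

    def test_matches_recursive_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            g = random_simple_graph(rng, 8, 0.35)
            w = hl.walk_counts(g, orders=range(2, 7))
            for order in range(2, 7):
                for x in range(g.n_nodes):
                    for y in range(g.n_nodes):
                        assert w[order][x, y] == count_walks(g, x, y, order)

    def test_overflow_raises(self):
        g = Graph(10, [(i, j) for i in range(10) for j in range(i + 1, 10)])
        with pytest.raises(WalkOverflowError, match="smaller k"):
            hl.walk_counts(g, orders=(20,))


class TestPathIndices:
    def test_lw_branch(self, branch_graph):
        assert one_score(hl.lw_score(branch_graph, [(0, 2)], k=2)) == pytest.approx(1.0)

    def test_lw_triangle(self, triangle):
        assert one_score(hl.lw_score(triangle, [(0, 1)], k=2)) == pytest.approx(4.0)

    def test_lw_disconnected_pair_zero(self):
        g = Graph(4, [(0, 1), (2, 3)])
        for k in (2, 3, 5):
            assert one_score(hl.lw_score(g, [(0, 2)], k=k)) == 0.0

    def test_lpk_equals_lw_at_k2(self):
        g = hl.ws(50, 4, 0.2, seed=9)
        pairs = [(i, j) for i in range(8) for j in range(i + 1, 8)]
        a = hl.lpk_score(g, pairs, k=2).scores
        b = hl.lw_score(g, pairs, k=2).scores
        assert np.array_equal(a, b)

    def test_lpk_branch_k4(self, branch_graph):
        # A2+A3+A4+A5 = 1+0+3+0 (odd walks vanish by bipartite parity).
        assert one_score(hl.lpk_score(branch_graph, [(0, 2)], k=4)) == pytest.approx(4.0)

    def test_lp_epsilon_zero_is_cn(self):
        g = hl.ba(40, 2, seed=5)
        pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        lp = hl.lp_score(g, pairs, epsilon=0.0, n_max=5).scores
        cn = hl.local_score(g, pairs, "cn").scores
        assert np.array_equal(lp, cn)

    def test_lp_epsilon_one_is_lpk(self):
        g = hl.ws(40, 4, 0.3, seed=6)
        pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        lp = hl.lp_score(g, pairs, epsilon=1.0, n_max=5).scores
        lpk = hl.lpk_score(g, pairs, k=4).scores
        assert np.allclose(lp, lpk)

    def test_lp_path4_single_3walk(self, path4):
        assert one_score(
            hl.lp_score(path4, [(0, 3)], epsilon=0.5, n_max=3)
        ) == pytest.approx(0.5)


class TestKatz:
    def test_single_edge_geometric_closed_form(self):
        g = Graph(2, [(0, 1)])
        beta = 0.1
        expected = beta / (1 - beta**2)
        assert one_score(hl.katz_score(g, [(0, 1)], beta=beta)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_truncated_series(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            g = random_simple_graph(rng, 12, 0.3)
            if g.n_edges == 0:
                continue
            beta = 0.5 / max(spectral_radius(g), 1.0)
            S = score_matrix(g, IndexConfig("katz", beta=beta))
            A = g.adjacency_matrix().toarray()
            series = np.zeros_like(A)
            term = np.eye(g.n_nodes)
            for _ in range(50):
                term = beta * (A @ term)
                series += term
            assert np.abs(S - series).max() < 1e-9

    def test_beta_to_zero_limit_is_a_squared(self):
        g = hl.ws(30, 4, 0.2, seed=4)
        beta = 1e-6
        S = score_matrix(g, IndexConfig("katz", beta=beta))
        A2 = hl.walk_counts(g, orders=(2,))[2]
        off = ~np.eye(g.n_nodes, dtype=bool) & (A2 > 0) & (g.adjacency_matrix().toarray() == 0)
        assert np.allclose(S[off] / beta**2, A2[off], rtol=1e-3)

    def test_divergent_beta_rejected(self, triangle):
        with pytest.raises(ConvergenceError, match="convergence"):
            hl.katz_score(triangle, [(0, 1)], beta=0.6)  # 1/lambda_max = 0.5


class TestLO:
    def _series(self, g, alpha, terms):
        A = g.adjacency_matrix().toarray()
        total = np.zeros_like(A)
        sign, power = 1.0, np.linalg.matrix_power(A, 3)
        A2 = A @ A
        coeff = alpha
        for _ in range(terms):
            total += sign * coeff * power
            power = power @ A2
            coeff *= alpha
            sign = -sign
        return total

    def test_three_term_series_at_tiny_alpha(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            g = random_simple_graph(rng, 10, 0.3)
            if g.n_edges == 0:
                continue
            S = score_matrix(g, IndexConfig("lo", alpha_lo=1e-4))
            assert np.abs(S - self._series(g, 1e-4, 3)).max() < 1e-9

    def test_convergent_series_on_triangle(self, triangle):
        S = score_matrix(triangle, IndexConfig("lo", alpha_lo=0.01))
        assert np.abs(S - self._series(triangle, 0.01, 12)).max() < 1e-10

    def test_alpha_to_zero_limit_is_a_cubed(self, triangle):
        alpha = 1e-8
        S = score_matrix(triangle, IndexConfig("lo", alpha_lo=alpha))
        A3 = hl.walk_counts(triangle, orders=(3,))[3]
        assert np.allclose(S / alpha, A3, rtol=1e-6)

    def test_empty_graph_all_zero(self):
        g = Graph(4, [])
        assert not score_matrix(g, IndexConfig("lo")).any()


ALL_CONFIGS = [
    IndexConfig("cn"),
    IndexConfig("salton"),
    IndexConfig("ra"),
    IndexConfig("ch"),
    IndexConfig("pa"),
    IndexConfig("reg"),
    IndexConfig("dfpa"),
    IndexConfig("lw", k=3),
    IndexConfig("lpk", k=3),
    IndexConfig("lp", epsilon=0.4, n_max=4),
    IndexConfig("katz", beta=0.05),
    IndexConfig("lo", alpha_lo=0.01),
    IndexConfig("hem", alpha=0.3, k=2),
]


class TestInvariants:
    @pytest.mark.parametrize("config", ALL_CONFIGS, ids=lambda c: c.describe())
    def test_symmetry_and_nonnegativity(self, config):
        rng = np.random.default_rng(57)
        for _ in range(4):
            g = random_simple_graph(rng, 15, 0.25)
            S = score_matrix(g, config)
            assert np.allclose(S, S.T, atol=1e-12)
            if config.name == "lo":
                # LO's alternating series admits small genuine negatives,
                # bounded by the second-order term alpha^2 * max|A^5|.
                alpha = config.alpha_lo
                bound = alpha**2 * np.linalg.matrix_power(
                    g.adjacency_matrix().toarray(), 5
                ).max()
                assert S.min() > -bound - 1e-12
            else:
                assert S.min() > -1e-9

    def test_pair_scores_orientation_invariant(self, branch_graph):
        fwd = hl.lw_score(branch_graph, [(0, 2)], k=2).scores
        rev = hl.lw_score(branch_graph, [(2, 0)], k=2).scores
        assert np.array_equal(fwd, rev)

    def test_regular_graph_rank_orders_coincide(self):
        """On a d-regular graph, Salton and RA are CN/d: the three indices
        induce identical pair rankings (degree information is constant)."""
        d = 4
        g = hl.random_regular(40, d, seed=8)
        pairs = [(i, j) for i in range(12) for j in range(i + 1, 12)]
        cn = hl.local_score(g, pairs, "cn").scores
        salton = hl.local_score(g, pairs, "salton").scores
        ra = hl.local_score(g, pairs, "ra").scores
        assert np.allclose(salton, cn / d)
        assert np.allclose(ra, cn / d)
        assert np.allclose(hl.reg_score(g, pairs).scores, 1 / d**2)

    def test_empty_pair_set(self, triangle):
        ps = hl.lpk_score(triangle, [], k=2)
        assert ps.scores.size == 0
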