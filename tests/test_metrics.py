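"""Metric battery against hand calculations and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from wirecost import (
    CoreStructure,
    core_decomposition,
    core_overlap,
    degree_assortativity,
    global_efficiency,
    hierarchy_curve,
    max_assessable_club_size,
    small_world_index,
    weighted_clustering,
    weighted_rich_club,
    wiring_statistics,
)

from conftest import make_net, random_weighted_net


# ----------------------------------------------------------- oracles

def efficiency_oracle(net):
    """All-pairs Dijkstra through networkx with reciprocal-weight costs."""
    g = nx.Graph()
    g.add_nodes_from(range(net.n))
    for (i, j), w in net.edges.items():
        g.add_edge(i, j, cost=1.0 / w)
    total = 0.0
    for i in range(net.n):
        dist = nx.single_source_dijkstra_path_length(g, i, weight="cost")
        total += sum(1.0 / d for j, d in dist.items() if j != i)
    return total / (net.n * (net.n - 1))


def clustering_oracle(net):
    """Triangle enumeration with explicit loops (Onnela normalisation)."""
    W = net.weight_matrix()
    if W.max() > 0:
        W = W / W.max()
    n = net.n
    k = (W > 0).sum(axis=1)
    C = np.zeros(n)
    for i in range(n):
        if k[i] < 2:
            continue
        t = 0.0
        nbrs = np.flatnonzero(W[i])
        for j, h in itertools.combinations(nbrs, 2):
            t += (W[i, j] * W[i, h] * W[j, h]) ** (1 / 3)
        C[i] = t / (k[i] * (k[i] - 1) / 2)
    return C.mean(), C


def assortativity_oracle(net):
    """Pearson correlation of endpoint degrees over the doubled edge list."""
    k = net.degrees()
    xs, ys = [], []
    for i, j in net.edges:
        xs += [k[i], k[j]]
        ys += [k[j], k[i]]
    return np.corrcoef(xs, ys)[0, 1]


def rich_club_oracle(net, kt):
    """Direct summation of the weighted k-density definition."""
    k = net.degrees()
    members = [i for i in range(net.n) if k[i] > kt]
    if len(members) < 2:
        return None
    e_max = len(members) * (len(members) - 1) // 2
    if e_max > net.n_edges:
        return None
    w_in = sum(
        w for (i, j), w in net.edges.items() if i in members and j in members
    )
    top = sorted(net.edges.values(), reverse=True)[:e_max]
    return w_in / sum(top)


def s_core_oracle(net, s, use_weights=True):
    """Peel nodes with intra-subgraph strength < s until stable."""
    members = set(range(net.n))
    while True:
        strength = {i: 0.0 for i in members}
        for (i, j), w in net.edges.items():
            if i in members and j in members:
                v = w if use_weights else 1.0
                strength[i] += v
                strength[j] += v
        drop = {i for i in members if strength[i] < s}
        if not drop:
            return members
        members -= drop


# ------------------------------------------------------------- efficiency

class TestGlobalEfficiency:
    def test_two_nodes_unit_edge(self):
        net = make_net([0.0, 1.0], {(0, 1): 1.0})
        assert global_efficiency(net)[0] == pytest.approx(1.0)

    def test_weighted_path_by_hand(self, path3):
        """a-b-c with unit weights: d(a,c)=2, so E=(1 + 1/2 + 1)/3 · ... = 5/6."""
        assert global_efficiency(path3)[0] == pytest.approx(5 / 6)

    def test_disconnected_pairs_contribute_zero(self):
        net = make_net([0.0, 1.0, 10.0, 11.0], {(0, 1): 1.0, (2, 3): 1.0})
        E, per = global_efficiency(net)
        assert E == pytest.approx(1 / 3)
        assert np.allclose(per, 1 / 3)

    @pytest.mark.parametrize("n,E,seed", [(12, 30, 0), (20, 60, 1), (30, 140, 2)])
    def test_matches_dijkstra_oracle(self, n, E, seed):
        net = random_weighted_net(n, E, seed=seed)
        assert global_efficiency(net)[0] == pytest.approx(
            efficiency_oracle(net), abs=1e-9
        )


# ------------------------------------------------------------- clustering

class TestWeightedClustering:
    def test_triangle_of_maximal_weights(self):
        net = make_net(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0]],
            {(0, 1): 3.0, (0, 2): 3.0, (1, 2): 3.0},
        )
        _, C = weighted_clustering(net)
        assert np.allclose(C, 1.0)

    def test_star_has_zero_clustering(self, star5):
        assert weighted_clustering(star5)[0] == 0.0

    def test_weighted_triangle_by_hand(self):
        """Triangle with weights (1, 1, 0.125): geometric mean at the node
        holding both unit edges is (1*1*0.125)^(1/3) = 0.5."""
        net = make_net(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0]],
            {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 0.125},
        )
        _, C = weighted_clustering(net)
        assert C[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("n,E,seed", [(12, 40, 3), (25, 100, 4), (30, 150, 5)])
    def test_matches_triangle_enumeration_oracle(self, n, E, seed):
        net = random_weighted_net(n, E, seed=seed)
        ours_g, ours = weighted_clustering(net)
        ref_g, ref = clustering_oracle(net)
        assert np.allclose(ours, ref, atol=1e-9)
        assert ours_g == pytest.approx(ref_g, abs=1e-9)

    def test_matches_networkx_onnela(self):
        net = random_weighted_net(20, 80, seed=6)
        _, ours = weighted_clustering(net)
        ref = nx.clustering(net.to_networkx(), weight="weight")
        assert np.allclose(ours, [ref[i] for i in range(net.n)], atol=1e-9)


# ------------------------------------------------------------ small world

class TestSmallWorld:
    def test_self_reference_is_exactly_one(self):
        assert small_world_index(0.31, 0.18, 0.31, 0.18) == 1.0

    def test_doubled_clustering(self):
        assert small_world_index(0.2, 0.5, 0.1, 0.5) == pytest.approx(2.0)

    def test_zero_reference_is_error(self):
        with pytest.raises(ValueError):
            small_world_index(0.2, 0.5, 0.0, 0.5)

    def test_consistent_with_published_cortical_arithmetic(self):
        """C=0.271, E=0.174 against references C_rnd=0.024, E_rnd=0.260
        reproduces the reported index 7.478 up to rounding of the inputs."""
        sw = small_world_index(0.271, 0.174, 0.024, 0.260)
        assert sw == pytest.approx(7.478, abs=0.15)


# -------------------------------------------------------------- hierarchy

class TestHierarchyCurve:
    def test_regular_uniform_graph_is_flat_at_one(self):
        edges = {p: 1.0 for p in itertools.combinations(range(5), 2)}
        net = make_net(np.arange(5.0), edges)
        hc = hierarchy_curve(net, bin_width=1)
        filled = hc.mean_clustering_per_bin[hc.counts > 0]
        assert np.allclose(filled, 1.0)

    def test_hub_and_cliques_pattern(self):
        """A hub joined to three disjoint triangles has below-average
        clustering (0.25 vs 1 for the triangle nodes), so its degree bin
        falls below 1 and the triangle bins above."""
        edges = {}
        for t in range(3):
            a, b, c = 1 + 3 * t, 2 + 3 * t, 3 + 3 * t
            edges.update({(a, b): 1.0, (a, c): 1.0, (b, c): 1.0})
            edges.update({(0, a): 1.0, (0, b): 1.0, (0, c): 1.0})
        coords = np.random.default_rng(0).uniform(0, 10, size=(10, 3))
        net = make_net(coords, edges)
        hc = hierarchy_curve(net, bin_width=1)
        vals = hc.mean_clustering_per_bin
        k = net.degrees()
        hub_bin = np.digitize(k[0], hc.bin_edges) - 1
        leaf_bin = np.digitize(k[1], hc.bin_edges) - 1
        assert vals[hub_bin] < 1.0 < vals[leaf_bin]
        assert hc.spearman_r < 0

    def test_invalid_inputs(self, triangle):
        with pytest.raises(ValueError):
            hierarchy_curve(triangle, bin_width=0)

    def test_bin_weighted_mean_is_one(self):
        net = random_weighted_net(40, 200, seed=9)
        hc = hierarchy_curve(net, bin_width=3)
        filled = hc.counts > 0
        mean = np.average(hc.mean_clustering_per_bin[filled], weights=hc.counts[filled])
        assert mean == pytest.approx(1.0, rel=1e-9)


# ---------------------------------------------------------- assortativity

class TestAssortativity:
    def test_star_is_perfectly_disassortative(self, star5):
        assert degree_assortativity(star5) == pytest.approx(-1.0)

    def test_degree_regular_graph_undefined(self):
        net = make_net([0.0, 1.0, 2.0, 3.0], {(0, 1): 1.0, (2, 3): 1.0})
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(degree_assortativity(net))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pearson_oracle(self, seed):
        net = random_weighted_net(8, 14, seed=seed)
        ours = degree_assortativity(net)
        assert ours == pytest.approx(assortativity_oracle(net), abs=1e-12)
        assert ours == pytest.approx(
            nx.degree_assortativity_coefficient(net.to_networkx()), abs=1e-9
        )


# ------------------------------------------------------------------ cores

class TestCoreDecomposition:
    def test_triangle_k_core(self, triangle):
        profile, core = core_decomposition(triangle, kind="k_core")
        assert core.threshold == 2 and core.members == frozenset({0, 1, 2})

    def test_star_k_core_collapses_at_one(self, star5):
        _, core = core_decomposition(star5, kind="k_core")
        assert core.threshold == 1 and len(core.members) == 5

    def test_s_core_on_binary_network_equals_k_core(self):
        net = random_weighted_net(25, 90, seed=7, binary=True)
        prof_k, core_k = core_decomposition(net, kind="k_core")
        prof_s, core_s = core_decomposition(net, kind="s_core")
        assert prof_k == prof_s
        assert core_k.members == core_s.members

    def test_profile_sizes_monotone_non_increasing(self):
        net = random_weighted_net(40, 200, seed=8)
        profile, _ = core_decomposition(net, kind="s_core")
        sizes = [s for _, s in profile]
        assert sizes == sorted(sizes, reverse=True)
        thresholds = [t for t, _ in profile]
        assert thresholds == sorted(thresholds)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_collapse_points_match_peeling_oracle(self, seed):
        """Each recorded collapse point (t, size) is checked just inside its
        validity interval (the exact threshold is a floating-point tie)."""
        net = random_weighted_net(25, 90, seed=seed)
        profile, core = core_decomposition(net, kind="s_core")
        for t, size in profile:
            assert len(s_core_oracle(net, t - 1e-9)) == size
        # just past the final threshold the core is empty
        assert len(s_core_oracle(net, core.threshold + 1e-6)) == 0
        assert s_core_oracle(net, core.threshold - 1e-9) == set(core.members)

    def test_k_core_matches_networkx_core_number(self):
        net = random_weighted_net(30, 140, seed=9)
        _, core = core_decomposition(net, kind="k_core")
        cn = nx.core_number(net.to_networkx())
        kmax = max(cn.values())
        assert core.threshold == kmax
        assert core.members == frozenset(i for i, c in cn.items() if c == kmax)

    def test_s_step_grid_profile(self):
        net = random_weighted_net(20, 60, seed=3)
        grid, _ = core_decomposition(net, kind="s_core", s_step=0.5)
        exact, _ = core_decomposition(net, kind="s_core")
        assert all(t == pytest.approx(i * 0.5) for i, (t, _) in enumerate(grid))
        assert grid[0][1] == exact[0][1]


# -------------------------------------------------------------- rich club

class TestWeightedRichClub:
    def test_maximal_when_club_holds_strongest_edges(self):
        """K4 of weight-10 edges plus weak pendants: the degree>2 club is
        fully connected by exactly the strongest connections, phi = 1."""
        edges = {p: 10.0 for p in itertools.combinations(range(4), 2)}
        edges[(0, 4)] = 1.0
        edges[(1, 5)] = 1.0
        net = make_net(np.arange(6.0), edges)
        rc = weighted_rich_club(net)
        assert rc["phi"][2] == pytest.approx(1.0)
        assert rc["phi"][3] == pytest.approx(1.0)  # club {0,1} via edge (0,1)

    def test_equal_weights_reduce_to_classical_k_density(self):
        net = random_weighted_net(30, 180, seed=10, binary=True)
        rc = weighted_rich_club(net)
        k = net.degrees()
        for kt, phi in rc["phi"].items():
            members = np.flatnonzero(k > kt)
            internal = sum(
                1 for (i, j) in net.edges if k[i] > kt and k[j] > kt
            )
            classical = internal / (len(members) * (len(members) - 1) / 2)
            assert phi == pytest.approx(classical, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_summation_oracle(self, seed):
        net = random_weighted_net(20, 80, seed=seed)
        rc = weighted_rich_club(net)
        assert rc["phi"], "no valid rich-club domain"
        for kt, phi in rc["phi"].items():
            assert phi == pytest.approx(rich_club_oracle(net, kt), abs=1e-12)
            assert 0.0 <= phi <= 1.0

    def test_domain_limited_by_interconnectable_size(self):
        net = random_weighted_net(30, 60, seed=4)
        rc = weighted_rich_club(net)
        xmax = rc["max_club_size"]
        assert all(size <= xmax for size in rc["club_size"].values())
        assert all("interconnectable" in r or "fewer" in r for r in rc["excluded"].values())

    def test_max_assessable_club_size_quadratic(self):
        for E in (1, 3, 10, 574, 17865):
            x = max_assessable_club_size(E)
            assert x * (x - 1) // 2 <= E < (x + 1) * x // 2


# ------------------------------------------------------------------ wiring

class TestWiringStatistics:
    def test_unit_square_cycle(self, square_cycle):
        ws = wiring_statistics(square_cycle)
        assert ws["mean_length"] == pytest.approx(1.0)
        assert ws["std_length"] == pytest.approx(0.0)

    def test_reference_to_self_is_null(self, square_cycle):
        ws = wiring_statistics(square_cycle, reference=square_cycle)
        assert ws["region_pct_change_mean"] == 0.0
        assert ws["ranksum_p"] > 0.99

    def test_hemisphere_statistics(self):
        net = make_net(
            [[-2, 0, 0], [-1, 0, 0], [1, 0, 0], [2, 0, 0]],
            {(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0},
            hemisphere=["left", "left", "right", "right"],
        )
        ws = wiring_statistics(net)
        assert ws["interhemispheric_fraction"] == pytest.approx(1 / 3)
        assert ws["interhemispheric_mean_length"] == pytest.approx(2.0)


class TestCoreOverlap:
    def _core(self, members):
        return CoreStructure(
            members=frozenset(members), threshold=0.0, kind="s_core",
            internal_edges=0, internal_density=0.0, external_reach=0,
        )

    def test_identical_cores(self, triangle):
        c = self._core({0, 1, 2})
        assert core_overlap(c, c, triangle)["overlap_fraction"] == 1.0

    def test_disjoint_cores(self):
        net = make_net(np.arange(6.0), {(0, 1): 1.0, (2, 3): 1.0, (4, 5): 1.0})
        rep = core_overlap(self._core({0, 1}), self._core({2, 3}), net)
        assert rep["overlap_fraction"] == 0.0

    def test_toy_network_hand_enumeration(self):
        """6 nodes: core A = {0,1,2} holds 2 internal edges and reaches
        nodes 3 and 4; core B = {2,3,4} shares one node with A."""
        net = make_net(
            np.arange(6.0),
            {(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0, (3, 4): 1.0, (0, 4): 1.0, (4, 5): 1.0},
        )
        rep = core_overlap(self._core({0, 1, 2}), self._core({2, 3, 4}), net)
        assert rep["overlap_fraction"] == pytest.approx(1 / 3)
        assert rep["core_a"]["internal_edges"] == 2
        assert rep["core_a"]["external_reach"] == 2
        assert rep["core_b"]["internal_edges"] == 2
        assert rep["core_b"]["external_reach"] == 3
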