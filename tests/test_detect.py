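from itertools import combinations

import networkx as nx
import pytest

from dppnet.detect import (
    ComplexCore,
    DetectorConfig,
    attach_score,
    clique_probability,
    clique_score,
    enumerate_maximal_cliques,
    expand_cores,
    identify_complexes,
    max_edge_weight,
    select_cores,
    to_active_correlated_cliques,
)

from conftest import clique_edges, make_dppn


def brute_force_maximal_cliques(graph, min_size=3):
    """Exhaustive subset enumeration oracle (bitmask adjacency)."""
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * len(nodes)
    for u, v in graph.edges:
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]

    def is_clique(mask):
        m = mask
        while m:
            i = (m & -m).bit_length() - 1
            m &= m - 1
            if (adj[i] & mask) != mask & ~(1 << i):
                return False
        return True

    cliques = [m for m in range(1, 1 << len(nodes)) if is_clique(m)]
    clique_set = set(cliques)
    maximal = set()
    for m in cliques:
        if bin(m).count("1") < min_size:
            continue
        if any(
            (m | (1 << j)) in clique_set
            for j in range(len(nodes))
            if not m & (1 << j)
        ):
            continue
        maximal.add(frozenset(nodes[i] for i in range(len(nodes)) if m & (1 << i)))
    return maximal


class TestEnumerateMaximalCliques:
    def test_k4(self):
        names = list("ABCD")
        dppn = make_dppn({v: {1: 0.99} for v in names}, clique_edges(names))
        assert enumerate_maximal_cliques(dppn) == {frozenset(names)}

    def test_two_triangles_sharing_vertex(self):
        edges = clique_edges("ABC") + clique_edges("CDE")
        dppn = make_dppn({v: {1: 0.99} for v in "ABCDE"}, edges)
        assert enumerate_maximal_cliques(dppn) == {
            frozenset("ABC"),
            frozenset("CDE"),
        }

    def test_path_graph_has_no_cliques(self):
        dppn = make_dppn(
            {v: {1: 0.99} for v in "ABCD"}, [("A", "B"), ("B", "C"), ("C", "D")]
        )
        assert enumerate_maximal_cliques(dppn) == set()

    def test_matches_brute_force_on_random_graphs(self):
        import random

        rng = random.Random(11)
        for _ in range(30):
            n = rng.randint(4, 10)
            g = nx.gnp_random_graph(n, rng.uniform(0.2, 0.7), seed=rng.randint(0, 9999))
            g = nx.relabel_nodes(g, {i: f"V{i}" for i in g.nodes})
            dppn = make_dppn({v: {1: 0.99} for v in g.nodes}, list(g.edges))
            assert enumerate_maximal_cliques(dppn) == brute_force_maximal_cliques(
                dppn.graph
            )


class TestActiveCorrelatedCliques:
    def test_triangle_probability_and_time(self, triangle_dppn):
        prob, t_c = clique_probability(triangle_dppn, "ABC", [2])
        assert prob == pytest.approx(0.970299, abs=1e-12)
        assert t_c == 2

    def test_argmax_time_selection(self):
        # products: 0.68*0.99*0.99 at T1 vs 0.99^3 at T5 -> T5 wins
        levels = {
            "A": {1: 0.68, 5: 0.99},
            "B": {1: 0.99, 5: 0.99},
            "C": {1: 0.99, 5: 0.99},
        }
        dppn = make_dppn(levels, clique_edges("ABC"))
        prob, t_c = clique_probability(dppn, "ABC", [1, 5])
        assert t_c == 5
        assert prob == pytest.approx(0.99**3, abs=1e-12)

    def test_tie_goes_to_earliest_time(self):
        levels = {v: {3: 0.95, 7: 0.95} for v in "ABC"}
        dppn = make_dppn(levels, clique_edges("ABC"))
        _, t_c = clique_probability(dppn, "ABC", [3, 7])
        assert t_c == 3

    def test_jointly_empty_active_set_excluded(self):
        # pairwise intersections nonempty, triple intersection empty
        levels = {
            "A": {1: 0.99, 2: 0.99},
            "B": {2: 0.99, 3: 0.99},
            "C": {1: 0.99, 3: 0.99},
        }
        dppn = make_dppn(levels, clique_edges("ABC"))
        cliques = enumerate_maximal_cliques(dppn)
        assert frozenset("ABC") in cliques
        assert to_active_correlated_cliques(dppn, cliques) == []

    def test_triangle_clique_score(self, triangle_dppn):
        # oracle: 0.99^3 * (3 * 0.5) = 1.4554485
        accs = to_active_correlated_cliques(
            triangle_dppn, enumerate_maximal_cliques(triangle_dppn)
        )
        assert len(accs) == 1
        assert accs[0].score == pytest.approx(1.4554485, abs=1e-9)
        assert accs[0].assigned_time == 2

    def test_score_monotone_in_topology_sum(self, triangle_dppn):
        assert clique_score(triangle_dppn, "ABC", 0.5) < clique_score(
            triangle_dppn, "ABC", 0.9
        )


class TestSelectCores:
    def test_two_disjoint_triangles(self):
        levels = {v: {1: 0.99} for v in "ABCDEF"}
        dppn = make_dppn(levels, clique_edges("ABC") + clique_edges("DEF"))
        cores = select_cores(
            dppn, enumerate_maximal_cliques(dppn), DetectorConfig(core_thresh=1.0)
        )
        assert {c.members for c in cores} == {frozenset("ABC"), frozenset("DEF")}
        assert all(c.origin == "clique" for c in cores)

    def test_heavy_overlap_removes_loser(self):
        # triangles ABC (all 0.99) and ABD (D at 0.68) share 2/3 >= 0.5
        levels = {
            "A": {1: 0.99},
            "B": {1: 0.99},
            "C": {1: 0.99},
            "D": {1: 0.68},
        }
        edges = clique_edges("ABC") + [("A", "D"), ("B", "D")]
        dppn = make_dppn(levels, edges)
        cores = select_cores(
            dppn, enumerate_maximal_cliques(dppn), DetectorConfig(core_thresh=1.0)
        )
        assert [c.members for c in cores] == [frozenset("ABC")]

    def test_partial_overlap_prunes_and_keeps(self):
        # K4 ABCD beats K4 CDEF... use two K4s sharing one vertex:
        # overlap 1/4 < 0.5 -> loser pruned to a triangle and kept
        levels = {v: {1: 0.99} for v in "ABCDEFG"}
        levels["E"] = {1: 0.68}  # make ABCD the clear winner
        edges = clique_edges("ABCD") + clique_edges("DEFG")
        dppn = make_dppn(levels, edges)
        cores = select_cores(
            dppn, enumerate_maximal_cliques(dppn), DetectorConfig(core_thresh=1.0)
        )
        assert {c.members for c in cores} == {frozenset("ABCD"), frozenset("EFG")}

    def test_isolated_high_weight_edge_becomes_core(self):
        dppn = make_dppn({"A": {1: 0.99}, "B": {1: 0.99}}, [("A", "B")])
        weight, t = max_edge_weight(dppn, "A", "B")
        assert weight == pytest.approx(0.5 * 0.99 * 0.99, abs=1e-12)
        cores = select_cores(dppn, set(), DetectorConfig(core_thresh=weight * 0.999))
        assert [c.members for c in cores] == [frozenset("AB")]
        assert cores[0].origin == "edge"
        assert cores[0].assigned_time == t == 1

    def test_edge_at_threshold_is_not_core(self):
        # "larger than" is strict
        dppn = make_dppn({"A": {1: 0.99}, "B": {1: 0.99}}, [("A", "B")])
        weight, _ = max_edge_weight(dppn, "A", "B")
        assert select_cores(dppn, set(), DetectorConfig(core_thresh=weight)) == []

    def test_edge_core_time_is_argmax_earliest_on_tie(self):
        levels = {
            "A": {1: 0.68, 4: 0.99, 9: 0.99},
            "B": {1: 0.99, 4: 0.99, 9: 0.99},
        }
        dppn = make_dppn(levels, [("A", "B")])
        _, t = max_edge_weight(dppn, "A", "B")
        assert t == 4  # T4 and T9 tie at 0.99*0.99; earliest wins

    def test_edge_cores_exclude_clique_covered_edges(self, triangle_dppn):
        cores = select_cores(
            triangle_dppn,
            enumerate_maximal_cliques(triangle_dppn),
            DetectorConfig(core_thresh=0.0),
        )
        assert [c.origin for c in cores] == ["clique"]


class TestAttachAndExpand:
    @pytest.fixture
    def k4_with_satellite(self):
        # K4 core ABCD; satellite S linked to A and B only, active at T3
        levels = {v: {3: 0.99} for v in "ABCDS"}
        edges = clique_edges("ABCD") + [("A", "S"), ("B", "S")]
        return make_dppn(levels, edges)

    def test_attach_score_is_mean_edge_weight(self, k4_with_satellite):
        dppn = k4_with_satellite
        core = ComplexCore(frozenset("ABCD"), 3, "clique", 1.0)
        expected = (
            dppn.edge_weight("A", "S", 3) + dppn.edge_weight("B", "S", 3)
        ) / 4.0
        assert attach_score(dppn, core, "S") == pytest.approx(expected, abs=1e-15)
        assert expected > 0.05

    def test_attach_score_no_edges_is_zero(self, k4_with_satellite):
        core = ComplexCore(frozenset("ABCD"), 3, "clique", 1.0)
        dppn = make_dppn(
            {v: {3: 0.99} for v in "ABCDZ"}, clique_edges("ABCD") + [("A", "B")]
        )
        assert attach_score(dppn, core, "Z") == 0.0

    def test_satellite_attached_at_default_threshold(self, k4_with_satellite):
        complexes = identify_complexes(k4_with_satellite, DetectorConfig())
        members = {pc.members for pc in complexes}
        assert frozenset("ABCDS") in members

    def test_extend_thresh_one_freezes_cores(self, k4_with_satellite):
        cores = select_cores(
            k4_with_satellite,
            enumerate_maximal_cliques(k4_with_satellite),
            DetectorConfig(core_thresh=1.0),
        )
        complexes = expand_cores(
            k4_with_satellite, cores, DetectorConfig(extend_thresh=1.0)
        )
        assert [pc.members for pc in complexes] == [c.members for c in cores]

    def test_extend_thresh_zero_attaches_any_connection(self, k4_with_satellite):
        cores = select_cores(
            k4_with_satellite,
            enumerate_maximal_cliques(k4_with_satellite),
            DetectorConfig(core_thresh=1.0),
        )
        complexes = expand_cores(
            k4_with_satellite, cores, DetectorConfig(extend_thresh=0.0)
        )
        assert complexes[0].members == frozenset("ABCDS")

    def test_candidate_inactive_at_tc_not_attached(self):
        levels = {v: {3: 0.99} for v in "ABCD"}
        levels["S"] = {7: 0.99}  # wrong time
        edges = clique_edges("ABCD") + [("A", "S"), ("B", "S")]
        dppn = make_dppn(levels, edges)
        complexes = identify_complexes(dppn, DetectorConfig(extend_thresh=0.0))
        assert all("S" not in pc.members for pc in complexes)


class TestIdentifyComplexes:
    def test_empty_dppn(self):
        dppn = make_dppn({}, [])
        assert identify_complexes(dppn) == []

    def test_overlapping_complexes_both_reported(self):
        # triangles ABC (active T4) and CDE (active T8) share protein C
        levels = {
            "A": {4: 0.99},
            "B": {4: 0.99},
            "C": {4: 0.99, 8: 0.99},
            "D": {8: 0.99},
            "E": {8: 0.99},
        }
        dppn = make_dppn(levels, clique_edges("ABC") + clique_edges("CDE"))
        members = {pc.members for pc in identify_complexes(dppn, DetectorConfig())}
        assert frozenset("ABC") in members
        assert frozenset("CDE") in members

    def test_assigned_time_reported(self, triangle_dppn):
        (pc,) = identify_complexes(triangle_dppn, DetectorConfig(extend_thresh=1.0))
        assert pc.assigned_time == 2

    def test_sorted_by_descending_score(self):
        levels = {v: {1: 0.99} for v in "ABCD"}
        levels.update({v: {1: 0.68} for v in "XYZ"})
        dppn = make_dppn(levels, clique_edges("ABCD") + clique_edges("XYZ"))
        complexes = identify_complexes(dppn, DetectorConfig(extend_thresh=1.0))
        scores = [pc.score for pc in complexes]
        assert scores == sorted(scores, reverse=True)

    def test_determinism(self):
        levels = {v: {1: 0.99, 5: 0.68} for v in "ABCDEFGH"}
        edges = clique_edges("ABCD") + clique_edges("DEFG") + [("G", "H")]
        results = []
        for _ in range(2):
            dppn = make_dppn(levels, edges)
            complexes = identify_complexes(dppn, DetectorConfig())
            results.append(
                [(sorted(pc.members), pc.assigned_time, pc.score) for pc in complexes]
            )
        assert results[0] == results[1]
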