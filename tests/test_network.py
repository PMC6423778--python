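"""PAN construction, edge betweenness, communities, modularity."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from _oracles import all_partitions as _all_partitions
from _oracles import enumerate_edge_betweenness as _enumerate_edge_betweenness

from stemsig import synthetic
from stemsig.network import (
    COL_ORG_A,
    COL_ORG_B,
    COL_SYM_A,
    COL_SYM_B,
    AugmentConfig,
    CommunityPartition,
    FormatError,
    InteractionGraph,
    augment_top_interactors,
    edge_betweenness,
    extract_signature_network,
    girvan_newman_communities,
    modularity,
    parse_biogrid,
)


def _graph(edges):
    edges = {tuple(sorted(e)) for e in edges}
    nodes = {v: False for e in edges for v in e}
    return InteractionGraph(nodes=nodes, edges=edges)


def _write_biogrid(tmp_path, rows):
    path = tmp_path / "biogrid.tsv"
    pd.DataFrame(
        rows, columns=[COL_SYM_A, COL_SYM_B, COL_ORG_A, COL_ORG_B]
    ).to_csv(path, sep="\t", index=False)
    return path


class TestParseBiogrid:
    def test_each_filter_exercised_once(self, tmp_path):
        path = _write_biogrid(
            tmp_path,
            [
                ("A", "B", 9606, 9606),
                ("A", "B", 9606, 9606),
                ("C", "C", 9606, 9606),
                ("D", "E", 10090, 10090),
            ],
        )
        edges, prov = parse_biogrid(path)
        assert edges == {("A", "B")}
        assert prov["duplicates"] == 1
        assert prov["self_loops"] == 1
        assert prov["taxid_filtered"] == 1

    def test_symbols_uppercased_and_reversed_pairs_collapse(self, tmp_path):
        path = _write_biogrid(
            tmp_path, [("abc", "xyz", 9606, 9606), ("XYZ", "ABC", 9606, 9606)]
        )
        edges, prov = parse_biogrid(path)
        assert edges == {("ABC", "XYZ")}
        assert prov["duplicates"] == 1

    def test_empty_file_gives_empty_graph(self, tmp_path):
        path = _write_biogrid(tmp_path, [])
        edges, prov = parse_biogrid(path)
        assert edges == set() and prov["rows"] == 0

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"foo": [1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match=COL_SYM_A):
            parse_biogrid(path)


class TestExtractSignatureNetwork:
    def test_empty_seeds_empty_graph(self):
        g = extract_signature_network({("A", "B")}, set())
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_star_center_keeps_whole_star(self):
        edges = {("HUB", x) for x in ("A", "B", "C")}
        g = extract_signature_network(edges, {"HUB"})
        assert g.n_edges == 3
        assert g.nodes["HUB"] and not g.nodes["A"]

    def test_brute_force_oracle_random_graph(self):
        rng = np.random.default_rng(0)
        nodes = [f"P{i}" for i in range(40)]
        edges = set()
        while len(edges) < 200:
            a, b = rng.choice(nodes, 2, replace=False)
            edges.add(tuple(sorted((a, b))))
        seeds = set(rng.choice(nodes, 10, replace=False))
        g = extract_signature_network(edges, seeds)
        expected = {e for e in edges if e[0] in seeds or e[1] in seeds}
        assert g.edges == expected


class TestAugmentTopInteractors:
    def test_zero_interactors_keeps_only_seed_edges(self):
        all_edges = {("S1", "S2"), ("S1", "X"), ("X", "Y")}
        g = extract_signature_network(all_edges, {"S1", "S2"})
        out = augment_top_interactors(
            g, all_edges, {"S1", "S2"}, AugmentConfig(n_interactors=0)
        )
        assert out.edges == {("S1", "S2")}

    def test_ranking_by_distinct_seed_partners(self):
        all_edges = {("S1", "X"), ("S2", "X"), ("S3", "X"), ("S1", "Y")}
        seeds = {"S1", "S2", "S3"}
        g = extract_signature_network(all_edges, seeds)
        out = augment_top_interactors(
            g, all_edges, seeds, AugmentConfig(n_interactors=1)
        )
        assert "X" in out.nodes and "Y" not in out.nodes

    def test_interactor_interactor_edges_included_by_default(self):
        all_edges = {("S1", "X"), ("S1", "Y"), ("X", "Y")}
        seeds = {"S1"}
        g = extract_signature_network(all_edges, seeds)
        out = augment_top_interactors(g, all_edges, seeds, AugmentConfig(2))
        assert ("X", "Y") in out.edges
        narrow = augment_top_interactors(
            g, all_edges, seeds, AugmentConfig(2, seed_edges_only=True)
        )
        assert ("X", "Y") not in narrow.edges

    def test_brute_force_sort_and_slice_with_ties(self):
        rng = np.random.default_rng(1)
        seeds = {f"S{i}" for i in range(10)}
        interactors = [f"I{i:02d}" for i in range(50)]
        all_edges = set()
        seed_count = {}
        for x in interactors:
            k = int(rng.integers(1, 8))
            partners = rng.choice(sorted(seeds), k, replace=False)
            seed_count[x] = len(set(partners))
            all_edges |= {tuple(sorted((x, s))) for s in partners}
        g = extract_signature_network(all_edges, seeds)
        out = augment_top_interactors(g, all_edges, seeds, AugmentConfig(30))
        expected = set(
            sorted(interactors, key=lambda v: (-seed_count[v], v))[:30]
        )
        assert {v for v in out.nodes if not out.nodes[v]} == expected


class TestEdgeBetweenness:
    def test_path_graph_hand_enumeration(self):
        # pairs (A,B), (B,C), (A,C): each edge carries 2 paths
        bet = edge_betweenness(_graph([("A", "B"), ("B", "C")]))
        assert bet[("A", "B")] == pytest.approx(2.0)
        assert bet[("B", "C")] == pytest.approx(2.0)

    def test_triangle_hand_enumeration(self):
        bet = edge_betweenness(
            _graph([("A", "B"), ("B", "C"), ("A", "C")])
        )
        assert all(v == pytest.approx(1.0) for v in bet.values())

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_shortest_path_enumeration_small_graphs(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 9))
        p = rng.uniform(0.2, 0.9)
        gnx = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        gnx = nx.relabel_nodes(gnx, {i: f"N{i}" for i in range(n)})
        if gnx.number_of_edges() == 0:
            return
        ours = edge_betweenness(_graph(gnx.edges()))
        oracle = _enumerate_edge_betweenness(gnx)
        for e, v in ours.items():
            assert v == pytest.approx(oracle[e]), e


class TestModularity:
    def test_single_edge_one_community(self):
        g = _graph([("A", "B")])
        assert modularity(g, {"A": 0, "B": 0}) == pytest.approx(0.0)

    def test_two_disjoint_edges_two_communities(self):
        g = _graph([("A", "B"), ("C", "D")])
        q = modularity(g, {"A": 0, "B": 0, "C": 1, "D": 1})
        assert q == pytest.approx(0.5)

    def test_all_singletons_negative(self):
        g = _graph([("A", "B"), ("B", "C"), ("A", "C")])
        q = modularity(g, {v: i for i, v in enumerate("ABC")})
        assert q < 0

    def test_matches_networkx_on_random_graph(self):
        rng = np.random.default_rng(2)
        gnx = nx.gnp_random_graph(12, 0.3, seed=3)
        g = _graph((f"N{a}", f"N{b}") for a, b in gnx.edges())
        membership = {v: int(rng.integers(0, 3)) for v in g.nodes}
        comms = [
            {v for v, c in membership.items() if c == k} for k in range(3)
        ]
        comms = [c for c in comms if c]
        expected = nx.algorithms.community.modularity(
            nx.relabel_nodes(gnx, {i: f"N{i}" for i in range(12)}), comms
        )
        assert modularity(g, membership) == pytest.approx(expected)

    def test_missing_node_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            modularity(_graph([("A", "B")]), {"A": 0})


class TestGirvanNewman:
    def test_two_triangles_with_bridge(self):
        edges = [
            ("A", "B"), ("B", "C"), ("A", "C"),
            ("D", "E"), ("E", "F"), ("D", "F"),
            ("C", "D"),
        ]
        g = _graph(edges)
        part = girvan_newman_communities(g)
        assert part.removal_sequence[0] == ("C", "D")  # the bridge
        groups = _membership_sets(part)
        assert groups == {frozenset("ABC"), frozenset("DEF")}
        # oracle: best modularity over every partition of the 6 nodes
        best_q = max(
            modularity(g, {v: i for i, block in enumerate(p) for v in block})
            for p in _all_partitions("ABCDEF")
        )
        assert part.Q == pytest.approx(best_q)

    def test_complete_graph_single_community(self):
        g = _graph(itertools.combinations("ABCDE", 2))
        part = girvan_newman_communities(g)
        assert len(_membership_sets(part)) == 1
        assert part.Q == pytest.approx(0.0)
        # oracle: no split of K5 beats the trivial partition
        best_q = max(
            modularity(g, {v: i for i, block in enumerate(p) for v in block})
            for p in _all_partitions("ABCDE")
        )
        assert best_q == pytest.approx(0.0)

    def test_components_never_merge(self):
        g = _graph([("A", "B"), ("B", "C"), ("X", "Y")])
        part = girvan_newman_communities(g)
        ms = part.membership
        assert ms["X"] == ms["Y"] != ms["A"]
        assert part.Q == pytest.approx(modularity(g, ms))

    def test_planted_partition_recovered_exactly(self):
        records, truth = synthetic.generate_interaction_file(
            2, [8, 8], p_in=0.9, p_out=0.02, seed=13, n_decoys=0
        )
        edges = {
            tuple(sorted((a, b)))
            for a, b in zip(records[COL_SYM_A], records[COL_SYM_B])
        }
        part = girvan_newman_communities(_graph(edges))
        found = _membership_sets(part)
        planted = {
            frozenset(
                v for v, c in truth.community_label.items() if c == k
            )
            for k in (0, 1)
        }
        assert found == planted

    def test_deterministic(self):
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("A", "C")]
        p1 = girvan_newman_communities(_graph(edges))
        p2 = girvan_newman_communities(_graph(edges))
        assert p1.removal_sequence == p2.removal_sequence
        assert p1.membership == p2.membership

    def test_q_at_least_trivial(self):
        rng = np.random.default_rng(4)
        gnx = nx.gnp_random_graph(10, 0.4, seed=5)
        part = girvan_newman_communities(
            _graph((f"N{a}", f"N{b}") for a, b in gnx.edges())
        )
        assert part.Q >= -1e-12


def _membership_sets(part: CommunityPartition) -> set[frozenset]:
    groups: dict[int, set] = {}
    for v, c in part.membership.items():
        groups.setdefault(c, set()).add(v)
    return {frozenset(g) for g in groups.values()}


def test_graph_validation():
    with pytest.raises(ValueError, match="self-loop"):
        InteractionGraph(nodes={"A": False}, edges={("A", "A")})
    with pytest.raises(ValueError, match="missing"):
        InteractionGraph(nodes={"A": False}, edges={("A", "B")})
    with pytest.raises(ValueError):
        AugmentConfig(n_interactors=-1)
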