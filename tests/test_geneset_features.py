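"""Gene-set redundancy removal and Fisher enrichment features.

The exact independent-set solver is checked against exhaustive subset
enumeration; the Fisher feature against explicit hypergeometric
summation (see conftest for both references).
"""

import math

import numpy as np
import pytest

from heal import (
    AssociationNetwork,
    GeneSet,
    build_redundancy_graph,
    fisher_enrichment_feature,
    geneset_feature_matrix,
    jaccard,
    select_nonredundant,
    weight_from_pvalue,
)

from .conftest import ref_fisher_p, ref_mwis


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_partial_overlap(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())


class TestWeightFromPvalue:
    @pytest.mark.parametrize(
        "p,expected", [(1.0, 1.0), (0.01, 1.02), (1e-100, 2.0)]
    )
    def test_reference_points(self, p, expected):
        assert math.isclose(weight_from_pvalue(p), expected)

    def test_strictly_decreasing_in_p(self):
        ps = np.logspace(-12, 0, 30)
        ws = [weight_from_pvalue(p) for p in ps]
        assert all(a > b for a, b in zip(ws, ws[1:]))

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError):
            weight_from_pvalue(p)


class TestRedundancyGraph:
    def test_disjoint_sets_no_edge(self):
        g = build_redundancy_graph(
            [GeneSet("a", {"x"}), GeneSet("b", {"y"})]
        )
        assert g.graph.number_of_edges() == 0

    def test_identical_sets_one_edge(self):
        g = build_redundancy_graph(
            [GeneSet("a", {"x", "y"}), GeneSet("b", {"x", "y"})]
        )
        assert g.graph.number_of_edges() == 1

    def test_threshold_is_strict(self):
        # J = 3/11 ~ 0.27 <= 0.3 -> no edge
        a = GeneSet("a", set("abcdefg"))
        b = GeneSet("b", set("abchijk"))
        assert jaccard(a.genes, b.genes) == pytest.approx(3 / 11)
        g = build_redundancy_graph([a, b], tau=0.3)
        assert g.graph.number_of_edges() == 0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            build_redundancy_graph([GeneSet("a", {"x"}), GeneSet("a", {"y"})])


def _graph_from(edges, weights, tau=0.3):
    """Assemble a GeneSetGraph directly with given edges/weights."""
    import networkx as nx

    from heal.geneset_features import GeneSetGraph

    g = nx.Graph()
    for v, w in weights.items():
        g.add_node(v, weight=w)
    g.add_edges_from(edges)
    return GeneSetGraph(g, tau)


class TestSelectNonredundant:
    def test_edgeless_graph_keeps_everything(self):
        g = _graph_from([], {f"v{i}": 1.0 for i in range(5)})
        kept, total = select_nonredundant(g)
        assert len(kept) == 5 and total == pytest.approx(5.0)

    def test_triangle_keeps_heaviest_vertex(self):
        g = _graph_from(
            [("a", "b"), ("b", "c"), ("a", "c")],
            {"a": 1.01, "b": 1.02, "c": 1.03},
        )
        kept, total = select_nonredundant(g)
        assert kept == {"c"} and total == pytest.approx(1.03)

    def test_path_keeps_endpoints(self):
        g = _graph_from([("a", "b"), ("b", "c")], {"a": 1.0, "b": 1.0, "c": 1.0})
        kept, total = select_nonredundant(g)
        assert kept == {"a", "c"} and total == pytest.approx(2.0)

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for trial in range(60):
            n = int(rng.integers(1, 13))
            vertices = [f"v{i}" for i in range(n)]
            weights = {v: float(rng.uniform(1.0, 2.0)) for v in vertices}
            edges = [
                (vertices[i], vertices[j])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.3
            ]
            g = _graph_from(edges, weights)
            kept, total = select_nonredundant(g)
            ref_w, _ = ref_mwis(vertices, edges, weights)
            assert total == pytest.approx(ref_w)
            edge_set = {frozenset(e) for e in edges}
            assert not any(
                frozenset((u, v)) in edge_set
                for u in kept
                for v in kept
                if u != v
            )

    def test_kept_sets_pairwise_nonredundant(self):
        rng = np.random.default_rng(23)
        genes = [f"g{i}" for i in range(40)]
        sets = []
        for k in range(12):
            members = rng.choice(genes, size=8, replace=False)
            sets.append(GeneSet(f"s{k}", set(members.tolist()), float(rng.uniform(1e-8, 1))))
        graph = build_redundancy_graph(sets, tau=0.3)
        kept, _ = select_nonredundant(graph)
        by_id = {s.set_id: s for s in sets}
        for a in kept:
            for b in kept:
                if a < b:
                    assert jaccard(by_id[a].genes, by_id[b].genes) <= 0.3


class TestNeighbourGeneList:
    def test_star_centre_and_leaf(self):
        net = AssociationNetwork([("hub", f"l{i}") for i in range(4)])
        assert net.neighbour_gene_list("hub") == {f"l{i}" for i in range(4)}
        assert net.neighbour_gene_list("l0") == {"hub"}

    def test_absent_gene_has_empty_list(self):
        net = AssociationNetwork([("a", "b")])
        assert net.neighbour_gene_list("zzz") == set()

    def test_self_loops_dropped(self):
        net = AssociationNetwork([("a", "a"), ("a", "b")])
        assert net.neighbour_gene_list("a") == {"b"}


class TestFisherEnrichment:
    def test_known_overrepresentation(self):
        # universe 20, list 5, set 4, overlap 4: p = 1/969
        universe = {f"g{i}" for i in range(20)}
        gene_set = GeneSet("s", {"g0", "g1", "g2", "g3"})
        gene_list = {"g0", "g1", "g2", "g3", "g10"}
        feat = fisher_enrichment_feature(gene_list, gene_set, universe)
        assert feat == pytest.approx(-math.log10(5 / 4845), rel=1e-9)
        assert feat == pytest.approx(2.9863, abs=1e-3)

    def test_no_overlap_gives_feature_near_zero(self):
        universe = {f"g{i}" for i in range(1000)}
        feat = fisher_enrichment_feature(
            {"g1", "g2"}, GeneSet("s", {"g900", "g901"}), universe
        )
        assert feat < 0.01

    def test_empty_list_gives_zero(self):
        universe = {"a", "b"}
        assert fisher_enrichment_feature(set(), GeneSet("s", {"a"}), universe) == 0.0

    def test_list_equal_universe_gives_zero(self):
        universe = {f"g{i}" for i in range(10)}
        feat = fisher_enrichment_feature(universe, GeneSet("s", {"g0", "g1"}), universe)
        assert feat == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_on_all_small_tables(self):
        """Exhaustive check over all 2x2 tables with universe <= 30."""
        for n_univ in (5, 12, 30):
            universe = {f"g{i}" for i in range(n_univ)}
            ordered = sorted(universe)
            for n_set in range(1, n_univ + 1, max(1, n_univ // 4)):
                gene_set = GeneSet("s", set(ordered[:n_set]))
                for n_list in range(1, n_univ + 1, max(1, n_univ // 4)):
                    for overlap in range(0, min(n_set, n_list) + 1):
                        gene_list = set(ordered[:overlap]) | set(
                            ordered[n_set:n_set + n_list - overlap]
                        )
                        if len(gene_list) != n_list:
                            continue
                        got = fisher_enrichment_feature(gene_list, gene_set, universe)
                        expected = ref_fisher_p(n_univ, n_set, n_list, overlap)
                        assert got == pytest.approx(
                            -math.log10(expected), rel=1e-9, abs=1e-12
                        )

    def test_monotone_in_overlap(self):
        n_univ, n_set, n_list = 40, 10, 8
        universe = {f"g{i}" for i in range(n_univ)}
        ordered = sorted(universe)
        feats = []
        for overlap in range(0, n_list + 1):
            gene_set = GeneSet("s", set(ordered[:n_set]))
            gene_list = set(ordered[:overlap]) | set(
                ordered[n_set:n_set + n_list - overlap]
            )
            feats.append(fisher_enrichment_feature(gene_list, gene_set, universe))
        assert all(a <= b + 1e-12 for a, b in zip(feats, feats[1:]))


class TestFeatureMatrix:
    def test_shape_contract(self):
        net = AssociationNetwork([("a", "b"), ("b", "c")])
        sets = [GeneSet("s1", {"a", "b"}), GeneSet("s2", {"c"})]
        table = geneset_feature_matrix(["a", "b", "c"], net, sets)
        assert table.n_samples == 3 and table.n_features == 2
        assert table.feature_names == ("enrich_s1", "enrich_s2")

    def test_isolated_gene_row_is_zero(self):
        net = AssociationNetwork([("a", "b")])
        sets = [GeneSet("s1", {"a", "b"})]
        table = geneset_feature_matrix(["zzz"], net, sets, universe={"a", "b", "zzz"})
        np.testing.assert_array_equal(table.values, [[0.0]])

    def test_matching_neighbourhood_dominates_row(self):
        # gene g's neighbourhood equals s_match exactly; other sets disjoint
        members = {f"m{i}" for i in range(6)}
        others = {f"o{i}" for i in range(6)}
        net = AssociationNetwork([("g", m) for m in members])
        sets = [GeneSet("s_match", members), GeneSet("s_other", others)]
        universe = members | others | {"g"} | {f"pad{i}" for i in range(20)}
        table = geneset_feature_matrix(["g"], net, sets, universe=universe)
        row = table.values[0]
        assert np.argmax(row) == 0
        assert row[0] > row[1]
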