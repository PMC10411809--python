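"""Gene-set de-redundancy and network-enrichment feature engineering.

Curated gene-set collections (e.g. GO terms) are heavily redundant. Pairs
of sets whose Jaccard overlap exceeds a threshold tau become edges of an
undirected graph over the sets; keeping a maximum-weight independent set
of that graph — weights 1 - log10(p)/100 from each set's significance —
retains the most significant, mutually non-redundant collection. Each
retained set then contributes one feature per gene: the -log10 one-sided
Fisher's exact p-value for over-representation of the gene's network
neighbourhood in the set.

The independent-set optimisation is a binary integer program
(x_i + x_j <= 1 on every edge, maximise sum w_i x_i); it is solved
exactly by branch-and-bound with connected-component decomposition,
which is ample at curated-collection scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .data_model import FeatureTable


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with its significance and derived MWIS weight."""

    set_id: str
    genes: frozenset
    p_value: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value for {self.set_id!r} must be in (0,1]")

    @property
    def weight(self) -> float:
        return weight_from_pvalue(self.p_value)


@dataclass(frozen=True)
class GeneSetGraph:
    """Gene sets as weighted vertices; redundant pairs (J > tau) as edges."""

    graph: nx.Graph
    tau: float

    @property
    def set_ids(self) -> tuple:
        return tuple(self.graph.nodes)

    def weight(self, set_id: str) -> float:
        return self.graph.nodes[set_id]["weight"]


class AssociationNetwork:
    """Undirected protein-association network; no self-loops."""

    def __init__(self, edges: Iterable[tuple]):
        g = nx.Graph()
        for a, b in edges:
            if a != b:
                g.add_edge(a, b)
        self._graph = g

    @property
    def genes(self) -> set:
        return set(self._graph.nodes)

    def neighbour_gene_list(self, gene) -> set:
        """All genes adjacent to ``gene``; empty when absent or isolated."""
        if gene not in self._graph:
            return set()
        return set(self._graph.neighbors(gene))


def jaccard(a: Iterable, b: Iterable) -> float:
    """|A n B| / |A u B| overlap of two gene sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard of two empty sets is undefined")
    return len(a & b) / len(union)


def weight_from_pvalue(p: float) -> float:
    """Vertex weight 1 - log10(p)/100; 1 at p=1, 2 at p=1e-100."""
    if not 0 < p <= 1:
        raise ValueError("p-value must be in (0,1]")
    return 1.0 - math.log10(p) / 100.0


def build_redundancy_graph(sets: Sequence[GeneSet], tau: float = 0.3) -> GeneSetGraph:
    """Edge between two sets iff their Jaccard overlap strictly exceeds tau."""
    ids = [s.set_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene-set ids")
    g = nx.Graph()
    for s in sets:
        g.add_node(s.set_id, weight=s.weight, genes=s.genes, p_value=s.p_value)
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if jaccard(sets[i].genes, sets[j].genes) > tau:
                g.add_edge(sets[i].set_id, sets[j].set_id)
    return GeneSetGraph(g, tau)


def _mwis_exact(adj: dict, weights: dict) -> tuple[float, frozenset]:
    """Exact maximum-weight independent set by branch-and-bound.

    Recursion: split into connected components; in each, branch on a
    maximum-degree vertex v — either exclude v, or include it and drop
    its closed neighbourhood. Memoised on the surviving vertex set.
    """

    @lru_cache(maxsize=None)
    def solve(vertices: frozenset) -> tuple[float, frozenset]:
        if not vertices:
            return 0.0, frozenset()
        sub = {v: adj[v] & vertices for v in vertices}
        # isolated vertices always belong to the optimum
        iso = {v for v, nb in sub.items() if not nb}
        if iso:
            w, kept = solve(vertices - iso)
            return w + sum(weights[v] for v in iso), kept | iso
        # component decomposition
        comps = []
        seen: set = set()
        for v in vertices:
            if v in seen:
                continue
            stack, comp = [v], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(sub[u] - comp)
            seen |= comp
            comps.append(frozenset(comp))
        if len(comps) > 1:
            total, kept = 0.0, frozenset()
            for comp in comps:
                w, k = solve(comp)
                total += w
                kept |= k
            return total, kept
        v = max(vertices, key=lambda u: (len(sub[u]), str(u)))
        w_out, k_out = solve(vertices - {v})
        w_in, k_in = solve(vertices - {v} - sub[v])
        w_in += weights[v]
        if w_in > w_out:
            return w_in, k_in | {v}
        return w_out, k_out

    total, kept = solve(frozenset(adj))
    solve.cache_clear()
    return total, kept


def select_nonredundant(graph: GeneSetGraph) -> tuple[set, float]:
    """Maximum-weight independent set of the redundancy graph.

    Returns the kept set_ids and their total weight; no two kept sets
    share an edge, and no other independent set has larger total weight.
    """
    g = graph.graph
    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    weights = {v: g.nodes[v]["weight"] for v in g.nodes}
    total, kept = _mwis_exact(adj, weights)
    return set(kept), float(total)


def fisher_enrichment_feature(gene_list: Iterable, gene_set: GeneSet, universe: Iterable) -> float:
    """-log10 one-sided Fisher over-representation p of a gene's
    neighbourhood in a gene set.

    2x2 table over the universe: (in list & in set, in list only, in set
    only, neither). Empty gene list means no over-representation is
    possible: p = 1, feature 0.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    gene_list = set(gene_list) & universe
    members = set(gene_set.genes) & universe
    if not gene_list or not members:
        return 0.0
    n_univ = len(universe)
    k_overlap = len(gene_list & members)
    # P(X >= k) under the hypergeometric null
    p = float(hypergeom.sf(k_overlap - 1, n_univ, len(members), len(gene_list)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return -math.log10(p)


def geneset_feature_matrix(
    genes: Sequence,
    network: AssociationNetwork,
    sets: Sequence[GeneSet],
    universe: Iterable | None = None,
) -> FeatureTable:
    """One enrichment feature per kept gene set, one row per query gene.

    The universe defaults to the union of all network genes and all set
    members.
    """
    if universe is None:
        universe = set(network.genes)
        for s in sets:
            universe |= s.genes
    universe = set(universe)
    values = np.zeros((len(genes), len(sets)))
    for i, g in enumerate(genes):
        neigh = network.neighbour_gene_list(g)
        for j, s in enumerate(sets):
            values[i, j] = fisher_enrichment_feature(neigh, s, universe)
    return FeatureTable(
        tuple(genes), tuple(f"enrich_{s.set_id}" for s in sets), values
    )


def gene_sets_from_gmt(sets: Mapping[str, Iterable], pvalues: Mapping[str, float]) -> list[GeneSet]:
    """Pair a GMT mapping with its p-value table (missing p defaults to 1)."""
    return [GeneSet(sid, frozenset(genes), float(pvalues.get(sid, 1.0))) for sid, genes in sets.items()]
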