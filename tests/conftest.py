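"""Shared fixtures and independent reference implementations.

The reference (oracle) functions here are deliberately written straight
from the mathematical definitions — naive enumeration, no shared code
with the package — so agreement between package and oracle is evidence,
not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from heal import LabelledSet, Pool, ScoredPool
from heal.data_model import FeatureTable


# ---------------------------------------------------------------------------
# reference: quartile / certainty-heuristic selection
# ---------------------------------------------------------------------------

def ref_quartile(values, i):
    """(i/4)(n+1)-th order statistic, linear interpolation, clamped."""
    v = sorted(values)
    n = len(v)
    pos = i / 4 * (n + 1)
    pos = max(1.0, min(float(n), pos))
    lo, hi = int(math.floor(pos)), int(math.ceil(pos))
    return v[lo - 1] + (pos - lo) * (v[hi - 1] - v[lo - 1])


def ref_heuristic(ids, scores, threshold=0.9, boundary=0.6):
    """Certainty selection computed by direct enumeration.

    Returns (positives, negatives, sup, inf) with positives/negatives as
    sets of sample IDs.
    """
    plus = [(s, i) for s, i in zip(scores, ids) if s >= boundary]
    minus = [(s, i) for s, i in zip(scores, ids) if s < boundary]
    sup = threshold
    positives = set()
    if plus:
        q3 = ref_quartile([s for s, _ in plus], 3)
        q4 = [s for s, _ in plus if s >= q3]
        if min(q4) > threshold:
            sup = min(q4)
        positives = {i for s, i in plus if s >= sup}
    inf = None
    negatives = set()
    if minus:
        q1 = ref_quartile([s for s, _ in minus], 1)
        members = [s for s, _ in minus if s <= q1]
        inf = max(members)
        negatives = {i for s, i in minus if s <= inf}
    return positives, negatives, sup, inf


# ---------------------------------------------------------------------------
# reference: maximum-weight independent set by exhaustive enumeration
# ---------------------------------------------------------------------------

def ref_mwis(vertices, edges, weights):
    """Try every vertex subset; keep the heaviest independent one."""
    vertices = list(vertices)
    edge_set = {frozenset(e) for e in edges}
    best_w, best = -1.0, set()
    for r in range(len(vertices) + 1):
        for combo in itertools.combinations(vertices, r):
            if any(frozenset(p) in edge_set for p in itertools.combinations(combo, 2)):
                continue
            w = sum(weights[v] for v in combo)
            if w > best_w:
                best_w, best = w, set(combo)
    return best_w, best


def ref_mwis_bitmask(n_vertices, edges_idx, weights_arr):
    """Exhaustive MWIS value over all 2^n subsets, vectorised.

    ``edges_idx`` are (i, j) integer pairs, ``weights_arr`` the vertex
    weights in index order. Feasible up to ~20 vertices.
    """
    masks = np.arange(1 << n_vertices, dtype=np.uint32)
    indep = np.ones(masks.shape, dtype=bool)
    for i, j in edges_idx:
        indep &= ~((masks >> i) & (masks >> j) & 1).astype(bool)
    totals = np.zeros(masks.shape)
    for v in range(n_vertices):
        totals += ((masks >> v) & 1) * weights_arr[v]
    totals[~indep] = -np.inf
    return float(totals.max())


# ---------------------------------------------------------------------------
# reference: one-sided Fisher over-representation p by enumeration
# ---------------------------------------------------------------------------

def ref_fisher_p(n_univ, n_set, n_list, overlap):
    """P(X >= overlap) for X hypergeometric, via explicit summation."""
    total = math.comb(n_univ, n_list)
    p = 0.0
    for j in range(overlap, min(n_set, n_list) + 1):
        p += math.comb(n_set, j) * math.comb(n_univ - n_set, n_list - j) / total
    return p


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_table(values, ids=None, names=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    names = names or [f"f{j}" for j in range(values.shape[1])]
    return FeatureTable(tuple(ids), tuple(names), values)


def make_scored_pool(scores, ids=None):
    scores = np.asarray(scores, dtype=float)
    ids = ids or [f"u{i:03d}" for i in range(len(scores))]
    # pool features are irrelevant to selection; a single dummy column
    table = FeatureTable(tuple(ids), ("f0",), np.zeros((len(scores), 1)))
    return ScoredPool(Pool(table), scores)


@pytest.fixture
def tiny_labelled():
    """8 samples, 2 features, balanced labels."""
    rng = np.random.default_rng(42)
    x = rng.normal(size=(8, 2))
    y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    x[y == 1] += 2.0
    return LabelledSet(make_table(x), y)
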