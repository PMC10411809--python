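"""Synthetic fixtures with the statistical structure the pipeline assumes.

Two generators: (1) two-class Gaussian feature tables with configurable
per-dimension class separation, class imbalance and redundant (correlated)
feature copies — the shape of the tabular benchmark data the annotation
loop is evaluated on; (2) gene-set collections with controlled pairwise
Jaccard overlap, log-uniform p-values and an association network with
planted neighbourhood/set coincidences for the enrichment features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    FeatureTable,
    LabelledSet,
    write_edge_list,
    write_gmt,
    write_labelled,
)
from .geneset_features import GeneSet


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a two-class Gaussian feature table.

    ``class_sep`` is the mean shift (in noise-sd units) applied to each
    informative dimension, so the overall between-class Mahalanobis
    separation is class_sep * sqrt(n_informative). Redundant features are
    noisy copies of informative ones calibrated to Pearson r ~ rho.
    """

    n_samples: int = 200
    n_features: int = 10
    n_informative: int = 5
    class_sep: float = 3.0
    pos_fraction: float = 0.35
    n_redundant: int = 0
    rho: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("n_informative + n_redundant must be <= n_features")
        if not 0 < self.pos_fraction < 1:
            raise ValueError("pos_fraction must be in (0,1)")
        if self.n_samples < 4 or self.n_informative < 1:
            raise ValueError("need n_samples >= 4 and n_informative >= 1")
        if not 0 < abs(self.rho) <= 1:
            raise ValueError("rho must be in (0,1]")


def make_binary_dataset(spec: SynthSpec) -> LabelledSet:
    """Draw a fully labelled two-class Gaussian dataset from a SynthSpec.

    Informative dims: N(+/- class_sep/2, 1) depending on class. Noise
    dims: N(0,1). Redundant dim r is rho * z_src + sqrt(1-rho^2) * eps of
    informative dim r mod n_informative, giving correlation ~ rho.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    n_pos = int(round(n * spec.pos_fraction))
    n_pos = min(max(n_pos, 1), n - 1)
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_pos, replace=False)] = 1

    x = rng.normal(size=(n, d))
    shift = np.where(y == 1, spec.class_sep / 2.0, -spec.class_sep / 2.0)
    x[:, : spec.n_informative] += shift[:, None]

    for r in range(spec.n_redundant):
        src = r % spec.n_informative
        col = spec.n_informative + r
        eps = rng.normal(size=n)
        x[:, col] = spec.rho * x[:, src] + np.sqrt(1 - spec.rho**2) * eps

    ids = tuple(f"s{i:04d}" for i in range(n))
    names = (
        tuple(f"inf_{j}" for j in range(spec.n_informative))
        + tuple(f"red_{j}" for j in range(spec.n_redundant))
        + tuple(
            f"noise_{j}"
            for j in range(d - spec.n_informative - spec.n_redundant)
        )
    )
    return LabelledSet(FeatureTable(ids, names, x), y)


def make_geneset_fixture(
    n_sets: int = 8,
    universe_size: int = 60,
    overlap_profile: str = "clique-3",
    seed: int = 0,
    set_size: int = 10,
    edge_prob: float = 0.08,
):
    """Gene-set collection + p-values + association edge list.

    ``overlap_profile`` controls engineered redundancy: ``clique-3``
    plants three sets with pairwise Jaccard > 0.3 (the remaining sets
    drawn with low mutual overlap); ``independent`` draws all sets with
    low overlap. P-values are log-uniform in [1e-10, 1]. The network is
    Erdos-Renyi plus one planted gene whose neighbourhood equals the
    first set exactly (a ground-truth enrichment signal).

    Returns (sets, pvalues, edges, planted_gene).
    """
    if overlap_profile not in ("clique-3", "independent"):
        raise ValueError(f"unknown overlap_profile {overlap_profile!r}")
    if overlap_profile == "clique-3" and n_sets < 3:
        raise ValueError("clique-3 profile needs at least 3 sets")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(universe_size)]

    members: list[set] = []
    if overlap_profile == "clique-3":
        # three sets sharing a common core large enough that J > 0.3
        core = set(rng.choice(genes, size=set_size - 2, replace=False).tolist())
        rest = [g for g in genes if g not in core]
        for _ in range(3):
            extra = set(rng.choice(rest, size=2, replace=False).tolist())
            members.append(core | extra)
    while len(members) < n_sets:
        cand = set(rng.choice(genes, size=set_size, replace=False).tolist())
        if all(len(cand & m) / len(cand | m) <= 0.3 for m in members):
            members.append(cand)

    pvalues = {
        f"set{k}": float(10 ** rng.uniform(-10, 0)) for k in range(n_sets)
    }
    sets = [
        GeneSet(f"set{k}", frozenset(members[k]), pvalues[f"set{k}"])
        for k in range(n_sets)
    ]

    edges: set = set()
    for i in range(universe_size):
        for j in range(i + 1, universe_size):
            if rng.random() < edge_prob:
                edges.add((genes[i], genes[j]))
    # planted enrichment: one gene's neighbourhood is exactly set0
    planted = next(g for g in genes if g not in members[0])
    edges = {(a, b) for (a, b) in edges if planted not in (a, b)}
    for m in sorted(members[0]):
        edges.add((planted, m))
    return sets, pvalues, sorted(edges), planted


def write_benchmark_fixture(out_dir: str | Path, spec: SynthSpec | None = None, seed: int = 0) -> dict:
    """Emit data.csv, sets.gmt, pvalues.csv, edges.tsv into ``out_dir``.

    The CSV/GMT/edge-list dialects are the same ones the CLI consumes, so
    end-to-end runs can start from these files directly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or SynthSpec(seed=seed)
    dataset = make_binary_dataset(spec)
    write_labelled(dataset, out / "data.csv", label_column="label", id_column="sample_id")
    sets, pvalues, edges, planted = make_geneset_fixture(seed=seed)
    write_gmt({s.set_id: s.genes for s in sets}, out / "sets.gmt")
    pd.DataFrame(
        {"set_id": list(pvalues), "p": [pvalues[k] for k in pvalues]}
    ).to_csv(out / "pvalues.csv", index=False)
    write_edge_list(edges, out / "edges.tsv")
    return {
        "data": out / "data.csv",
        "gmt": out / "sets.gmt",
        "pvalues": out / "pvalues.csv",
        "edges": out / "edges.tsv",
        "planted_gene": planted,
    }
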