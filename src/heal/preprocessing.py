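"""Normalisation, redundancy filtering, class balancing and feature ranking.

The ordering mirrors the annotation pipeline: z-scoring and the pairwise
Pearson redundancy filter are fit once, up front, on the union of labelled
and unlabelled feature values; SMOTE balancing and the embedded
permutation-importance feature selection are recomputed every iteration
from the current labelled set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

from .data_model import FeatureTable, LabelledSet


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered by permutation importance (descending)."""

    feature_names: tuple
    importance: tuple

    def __post_init__(self):
        if len(self.feature_names) != len(self.importance):
            raise ValueError("feature_names and importance lengths differ")
        imp = tuple(float(v) for v in self.importance)
        if any(imp[i] < imp[i + 1] for i in range(len(imp) - 1)):
            raise ValueError("importance not in descending order")
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "importance", imp)

    def top(self, k: int) -> tuple:
        return self.feature_names[: min(k, len(self.feature_names))]


def zscore_normalize(table: FeatureTable) -> FeatureTable:
    """Standardise each column to mean 0, sample (n-1) sd 1.

    Constant columns carry no information and are mapped to all-zeros.
    """
    if table.n_samples < 2:
        raise ValueError("z-score normalisation needs at least 2 samples")
    x = table.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    out = np.zeros_like(x)
    nz = sd > 0
    out[:, nz] = (x[:, nz] - mean[nz]) / sd[nz]
    return FeatureTable(table.sample_ids, table.feature_names, out)


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; defined as 0 when either vector has zero variance."""
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def correlation_filter(
    table: FeatureTable,
    target: np.ndarray | None = None,
    r_cut: float = 0.70,
    target_rows: np.ndarray | None = None,
) -> tuple[FeatureTable, list]:
    """Drop one feature of every pair with |Pearson r| above ``r_cut``.

    Pairs are examined in descending |r|; whenever both members of an
    offending pair are still retained, the one with the smaller |r| to
    the class label is dropped (ties keep the earlier column). ``target``
    may cover only a subset of rows (``target_rows`` gives their indices),
    as when the filter is fit on labelled+pool but labels exist for the
    labelled rows only.
    """
    x = table.values
    n_feat = table.n_features
    if n_feat < 2:
        return table, []
    if target is not None:
        target = np.asarray(target, dtype=float)
        xt = x if target_rows is None else x[np.asarray(target_rows)]
        tcorr = np.array([abs(_safe_pearson(xt[:, j], target)) for j in range(n_feat)])
    else:
        tcorr = np.zeros(n_feat)

    sd = x.std(axis=0)
    nzmask = sd > 0
    corr = np.zeros((n_feat, n_feat))
    if nzmask.sum() >= 2:
        sub = np.corrcoef(x[:, nzmask], rowvar=False)
        corr[np.ix_(nzmask, nzmask)] = np.nan_to_num(sub)
    np.fill_diagonal(corr, 0.0)

    pairs = [
        (abs(corr[i, j]), i, j)
        for i in range(n_feat)
        for j in range(i + 1, n_feat)
        if abs(corr[i, j]) > r_cut
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    retained = np.ones(n_feat, dtype=bool)
    for _, i, j in pairs:
        if retained[i] and retained[j]:
            # keep the member more correlated with the target; earlier
            # column wins ties
            drop = j if tcorr[j] <= tcorr[i] else i
            retained[drop] = False
    kept = [table.feature_names[j] for j in range(n_feat) if retained[j]]
    dropped = [table.feature_names[j] for j in range(n_feat) if not retained[j]]
    return table.select_features(kept), dropped


def smote_balance(labelled: LabelledSet, k_neighbors: int = 5, seed: int = 0) -> LabelledSet:
    """Equalise class counts by synthetic minority over-sampling.

    Each synthetic point is a convex combination x + u (x_nn - x),
    u ~ U(0,1), of a minority sample and one of its k nearest minority
    neighbours (k capped at minority size - 1). Original rows are
    untouched; synthetic rows get provenance tag ``synthetic``.
    """
    if not labelled.has_both_classes():
        raise ValueError("both classes required before balancing")
    n0, n1 = labelled.class_counts()
    if n0 == n1:
        return labelled
    minority = 1 if n1 < n0 else 0
    n_needed = abs(n0 - n1)
    min_idx = np.flatnonzero(labelled.labels == minority)
    if len(min_idx) < 2:
        raise ValueError("minority class has fewer than 2 samples; SMOTE needs a neighbour")
    x_min = labelled.table.values[min_idx]
    k = min(k_neighbors, len(min_idx) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)
    # first neighbour is the point itself
    neigh = nn.kneighbors(x_min, return_distance=False)[:, 1:]

    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(min_idx), size=n_needed)
    pick = rng.integers(0, k, size=n_needed)
    gap = rng.uniform(0.0, 1.0, size=n_needed)
    x_new = x_min[base] + gap[:, None] * (x_min[neigh[base, pick]] - x_min[base])

    existing = set(labelled.sample_ids)
    new_ids, i = [], 0
    while len(new_ids) < n_needed:
        cand = f"synthetic_{i}"
        if cand not in existing:
            new_ids.append(cand)
        i += 1
    synth = FeatureTable(tuple(new_ids), labelled.table.feature_names, x_new)
    return labelled.append(synth, [minority] * n_needed, "synthetic")


def _forest_oob_importance(
    x: np.ndarray, y: np.ndarray, n_trees: int, seed: int
) -> np.ndarray:
    """Breiman-style permutation importance from a bagged tree forest.

    Each tree is fit on a bootstrap sample; its out-of-bag accuracy is
    compared with the accuracy after shuffling one feature column at a
    time, and the drops are averaged over trees.
    """
    n, d = x.shape
    rng = np.random.default_rng(seed)
    deltas = np.zeros((n_trees, d))
    counts = np.zeros(d)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(0, 2**31 - 1))
        ).fit(x[boot], y[boot])
        x_oob, y_oob = x[oob], y[oob]
        base_acc = float(np.mean(tree.predict(x_oob) == y_oob))
        perm = rng.permutation(oob.size)
        for j in range(d):
            x_perm = x_oob.copy()
            x_perm[:, j] = x_oob[perm, j]
            acc = float(np.mean(tree.predict(x_perm) == y_oob))
            deltas[t, j] += base_acc - acc
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        imp = np.where(counts > 0, deltas.sum(axis=0) / np.maximum(counts, 1), 0.0)
    return imp


def select_top_features(
    labelled: LabelledSet, k: int = 400, n_trees: int = 100, seed: int = 0
) -> FeatureRanking:
    """Rank features by out-of-bag permutation importance; keep the top k.

    Importance of a feature is the baseline out-of-bag accuracy of a
    bagged random-forest minus the accuracy after that feature's values
    are shuffled. Ranking ties are broken by column order.
    """
    if not labelled.has_both_classes():
        raise ValueError("feature selection requires both classes in the labelled set")
    x, y = labelled.table.values, labelled.labels
    imp = _forest_oob_importance(x, y, n_trees=n_trees, seed=seed)
    order = sorted(range(len(imp)), key=lambda j: (-imp[j], j))
    names = tuple(labelled.table.feature_names[j] for j in order)
    return FeatureRanking(names, tuple(imp[j] for j in order))
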