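"""Query-selection strategies for the annotation loop.

The certainty heuristic replaces the human oracle: at each iteration the
scored pool is split at the classification boundary into a positive side
P+ (score >= boundary) and a negative side P-, quartiles of each side are
computed with the (i/4)(n+1)-th order-statistic rule, and dynamic cut-offs
are derived — ``sup`` on the positive side (never below the user
threshold) and ``inf`` on the negative side (the top of the first
quartile, deliberately with no user threshold). Samples beyond the
cut-offs are pseudo-labelled and appended to the training set.

Uncertainty sampling (closest to the boundary) and random sampling are
provided as the classical oracle-in-the-loop benchmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import Pool

STRATEGIES = ("certainty", "uncertainty", "random")


@dataclass(frozen=True)
class ScoredPool:
    """Pool plus per-sample positive-class probability."""

    pool: Pool
    score: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.score, dtype=float)
        if s.shape != (len(self.pool),):
            raise ValueError("one score per pool sample required")
        if s.size and (s.min() < 0 or s.max() > 1):
            raise ValueError("scores must lie in [0,1]")
        object.__setattr__(self, "score", s)

    def __len__(self) -> int:
        return len(self.pool)


@dataclass(frozen=True)
class SelectedBatch:
    """The samples chosen in one iteration, with the cut-offs that chose them."""

    sample_ids: tuple
    pseudo_labels: tuple
    scores: tuple
    sup: float
    inf: float | None
    strategy: str

    def __post_init__(self):
        if not (len(self.sample_ids) == len(self.pseudo_labels) == len(self.scores)):
            raise ValueError("batch fields must align")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "pseudo_labels", tuple(int(v) for v in self.pseudo_labels))
        object.__setattr__(self, "scores", tuple(float(v) for v in self.scores))

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_positive(self) -> int:
        return sum(self.pseudo_labels)

    @property
    def n_negative(self) -> int:
        return len(self) - self.n_positive


def partition_by_boundary(
    scored: ScoredPool, boundary: float = 0.6
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of pool samples on the positive (score >= boundary) and
    negative (score < boundary) side."""
    s = scored.score
    plus = np.flatnonzero(s >= boundary)
    minus = np.flatnonzero(s < boundary)
    return plus, minus


def quartile(values: Sequence[float], i: int) -> float:
    """The i-th quartile as the (i/4)(n+1)-th order statistic.

    Fractional positions are linearly interpolated between adjacent order
    statistics; positions outside [1, n] are clamped, so Q4 of any sample
    is its maximum.
    """
    if not 1 <= i <= 4:
        raise ValueError("quartile index must be in 1..4")
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("quartile of empty sample is undefined")
    pos = (i / 4) * (n + 1)
    pos = min(max(pos, 1.0), float(n))
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return float(v[lo - 1] + frac * (v[hi - 1] - v[lo - 1]))


def heuristic_select(
    scored: ScoredPool, threshold: float = 0.9, boundary: float = 0.6
) -> SelectedBatch:
    """Certainty selection with quartile-derived dynamic cut-offs.

    Positive side: members of the fourth quartile are the scores >= Q3;
    ``sup`` is their minimum when that minimum clears the user threshold,
    else the threshold itself, and scores >= sup are pseudo-labelled 1.
    Negative side: members of the first quartile are the scores <= Q1;
    ``inf`` is their maximum and scores <= inf are pseudo-labelled 0.
    Either side (or the whole batch) may come out empty.
    """
    ids = np.array(scored.pool.sample_ids, dtype=object)
    s = scored.score
    plus, minus = partition_by_boundary(scored, boundary)

    sup = threshold
    pos_sel: list[int] = []
    if plus.size:
        q3 = quartile(s[plus], 3)
        q4_members = s[plus] >= q3
        min_q4 = float(s[plus][q4_members].min())
        if min_q4 > threshold:
            sup = min_q4
        pos_sel = [int(k) for k in plus[s[plus] >= sup]]

    inf: float | None = None
    neg_sel: list[int] = []
    if minus.size:
        q1 = quartile(s[minus], 1)
        q1_members = s[minus] <= q1
        inf = float(s[minus][q1_members].max())
        neg_sel = [int(k) for k in minus[s[minus] <= inf]]

    chosen = sorted(pos_sel, key=lambda k: ids[k]) + sorted(neg_sel, key=lambda k: ids[k])
    labels = [1] * len(pos_sel) + [0] * len(neg_sel)
    return SelectedBatch(
        tuple(ids[chosen]),
        tuple(labels),
        tuple(s[chosen]),
        sup=sup,
        inf=inf,
        strategy="certainty",
    )


def uncertainty_select(
    scored: ScoredPool, batch_size: int = 20, boundary: float = 0.6
) -> SelectedBatch:
    """The batch_size samples closest to the classification boundary.

    Pre-labels come from the score vs the boundary and are meant to be
    corrected by an oracle. Ties in distance are broken by sample ID.
    """
    if len(scored) == 0:
        raise ValueError("uncertainty selection on an empty pool")
    ids = list(scored.pool.sample_ids)
    s = scored.score
    order = sorted(range(len(ids)), key=lambda k: (abs(s[k] - boundary), ids[k]))
    take = order[: min(batch_size, len(ids))]
    return SelectedBatch(
        tuple(ids[k] for k in take),
        tuple(int(s[k] >= boundary) for k in take),
        tuple(s[k] for k in take),
        sup=boundary,
        inf=None,
        strategy="uncertainty",
    )


def random_select(scored: ScoredPool, batch_size: int = 20, seed: int = 0, boundary: float = 0.6) -> SelectedBatch:
    """Uniform sample without replacement; pre-labels from score vs boundary."""
    if len(scored) == 0:
        raise ValueError("random selection on an empty pool")
    rng = np.random.default_rng(seed)
    n = len(scored)
    take = sorted(rng.choice(n, size=min(batch_size, n), replace=False).tolist())
    ids = list(scored.pool.sample_ids)
    s = scored.score
    return SelectedBatch(
        tuple(ids[k] for k in take),
        tuple(int(s[k] >= boundary) for k in take),
        tuple(s[k] for k in take),
        sup=boundary,
        inf=None,
        strategy="random",
    )
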