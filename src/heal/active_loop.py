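"""Iteration engine for heuristic-enabled and classical active learning.

One iteration: SMOTE-balance the current labelled set, rank features by
out-of-bag permutation importance and keep the top k, train the gradient
boosting classifier, score the unlabelled pool, select a batch with the
configured strategy, label it (pseudo-labels for the certainty heuristic,
simulated-oracle truth for the benchmarks), move it from pool to labelled
set. The loop stops when the target fraction of the dataset is labelled,
when a selection comes back empty (stall), or at the iteration cap.
"""

from __future__ import annotations

import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.metrics import (
    accuracy_score,
    make_scorer,
    precision_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, cross_validate

from .data_model import IterationRecord, LabelledSet, Pool, RunConfig
from .preprocessing import select_top_features, smote_balance
from .strategies import (
    ScoredPool,
    SelectedBatch,
    heuristic_select,
    random_select,
    uncertainty_select,
)

logger = logging.getLogger("heal")


@contextmanager
def _quiet_lightgbm():
    # lightgbm registers synthetic column names even for ndarray input and
    # sklearn then warns on every ndarray predict; the warning is spurious
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        yield


@dataclass(frozen=True)
class Metrics:
    """Confusion counts plus the three headline scores."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float | None
    roc_auc: float | None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "roc_auc": self.roc_auc,
        }


@dataclass(frozen=True)
class AnnotationResult:
    """Final state of an annotation run plus its full history."""

    final_labelled: LabelledSet
    residual_pool: Pool
    history: tuple
    status: str  # completed | stalled | max_iter

    def __post_init__(self):
        if self.status not in ("completed", "stalled", "max_iter"):
            raise ValueError(f"unknown status {self.status!r}")
        object.__setattr__(self, "history", tuple(self.history))

    @property
    def assigned_ids(self) -> tuple:
        """Sample IDs labelled during the run (non-initial provenance)."""
        return tuple(
            s
            for s, tag in zip(self.final_labelled.sample_ids, self.final_labelled.provenance)
            if tag in ("pseudo", "oracle")
        )

    def assigned_labels(self) -> dict:
        lab = dict(zip(self.final_labelled.sample_ids, map(int, self.final_labelled.labels)))
        return {s: lab[s] for s in self.assigned_ids}


class TrainingError(RuntimeError):
    """Classifier training failed; carries partial loop history if any."""

    def __init__(self, message: str, history: tuple = ()):
        super().__init__(message)
        self.history = tuple(history)


def train_classifier(
    labelled: LabelledSet, params: dict | None = None, seed: int = 0, cv_folds: int = 5
) -> tuple[LGBMClassifier, dict]:
    """Fit the gradient boosting classifier and report k-fold CV scores.

    CV (stratified) is for reporting only; the returned model is refit on
    the full set. Folds are capped by the smaller class count.
    """
    if not labelled.has_both_classes():
        raise TrainingError("cannot train: only one class present")
    params = dict(params) if params else {}
    x, y = labelled.table.values, labelled.labels
    model = LGBMClassifier(**params, random_state=seed, verbose=-1)
    n_folds = min(cv_folds, min(labelled.class_counts()))
    cv_scores: dict[str, float] = {}
    if n_folds >= 2:
        with _quiet_lightgbm():
            cv = cross_validate(
                LGBMClassifier(**params, random_state=seed, verbose=-1),
                x,
                y,
                cv=StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed),
                scoring={
                    "accuracy": "accuracy",
                    "precision": make_scorer(precision_score, zero_division=0),
                    "roc_auc": "roc_auc",
                },
                error_score="raise",
            )
        cv_scores = {
            "accuracy": float(np.mean(cv["test_accuracy"])),
            "precision": float(np.mean(cv["test_precision"])),
            "roc_auc": float(np.mean(cv["test_roc_auc"])),
        }
    model.fit(x, y)
    return model, cv_scores


def compute_metrics(predicted, scores, truth) -> Metrics:
    """Confusion-matrix metrics at given hard labels, AUC from scores."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.size == 0 or predicted.shape != truth.shape:
        raise ValueError("predicted and truth must be aligned, non-empty")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    acc = float(accuracy_score(truth, predicted))
    prec = None if tp + fp == 0 else float(precision_score(truth, predicted, zero_division=0))
    auc = None
    if scores is not None and len(np.unique(truth)) == 2:
        auc = float(roc_auc_score(truth, np.asarray(scores, dtype=float)))
    return Metrics(tp, fp, tn, fn, acc, prec, auc)


def simulated_oracle(batch: SelectedBatch, truth: dict) -> SelectedBatch:
    """Replace every pre-label with the ground truth (the 'human expert')."""
    missing = [s for s in batch.sample_ids if s not in truth]
    if missing:
        raise KeyError(f"truth missing for batch samples: {missing[:5]}")
    return SelectedBatch(
        batch.sample_ids,
        tuple(int(truth[s]) for s in batch.sample_ids),
        batch.scores,
        sup=batch.sup,
        inf=batch.inf,
        strategy=batch.strategy,
    )


def _iteration_seed(seed: int, alpha: int) -> int:
    """Deterministic per-iteration stream, independent across alpha."""
    return int(np.random.SeedSequence([seed, alpha]).generate_state(1)[0] % (2**31 - 1))


def _top1_fallback(scored: ScoredPool, boundary: float) -> SelectedBatch:
    """Stall fallback: the single most extreme sample on each side."""
    ids = list(scored.pool.sample_ids)
    s = scored.score
    chosen: list[int] = []
    labels: list[int] = []
    plus = [k for k in range(len(ids)) if s[k] >= boundary]
    minus = [k for k in range(len(ids)) if s[k] < boundary]
    if plus:
        chosen.append(max(plus, key=lambda k: (s[k], ids[k])))
        labels.append(1)
    if minus:
        chosen.append(min(minus, key=lambda k: (s[k], ids[k])))
        labels.append(0)
    return SelectedBatch(
        tuple(ids[k] for k in chosen), tuple(labels), tuple(s[k] for k in chosen),
        sup=boundary, inf=None, strategy="certainty",
    )


def _run_loop(
    labelled: LabelledSet,
    pool: Pool,
    config: RunConfig,
    strategy: str,
    truth: dict | None,
) -> AnnotationResult:
    if strategy in ("uncertainty", "random") and truth is None:
        raise ValueError(f"strategy {strategy!r} needs a simulated oracle (truth labels)")
    overlap = set(labelled.sample_ids) & set(pool.sample_ids)
    if overlap:
        raise ValueError(f"pool IDs overlap labelled set: {sorted(overlap)[:5]}")

    total = len(labelled) + len(pool)
    history: list[IterationRecord] = []
    alpha = 0
    status = "completed"
    while True:
        frac = len(labelled) / total
        if frac >= config.stop_fraction or len(pool) == 0:
            status = "completed"
            break
        alpha += 1
        if alpha > config.max_iterations:
            status = "max_iter"
            break
        it_seed = _iteration_seed(config.seed, alpha)

        try:
            balanced = smote_balance(labelled, seed=it_seed)
            ranking = select_top_features(
                balanced, k=config.top_k_features, seed=it_seed
            )
            kept = ranking.top(config.top_k_features)
            model, cv_scores = train_classifier(
                balanced.select_features(kept), config.classifier_params, seed=it_seed
            )
        except (TrainingError, ValueError) as exc:
            raise TrainingError(str(exc), history=tuple(history)) from exc

        pool_x = pool.table.select_features(kept).values
        with _quiet_lightgbm():
            scored = ScoredPool(pool, model.predict_proba(pool_x)[:, 1])

        if strategy == "certainty":
            batch = heuristic_select(scored, config.threshold, config.boundary)
            if len(batch) == 0 and config.stall_fallback == "top1":
                batch = _top1_fallback(scored, config.boundary)
        elif strategy == "uncertainty":
            batch = uncertainty_select(scored, config.batch_size, config.boundary)
        else:
            batch = random_select(scored, config.batch_size, seed=it_seed, boundary=config.boundary)

        if strategy in ("uncertainty", "random"):
            batch = simulated_oracle(batch, truth)
            tag = "oracle"
        else:
            tag = "pseudo"

        if len(batch) == 0:
            status = "stalled"
            break

        labelled = labelled.append(
            pool.table.select_samples(list(batch.sample_ids)),
            list(batch.pseudo_labels),
            tag,
        )
        pool = pool.remove(batch.sample_ids)
        record = IterationRecord(
            alpha=alpha,
            sup=batch.sup,
            inf=batch.inf,
            n_selected=len(batch),
            n_pos_selected=batch.n_positive,
            n_neg_selected=batch.n_negative,
            classifier_cv_scores=cv_scores,
            labelled_fraction=len(labelled) / total,
        )
        history.append(record)
        logger.info(record.format_log_line())

    return AnnotationResult(labelled, pool, tuple(history), status)


def run_heal(labelled: LabelledSet, pool: Pool, config: RunConfig) -> AnnotationResult:
    """Run the heuristic-enabled loop: pseudo-labels, no human oracle."""
    return _run_loop(labelled, pool, config, "certainty", truth=None)


def run_active_learning(
    labelled: LabelledSet,
    pool: Pool,
    config: RunConfig,
    strategy: str,
    truth: dict | None = None,
) -> AnnotationResult:
    """Run any of the three strategies; benchmarks need ``truth`` for the oracle."""
    if strategy not in ("certainty", "uncertainty", "random"):
        raise ValueError(f"unknown strategy {strategy!r}")
    return _run_loop(labelled, pool, config, strategy, truth)


def run_benchmark(
    dataset: LabelledSet, strategy: str, config: RunConfig, labelled_fraction: float = 0.2
):
    """Benchmark protocol on a fully labelled dataset.

    A stratified fraction (default 20%) seeds the labelled set, the rest
    becomes the pool with labels hidden. The loop runs with the chosen
    strategy; annotation metrics compare every label assigned during the
    run with the held-back truth, residual metrics evaluate a final
    classifier (trained on the accumulated labelled set) on the samples
    still unlabelled at stop.

    Returns (AnnotationResult, metrics_annotation, metrics_residual);
    either metrics is None when its evaluation set is empty.
    """
    from .data_model import split_labelled_pool

    seed_set, pool, truth = split_labelled_pool(dataset, labelled_fraction, config.seed)
    result = run_active_learning(seed_set, pool, config, strategy, truth)

    assigned = result.assigned_labels()
    metrics_annotation = None
    if assigned:
        ids = list(assigned)
        metrics_annotation = compute_metrics(
            [assigned[s] for s in ids], None, [truth[s] for s in ids]
        )

    metrics_residual = None
    if len(result.residual_pool) > 0:
        it_seed = _iteration_seed(config.seed, max(len(result.history) + 1, 1))
        balanced = smote_balance(result.final_labelled, seed=it_seed)
        ranking = select_top_features(balanced, k=config.top_k_features, seed=it_seed)
        kept = ranking.top(config.top_k_features)
        model, _ = train_classifier(
            balanced.select_features(kept), config.classifier_params, seed=it_seed
        )
        res_x = result.residual_pool.table.select_features(kept).values
        with _quiet_lightgbm():
            scores = model.predict_proba(res_x)[:, 1]
        predicted = (scores >= config.boundary).astype(int)
        res_truth = [truth[s] for s in result.residual_pool.sample_ids]
        metrics_residual = compute_metrics(predicted, scores, res_truth)

    return result, metrics_annotation, metrics_residual
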