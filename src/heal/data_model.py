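"""Core data containers and file I/O for the annotation pipeline.

The universal carrier is the :class:`FeatureTable`, a samples x features
matrix of finite floats with unique sample IDs and feature names. A
:class:`LabelledSet` pairs a table with binary labels (and a provenance tag
per sample recording how each label was obtained); a :class:`Pool` is the
unlabelled candidate set awaiting annotation.

File formats are deliberately plain: CSV feature tables (header row, one
sample per row), GMT gene-set collections, two-column p-value CSVs and
whitespace-separated network edge lists.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

PROVENANCE_TAGS = ("initial", "pseudo", "oracle", "synthetic")

#: LightGBM hyperparameters used for the gene-essentiality application.
DEFAULT_CLASSIFIER_PARAMS: dict = {
    "n_estimators": 600,
    "learning_rate": 0.05,
    "num_leaves": 32,
    "colsample_bytree": 0.2,
    "reg_alpha": 3,
    "reg_lambda": 1,
    "min_split_gain": 0.01,
    "min_child_weight": 40,
}


def small_data_classifier_params() -> dict:
    """LightGBM profile for small, low-dimensional training sets.

    The default hyperparameters target very wide feature tables with
    hundreds of labelled rows; ``min_child_weight=40`` (a minimum
    sum-of-hessians per leaf; the log-loss hessian is at most 0.25 per
    sample) forbids any split until a node holds ~160 samples, so on a
    table of a few dozen rows the booster degenerates to a constant.
    Simulation-scale runs should use this profile instead: it keeps the
    default boosting settings (including the per-tree feature subsampling
    that forces the ensemble to spread over features) and relaxes only
    the two leaf-size floors that assume a large training set.
    """
    return {
        **DEFAULT_CLASSIFIER_PARAMS,
        "min_child_weight": 1e-3,
        "min_child_samples": 5,
    }


class ConfigurationError(ValueError):
    """A run or file configuration is invalid (e.g. missing label column)."""


class IngestionError(ValueError):
    """Input data violates the format contract (e.g. non-numeric cell)."""


@dataclass(frozen=True)
class FeatureTable:
    """Immutable samples x features matrix with named rows and columns."""

    sample_ids: tuple
    feature_names: tuple
    values: np.ndarray  # (n_samples, n_features) float64

    def __post_init__(self):
        ids = tuple(self.sample_ids)
        names = tuple(str(n) for n in self.feature_names)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise IngestionError("feature matrix must be 2-dimensional")
        if vals.shape != (len(ids), len(names)):
            raise IngestionError(
                f"matrix shape {vals.shape} does not match "
                f"{len(ids)} samples x {len(names)} features"
            )
        if len(set(ids)) != len(ids):
            raise IngestionError("duplicate sample IDs")
        if len(set(names)) != len(names):
            raise IngestionError("duplicate feature names")
        if not np.all(np.isfinite(vals)):
            raise IngestionError("non-finite value in feature matrix")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "values", vals)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.sample_ids), columns=list(self.feature_names)
        )

    def select_samples(self, ids: Sequence) -> "FeatureTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return FeatureTable(tuple(ids), self.feature_names, self.values[idx])

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        pos = {f: j for j, f in enumerate(self.feature_names)}
        idx = [pos[n] for n in names]
        return FeatureTable(self.sample_ids, tuple(names), self.values[:, idx])


@dataclass(frozen=True)
class LabelledSet:
    """A FeatureTable with aligned binary labels and provenance tags."""

    table: FeatureTable
    labels: np.ndarray  # (n_samples,) of {0,1}
    provenance: tuple = ()

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        if labels.shape != (self.table.n_samples,):
            raise IngestionError("labels not aligned 1:1 with table rows")
        if labels.size and not np.isin(labels, (0, 1)).all():
            raise IngestionError("labels must be binary {0,1}")
        prov = tuple(self.provenance) or ("initial",) * self.table.n_samples
        if len(prov) != self.table.n_samples:
            raise IngestionError("provenance not aligned with table rows")
        bad = set(prov) - set(PROVENANCE_TAGS)
        if bad:
            raise IngestionError(f"unknown provenance tags: {sorted(bad)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "provenance", prov)

    def __len__(self) -> int:
        return self.table.n_samples

    @property
    def sample_ids(self) -> tuple:
        return self.table.sample_ids

    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def has_both_classes(self) -> bool:
        n0, n1 = self.class_counts()
        return n0 > 0 and n1 > 0

    def append(
        self, table: FeatureTable, labels: Sequence[int], provenance_tag: str
    ) -> "LabelledSet":
        """New LabelledSet with the given rows appended."""
        if table.feature_names != self.table.feature_names:
            raise IngestionError("feature columns differ between sets")
        merged = FeatureTable(
            self.table.sample_ids + table.sample_ids,
            self.table.feature_names,
            np.vstack([self.table.values, table.values]),
        )
        return LabelledSet(
            merged,
            np.concatenate([self.labels, np.asarray(labels, dtype=int)]),
            self.provenance + (provenance_tag,) * table.n_samples,
        )

    def select_features(self, names: Sequence[str]) -> "LabelledSet":
        return LabelledSet(self.table.select_features(names), self.labels, self.provenance)


@dataclass(frozen=True)
class Pool:
    """Unlabelled candidate set U; IDs must be disjoint from its LabelledSet."""

    table: FeatureTable

    def __len__(self) -> int:
        return self.table.n_samples

    @property
    def sample_ids(self) -> tuple:
        return self.table.sample_ids

    def remove(self, ids: Iterable) -> "Pool":
        drop = set(ids)
        keep = [s for s in self.table.sample_ids if s not in drop]
        return Pool(self.table.select_samples(keep))


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of an annotation run.

    ``boundary`` splits predicted probabilities into positive/negative
    sides, ``threshold`` is the user confidence floor of the heuristic,
    ``batch_size`` applies to the benchmark (uncertainty/random)
    strategies only, and the run stops once ``stop_fraction`` of the full
    dataset carries a label.
    """

    boundary: float = 0.6
    threshold: float = 0.9
    batch_size: int = 20
    stop_fraction: float = 0.90
    top_k_features: int = 400
    corr_cutoff: float = 0.70
    jaccard_tau: float = 0.3
    classifier_params: Mapping = field(default_factory=lambda: dict(DEFAULT_CLASSIFIER_PARAMS))
    seed: int = 0
    max_iterations: int = 100
    stall_fallback: str = "stop"  # "stop" | "top1"

    def __post_init__(self):
        if not 0 < self.boundary < 1:
            raise ConfigurationError("boundary must be in (0,1)")
        if not 0 < self.threshold <= 1:
            raise ConfigurationError("threshold must be in (0,1]")
        if self.threshold < self.boundary:
            raise ConfigurationError("threshold must be >= boundary")
        if not 0 < self.stop_fraction <= 1:
            raise ConfigurationError("stop_fraction must be in (0,1]")
        if self.batch_size < 1 or self.top_k_features < 1:
            raise ConfigurationError("batch_size and top_k_features must be positive")
        if self.stall_fallback not in ("stop", "top1"):
            raise ConfigurationError("stall_fallback must be 'stop' or 'top1'")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a flat YAML or INI key/value file; kwargs override the file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml", ".json"):
            raw = yaml.safe_load(text) or {}
        else:
            parser = configparser.ConfigParser()
            parser.read_string(text)
            raw = {k: yaml.safe_load(v) for section in parser.sections() for k, v in parser[section].items()}
        raw.update(overrides)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class IterationRecord:
    """Per-iteration log record of the annotation loop."""

    alpha: int
    sup: float
    inf: float | None
    n_selected: int
    n_pos_selected: int
    n_neg_selected: int
    classifier_cv_scores: Mapping[str, float]
    labelled_fraction: float

    def __post_init__(self):
        if self.n_selected != self.n_pos_selected + self.n_neg_selected:
            raise ValueError("n_selected must equal n_pos_selected + n_neg_selected")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "sup": self.sup,
            "inf": self.inf,
            "n_selected": self.n_selected,
            "n_pos_selected": self.n_pos_selected,
            "n_neg_selected": self.n_neg_selected,
            "classifier_cv_scores": dict(self.classifier_cv_scores),
            "labelled_fraction": self.labelled_fraction,
        }

    def format_log_line(self) -> str:
        cv = " ".join(f"cv_{k}={v:.4f}" for k, v in self.classifier_cv_scores.items())
        inf = "na" if self.inf is None else f"{self.inf:.6g}"
        return (
            f"iter={self.alpha} sup={self.sup:.6g} inf={inf} "
            f"n_selected={self.n_selected} n_pos={self.n_pos_selected} "
            f"n_neg={self.n_neg_selected} {cv} "
            f"labelled_fraction={self.labelled_fraction:.4f}"
        )


# ---------------------------------------------------------------------------
# CSV feature-table I/O
# ---------------------------------------------------------------------------

def load_dataset(
    path: str | Path,
    label_column: str,
    positive_label,
    id_column: str | None = None,
    impute_missing: bool = False,
) -> tuple[LabelledSet, Pool]:
    """Partition a CSV into labelled rows and unlabelled pool rows.

    Rows whose ``label_column`` is non-empty become the LabelledSet (the
    value equal to ``positive_label`` maps to 1, everything else to 0);
    rows with an empty label go to the Pool. Missing feature values are
    an error unless ``impute_missing`` requests column-mean imputation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={label_column: str} if label_column else None)
    if label_column not in df.columns:
        raise ConfigurationError(f"label column {label_column!r} not found in {path.name}")
    if id_column is not None:
        if id_column not in df.columns:
            raise ConfigurationError(f"id column {id_column!r} not found in {path.name}")
        ids = [str(v) for v in df[id_column]]
        df = df.drop(columns=[id_column])
    else:
        ids = [str(i) for i in range(len(df))]

    label_raw = df[label_column]
    feat = df.drop(columns=[label_column])
    for col in feat.columns:
        coerced = pd.to_numeric(feat[col], errors="coerce")
        bad = coerced.isna() & feat[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise IngestionError(
                f"non-numeric feature value at row {ids[row]!r}, column {col!r}"
            )
        feat[col] = coerced
    if feat.isna().any().any():
        if not impute_missing:
            col = feat.columns[feat.isna().any()][0]
            row = int(np.flatnonzero(feat[col].isna().to_numpy())[0])
            raise IngestionError(
                f"missing feature value at row {ids[row]!r}, column {col!r} "
                "(pass impute_missing=True for mean imputation)"
            )
        feat = feat.fillna(feat.mean())

    has_label = label_raw.notna() & (label_raw.astype(str).str.strip() != "")
    if not has_label.any():
        raise ConfigurationError("no labelled rows in input")
    feat.index = ids
    labelled_df = feat.loc[has_label.to_numpy()]
    pool_df = feat.loc[(~has_label).to_numpy()]
    y = (label_raw[has_label].astype(str).str.strip() == str(positive_label)).astype(int)
    labelled = LabelledSet(FeatureTable.from_dataframe(labelled_df), y.to_numpy())
    return labelled, Pool(FeatureTable.from_dataframe(pool_df))


def write_labelled(
    labelled: LabelledSet,
    path: str | Path,
    label_column: str = "label",
    id_column: str = "sample_id",
    provenance_column: str | None = None,
) -> None:
    """Write a LabelledSet back to CSV (inverse of :func:`load_dataset`)."""
    df = labelled.table.to_dataframe()
    df.insert(0, id_column, list(labelled.sample_ids))
    df[label_column] = labelled.labels
    if provenance_column:
        df[provenance_column] = list(labelled.provenance)
    df.to_csv(path, index=False)


def split_labelled_pool(
    dataset: LabelledSet, labelled_fraction: float, seed: int
) -> tuple[LabelledSet, Pool, dict]:
    """Hold out ``1 - labelled_fraction`` of a fully labelled dataset as pool.

    The split is stratified by class so both classes are represented in
    the seed labelled set; the ground-truth labels of pool samples are
    returned for the simulated oracle and for evaluation.
    """
    if not 0 < labelled_fraction < 1:
        raise ConfigurationError("labelled_fraction must be in (0,1)")
    ids = np.array(dataset.sample_ids, dtype=object)
    try:
        lab_ids, pool_ids = train_test_split(
            ids,
            train_size=labelled_fraction,
            stratify=dataset.labels,
            random_state=seed,
        )
    except ValueError as exc:
        raise ConfigurationError(
            "labelled fraction too small to keep both classes; increase it"
        ) from exc
    lab_ids, pool_ids = list(lab_ids), list(pool_ids)
    label_of = dict(zip(dataset.sample_ids, (int(v) for v in dataset.labels)))
    labelled = LabelledSet(
        dataset.table.select_samples(lab_ids),
        np.array([label_of[s] for s in lab_ids]),
    )
    if not labelled.has_both_classes():
        raise ConfigurationError(
            "a class is absent from the labelled part; increase labelled_fraction"
        )
    pool = Pool(dataset.table.select_samples(pool_ids))
    truth = {s: label_of[s] for s in pool_ids}
    return labelled, pool, truth


# ---------------------------------------------------------------------------
# GMT / p-value / edge-list I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set]:
    """Read a GMT file: tab-separated set_id, description, member genes."""
    sets: dict[str, set] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise IngestionError(f"{path}: line {ln}: expected >=3 tab-separated fields")
        set_id, _desc, *genes = parts
        if set_id in sets:
            raise IngestionError(f"{path}: duplicate set id {set_id!r}")
        members = {g for g in genes if g}
        if not members:
            raise IngestionError(f"{path}: line {ln}: gene set {set_id!r} is empty")
        sets[set_id] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable], path: str | Path, descriptions: Mapping | None = None) -> None:
    lines = []
    for set_id, genes in sets.items():
        desc = (descriptions or {}).get(set_id, "na")
        lines.append("\t".join([set_id, str(desc), *sorted(map(str, genes))]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pvalues(path: str | Path) -> dict[str, float]:
    """Two-column CSV (set_id, p) with a header row."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise IngestionError(f"{path}: expected two columns (set_id, p)")
    out = {}
    for set_id, p in zip(df.iloc[:, 0], pd.to_numeric(df.iloc[:, 1], errors="coerce")):
        if not np.isfinite(p) or not 0 < p <= 1:
            raise IngestionError(f"{path}: invalid p-value for set {set_id!r}")
        out[str(set_id)] = float(p)
    return out


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Whitespace/tab edge list; an optional third score column is ignored."""
    edges = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise IngestionError(f"{path}: line {ln}: expected at least two columns")
        a, b = parts[0], parts[1]
        if a != b:
            edges.append((a, b))
    return edges


def write_edge_list(edges: Iterable[tuple], path: str | Path) -> None:
    Path(path).write_text("\n".join(f"{a}\t{b}" for a, b in edges) + "\n")
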