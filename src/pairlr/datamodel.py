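"""Domain types and I/O: feature tables, pipeline configuration, trained models.

The central container is :class:`FeatureTable`, a sample-by-feature numeric
matrix with string sample ids, feature names, per-feature kind tags
(``radiomics`` or ``clinical``) and an optional binary outcome label per
sample (1 = event, e.g. locoregional recurrence; 0 = no event).

Feature tables travel as plain CSV (comma-separated, mandatory header, UTF-8,
decimal point); trained models travel as JSON with an explicit format-version
field. Reading never mutates values: no imputation or scaling happens at
ingestion.
"""

from __future__ import annotations

import base64
import json
import logging
import pickle
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pairlr")

MODEL_FORMAT_VERSION = 1

NORMALIZATION_SCHEMES = ("unit", "zero_center", "unit_zero_center")
REDUCTIONS = ("pcc", "pca", "none")
SCREENERS = ("anova", "rfe", "relief")
CLASSIFIERS = (
    "gaussian_nb",
    "logistic",
    "svm_linear",
    "svm_rbf",
    "lda",
    "knn",
    "decision_tree",
    "random_forest",
    "adaboost",
    "gaussian_process",
)
TEMPLATE_STRATEGIES = ("medoid", "random", "manual")


class PairlrError(ValueError):
    """Base error for invalid inputs or contract violations."""


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Sample-by-feature numeric matrix with ids, names and optional labels.

    Invariants: unique sample ids, unique feature names, finite values,
    labels (when present) in {0, 1}.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    feature_kinds: list[str] = field(default_factory=list)
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PairlrError("values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.sample_ids) != n:
            raise PairlrError(f"{len(self.sample_ids)} ids for {n} rows")
        if len(self.feature_names) != d:
            raise PairlrError(f"{len(self.feature_names)} names for {d} columns")
        if len(set(self.sample_ids)) != n:
            dup = _first_duplicate(self.sample_ids)
            raise PairlrError(f"duplicate sample id {dup!r}")
        if len(set(self.feature_names)) != d:
            dup = _first_duplicate(self.feature_names)
            raise PairlrError(f"duplicate feature name {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise PairlrError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )
        if not self.feature_kinds:
            self.feature_kinds = ["radiomics"] * d
        if len(self.feature_kinds) != d:
            raise PairlrError("feature_kinds length mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise PairlrError("labels length mismatch")
            bad = set(np.unique(self.labels)) - {0, 1}
            if bad:
                raise PairlrError(f"labels outside {{0,1}}: {sorted(bad)}")
            self.labels = self.labels.astype(int)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        """Return a new table restricted to ``names``, in the given order."""
        index = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in index]
        if missing:
            raise PairlrError(f"missing feature column(s): {missing}")
        cols = [index[f] for f in names]
        return FeatureTable(
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            values=self.values[:, cols],
            feature_kinds=[self.feature_kinds[j] for j in cols],
            labels=None if self.labels is None else self.labels.copy(),
        )

    def select_samples(self, indices: Sequence[int]) -> "FeatureTable":
        idx = list(indices)
        return FeatureTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=list(self.feature_names),
            values=self.values[idx, :],
            feature_kinds=list(self.feature_kinds),
            labels=None if self.labels is None else self.labels[idx],
        )

    def to_dataframe(self, id_column: str = "sample_id",
                     label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, id_column, self.sample_ids)
        if self.labels is not None:
            df.insert(1, label_column, self.labels)
        return df


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def read_feature_table(
    path: str | Path,
    id_column: str = "sample_id",
    label_column: Optional[str] = "label",
    feature_kinds: Optional[dict[str, str]] = None,
    drop_incomplete: bool = False,
) -> FeatureTable:
    """Read a feature table from CSV.

    All columns other than the id and label columns are parsed as numeric
    features. Missing cells are rejected unless ``drop_incomplete``, which
    removes the offending rows and logs how many were dropped.
    """
    path = Path(path)
    if not path.exists():
        raise PairlrError(f"no such file: {path}")
    df = pd.read_csv(path, encoding="utf-8")
    if id_column not in df.columns:
        raise PairlrError(f"id column {id_column!r} not found in {path.name}")
    if label_column is not None and label_column not in df.columns:
        label_column = None
    feature_cols = [c for c in df.columns if c not in (id_column, label_column)]
    if drop_incomplete:
        before = len(df)
        df = df.dropna(subset=feature_cols + ([label_column] if label_column else []))
        dropped = before - len(df)
        if dropped:
            logger.info("dropped %d incomplete row(s) from %s", dropped, path.name)
    for col in feature_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = df.loc[bad, id_column].iloc[0]
            raise PairlrError(
                f"non-numeric value in feature {col!r} at sample {row!r}"
            )
        if parsed.isna().any():
            row = df.loc[parsed.isna(), id_column].iloc[0]
            raise PairlrError(
                f"missing value in feature {col!r} at sample {row!r} "
                "(use drop_incomplete to remove such rows)"
            )
        df[col] = parsed
    labels = None
    if label_column is not None:
        lab = pd.to_numeric(df[label_column], errors="coerce")
        if lab.isna().any() or not set(lab.unique()) <= {0, 1}:
            raise PairlrError(f"label column {label_column!r} has values outside {{0,1}}")
        labels = lab.to_numpy(dtype=int)
    kinds = None
    if feature_kinds:
        kinds = [feature_kinds.get(c, "radiomics") for c in feature_cols]
    return FeatureTable(
        sample_ids=df[id_column].astype(str).tolist(),
        feature_names=feature_cols,
        values=df[feature_cols].to_numpy(dtype=float),
        feature_kinds=kinds or [],
        labels=labels,
    )


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    id_column: str = "sample_id",
    label_column: str = "label",
) -> None:
    table.to_dataframe(id_column, label_column).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PipelineConfig
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full modelling pipeline.

    Defaults follow the selected pNB scheme: normalisation to unit with
    zero-centre, Pearson-correlation redundancy filtering, ANOVA feature
    screening, 12 retained features, Gaussian naive Bayes pair classifier,
    7 templates, 7:3 train/test split, fivefold cross-validation.
    """

    normalization_scheme: str = "unit_zero_center"
    reduction: str = "pcc"
    pcc_threshold: float = 0.99
    screener: str = "anova"
    n_features: int = 12
    classifier: str = "gaussian_nb"
    n_templates: int = 7
    template_strategy: str = "medoid"
    manual_template_ids: Optional[tuple[str, ...]] = None
    pair_mode: str = "signed"  # or "absolute"
    decision_threshold: float = 0.5
    split_ratio: float = 0.7
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        _check_enum("normalization_scheme", self.normalization_scheme, NORMALIZATION_SCHEMES)
        _check_enum("reduction", self.reduction, REDUCTIONS)
        _check_enum("screener", self.screener, SCREENERS)
        _check_enum("classifier", self.classifier, CLASSIFIERS)
        _check_enum("template_strategy", self.template_strategy, TEMPLATE_STRATEGIES)
        _check_enum("pair_mode", self.pair_mode, ("signed", "absolute"))
        if not (0 < self.pcc_threshold <= 1):
            raise PairlrError("pcc_threshold must be in (0, 1]")
        if self.n_features < 1:
            raise PairlrError("n_features must be >= 1")
        if self.n_templates < 2:
            raise PairlrError("n_templates must be >= 2")
        if not (0 < self.split_ratio < 1):
            raise PairlrError("split_ratio must be in (0, 1)")
        if self.cv_folds < 2:
            raise PairlrError("cv_folds must be >= 2")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if d["manual_template_ids"] is not None:
            d["manual_template_ids"] = list(d["manual_template_ids"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("manual_template_ids") is not None:
            d["manual_template_ids"] = tuple(d["manual_template_ids"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PairlrError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


def _check_enum(name: str, value: str, allowed: tuple[str, ...]) -> None:
    if value not in allowed:
        raise PairlrError(f"{name} must be one of {allowed}, got {value!r}")


# ---------------------------------------------------------------------------
# TrainedPairwiseModel + JSON serialization
# ---------------------------------------------------------------------------

@dataclass
class TrainedPairwiseModel:
    """Frozen preprocessing + templates + fitted pair classifier.

    ``normalizer``, ``pca`` (optional), ``selected_features``, ``templates``
    and ``classifier`` are everything needed to score a new sample; all were
    fitted on the training partition only (``training_sample_ids`` records
    exactly which samples contributed, for leakage auditing).
    """

    config: PipelineConfig
    normalizer: "object"            # preprocess.NormalizerParams
    kept_features: list[str]        # after redundancy reduction
    selected_features: list[str]    # after screening, ordered
    templates: Optional["object"]   # pairing.TemplateSet; None for plain models
    classifier: "object"            # model.PairClassifier
    pca: Optional["object"] = None  # preprocess.PCAParams when reduction == "pca"
    decision_threshold: float = 0.5
    training_sample_ids: list[str] = field(default_factory=list)
    pairwise: bool = True
    version: int = MODEL_FORMAT_VERSION


def _array_to_json(a: np.ndarray) -> list:
    return np.asarray(a, dtype=float).tolist()


def save_model(model: TrainedPairwiseModel, path: str | Path) -> None:
    """Serialize a trained model to JSON (stable key order, versioned)."""
    from .pairing import TemplateSet  # local import to avoid cycles
    from .preprocess import NormalizerParams, PCAParams

    norm: NormalizerParams = model.normalizer
    payload = {
        "format_version": model.version,
        "pairwise": model.pairwise,
        "config": model.config.to_dict(),
        "normalizer": {
            "scheme": norm.scheme,
            "feature_names": norm.feature_names,
            "center": _array_to_json(norm.center),
            "scale": _array_to_json(norm.scale),
            "constant_features": norm.constant_features,
        },
        "kept_features": model.kept_features,
        "selected_features": model.selected_features,
        "decision_threshold": model.decision_threshold,
        "training_sample_ids": model.training_sample_ids,
        "classifier": _classifier_to_json(model.classifier),
        "templates": None,
        "pca": None,
    }
    if model.templates is not None:
        t: TemplateSet = model.templates
        payload["templates"] = {
            "sample_ids": t.sample_ids,
            "labels": [int(x) for x in t.labels],
            "vectors": _array_to_json(t.vectors),
            "strategy": t.strategy,
        }
    if model.pca is not None:
        p: PCAParams = model.pca
        payload["pca"] = {
            "mean": _array_to_json(p.mean),
            "components": _array_to_json(p.components),
            "explained_variance_ratio": _array_to_json(p.explained_variance_ratio),
            "input_features": p.input_features,
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)


def load_model(path: str | Path) -> TrainedPairwiseModel:
    from .pairing import TemplateSet
    from .preprocess import NormalizerParams, PCAParams

    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise PairlrError(f"cannot parse model file {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise PairlrError(
            f"model format version {version!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    norm = NormalizerParams(
        scheme=payload["normalizer"]["scheme"],
        feature_names=list(payload["normalizer"]["feature_names"]),
        center=np.asarray(payload["normalizer"]["center"], dtype=float),
        scale=np.asarray(payload["normalizer"]["scale"], dtype=float),
        constant_features=list(payload["normalizer"]["constant_features"]),
    )
    templates = None
    if payload["templates"] is not None:
        t = payload["templates"]
        templates = TemplateSet(
            sample_ids=list(t["sample_ids"]),
            labels=np.asarray(t["labels"], dtype=int),
            vectors=np.asarray(t["vectors"], dtype=float),
            strategy=t["strategy"],
        )
    pca = None
    if payload["pca"] is not None:
        p = payload["pca"]
        pca = PCAParams(
            mean=np.asarray(p["mean"], dtype=float),
            components=np.asarray(p["components"], dtype=float),
            explained_variance_ratio=np.asarray(p["explained_variance_ratio"], dtype=float),
            input_features=list(p["input_features"]),
        )
    return TrainedPairwiseModel(
        config=PipelineConfig.from_dict(payload["config"]),
        normalizer=norm,
        kept_features=list(payload["kept_features"]),
        selected_features=list(payload["selected_features"]),
        templates=templates,
        classifier=_classifier_from_json(payload["classifier"]),
        pca=pca,
        decision_threshold=payload["decision_threshold"],
        training_sample_ids=list(payload["training_sample_ids"]),
        pairwise=payload["pairwise"],
        version=version,
    )


def _classifier_to_json(clf) -> dict:
    """GaussianNB gets an explicit parameter dump; other families a pickle blob."""
    from sklearn.naive_bayes import GaussianNB

    est = clf.estimator
    if isinstance(est, GaussianNB):
        return {
            "family": clf.family,
            "kind": "gaussian_nb",
            "classes": [int(c) for c in est.classes_],
            "theta": _array_to_json(est.theta_),
            "var": _array_to_json(est.var_),
            "class_prior": _array_to_json(est.class_prior_),
            "class_count": _array_to_json(est.class_count_),
            "epsilon": float(est.epsilon_),
            "var_smoothing": float(est.var_smoothing),
        }
    blob = base64.b64encode(pickle.dumps(est, protocol=4)).decode("ascii")
    return {"family": clf.family, "kind": "pickle", "payload": blob}


def _classifier_from_json(d: dict):
    from sklearn.naive_bayes import GaussianNB

    from .model import PairClassifier

    if d["kind"] == "gaussian_nb":
        est = GaussianNB(var_smoothing=d["var_smoothing"])
        est.classes_ = np.asarray(d["classes"])
        est.theta_ = np.asarray(d["theta"], dtype=float)
        est.var_ = np.asarray(d["var"], dtype=float)
        est.class_prior_ = np.asarray(d["class_prior"], dtype=float)
        est.class_count_ = np.asarray(d["class_count"], dtype=float)
        est.epsilon_ = d["epsilon"]
        return PairClassifier(family=d["family"], estimator=est)
    est = pickle.loads(base64.b64decode(d["payload"]))
    return PairClassifier(family=d["family"], estimator=est)
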