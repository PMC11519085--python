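"""Pair classification, vote aggregation, and the end-to-end pipeline.

A pair classifier is an ordinary binary classifier trained on template-sample
difference vectors, predicting the probability ``P_PP`` that a pair is
positive (template and sample share the outcome class). A sample's evidence
is aggregated over templates: a template labelled 1 votes ``P_PP`` for the
sample being an event, a template labelled 0 votes ``1 − P_PP``; the mean of
these per-template scores is the sample probability ``P_i``, thresholded at
0.5 (ties go to class 1) for the hard class.

``fit_pipeline`` runs the full chain — normalize, redundancy-reduce, screen,
select templates, build pairs, fit the pair classifier — freezing every
data-dependent statistic from the training partition only. ``crossvalidate``
refits the whole chain inside each fold, and ``grid_optimize`` searches the
scheme grid by mean cross-validation AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datamodel import (
    FeatureTable,
    PairlrError,
    PipelineConfig,
    TrainedPairwiseModel,
)
from .pairing import PairSet, TemplateSet, build_pairs, select_templates
from .preprocess import apply_normalizer, fit_normalizer, pca_reduce, pcc_filter, screen

logger = logging.getLogger("pairlr")


# ---------------------------------------------------------------------------
# Pair classifier
# ---------------------------------------------------------------------------

@dataclass
class PairClassifier:
    """A fitted binary classifier over pair vectors.

    ``predict_ppp`` returns the positive-pair probability in [0, 1];
    the negative-pair probability is its complement.
    """

    family: str
    estimator: object

    def predict_ppp(self, vectors: np.ndarray) -> np.ndarray:
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        proba = self.estimator.predict_proba(vectors)
        classes = list(self.estimator.classes_)
        col = classes.index(1)
        return np.clip(proba[:, col], 0.0, 1.0)


def make_estimator(family: str, seed: int = 0):
    """Instantiate one of the ten compared classifier families."""
    if family == "gaussian_nb":
        return GaussianNB()  # var_smoothing acts as the variance floor
    if family == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if family == "svm_linear":
        return SVC(kernel="linear", probability=True, random_state=seed)
    if family == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if family == "lda":
        return LinearDiscriminantAnalysis()
    if family == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if family == "gaussian_process":
        return GaussianProcessClassifier(random_state=seed)
    raise PairlrError(f"unknown classifier family {family!r}")


def fit_pair_classifier(pairs: PairSet, family: str = "gaussian_nb",
                        seed: int = 0) -> PairClassifier:
    if pairs.pair_labels is None:
        raise PairlrError("pair labels required to fit a pair classifier")
    labels = np.asarray(pairs.pair_labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise PairlrError("both positive and negative pairs required")
    est = make_estimator(family, seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*converge.*")
        est.fit(pairs.vectors, labels)
    return PairClassifier(family=family, estimator=est)


# ---------------------------------------------------------------------------
# Vote aggregation
# ---------------------------------------------------------------------------

@dataclass
class VoteResult:
    """Aggregated per-sample vote: probability, class, template contributions."""

    sample_ids: list[str]
    probabilities: np.ndarray          # P_i per sample
    predicted: np.ndarray              # hard class per sample
    contributions: Optional[np.ndarray] = None  # (n_samples, n_templates) s_I
    threshold: float = 0.5


def aggregate_votes(
    pair_probs: Sequence[float],
    template_labels: Sequence[int],
    threshold: float = 0.5,
) -> tuple[float, int, np.ndarray]:
    """Aggregate one sample's per-template positive-pair probabilities.

    A template labelled 1 contributes ``s_I = P_PP``; a template labelled 0
    contributes ``s_I = 1 − P_PP``. ``P_i`` is the mean contribution and the
    class is 1 when ``P_i >= threshold`` (ties to class 1).

    Returns ``(P_i, predicted_class, contributions)``.
    """
    probs = np.asarray(pair_probs, dtype=float)
    labels = np.asarray(template_labels, dtype=int)
    if probs.size == 0:
        raise PairlrError("empty pair probability list")
    if probs.shape != labels.shape:
        raise PairlrError("one probability per template required")
    if np.any((probs < 0) | (probs > 1)):
        raise PairlrError("pair probabilities must lie in [0, 1]")
    if len(np.unique(labels)) < 2:
        logger.warning("templates cover a single class; votes are one-sided")
    s = np.where(labels == 1, probs, 1.0 - probs)
    p_i = float(s.mean())
    return p_i, int(p_i >= threshold), s


# ---------------------------------------------------------------------------
# Cohort splitting
# ---------------------------------------------------------------------------

def split_cohort(
    table: FeatureTable,
    labels: np.ndarray,
    ratio: float = 0.7,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/test split with largest-remainder per-stratum sizes.

    For the study cohort (n = 130, 64 events) a 0.7 ratio yields 91 training
    samples (45 events) and 39 test samples.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != table.n_samples:
        raise PairlrError("labels length mismatch")
    if not (0 < ratio < 1):
        raise PairlrError("ratio must be in (0, 1)")
    n = table.n_samples
    total_train = int(round(n * ratio))
    classes = sorted(np.unique(labels))
    quotas = {c: (labels == c).sum() * ratio for c in classes}
    alloc = {c: int(np.floor(quotas[c])) for c in classes}
    leftover = total_train - sum(alloc.values())
    for c in sorted(classes, key=lambda c: (-(quotas[c] - alloc[c]), c))[:leftover]:
        alloc[c] += 1
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        members = np.flatnonzero(labels == c)
        perm = rng.permutation(len(members))
        members = members[perm]
        train_idx.extend(members[: alloc[c]].tolist())
        test_idx.extend(members[alloc[c]:].tolist())
    train_idx.sort()
    test_idx.sort()
    train = table.select_samples(train_idx)
    test = table.select_samples(test_idx)
    train.labels = labels[train_idx]
    test.labels = labels[test_idx]
    return train, test


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _preprocess_fit(table: FeatureTable, labels: np.ndarray,
                    config: PipelineConfig):
    """Fit normalize -> reduce -> screen on training data; return frozen parts."""
    normalizer = fit_normalizer(table, config.normalization_scheme)
    normed = apply_normalizer(normalizer, table)
    pca_params = None
    if config.reduction == "pcc":
        kept = pcc_filter(normed, config.pcc_threshold)
        reduced = normed.select_features(kept)
    elif config.reduction == "pca":
        n_comp = min(normed.n_samples - 1, normed.n_features)
        reduced, pca_params = pca_reduce(normed, n_comp)
        kept = list(reduced.feature_names)
    else:
        kept = list(normed.feature_names)
        reduced = normed
    screening = screen(reduced, labels, config.screener, seed=config.seed)
    if config.n_features > len(screening.feature_names):
        raise PairlrError(
            f"n_features={config.n_features} exceeds the "
            f"{len(screening.feature_names)} features surviving reduction"
        )
    selected = screening.top(config.n_features)
    processed = reduced.select_features(selected)
    return normalizer, pca_params, kept, selected, processed, screening


def _preprocess_apply(model: TrainedPairwiseModel, table: FeatureTable) -> FeatureTable:
    normed = apply_normalizer(model.normalizer, table)
    if model.pca is not None:
        normed = model.pca.transform(normed)
    return normed.select_features(model.selected_features)


def fit_pipeline(
    train_table: FeatureTable,
    labels: Optional[np.ndarray] = None,
    config: Optional[PipelineConfig] = None,
) -> TrainedPairwiseModel:
    """Train the pairwise model end to end on a labelled training table."""
    config = config or PipelineConfig()
    if labels is None:
        labels = train_table.labels
    if labels is None:
        raise PairlrError("training labels required")
    labels = np.asarray(labels, dtype=int)
    normalizer, pca_params, kept, selected, processed, _ = _preprocess_fit(
        train_table, labels, config
    )
    templates = select_templates(
        processed,
        labels,
        n_templates=config.n_templates,
        strategy=config.template_strategy,
        manual_ids=config.manual_template_ids,
        seed=config.seed,
    )
    pairs = build_pairs(
        templates, processed, labels,
        exclude_self=True,
        absolute=config.pair_mode == "absolute",
    )
    clf = fit_pair_classifier(pairs, config.classifier, seed=config.seed)
    return TrainedPairwiseModel(
        config=config,
        normalizer=normalizer,
        kept_features=kept,
        selected_features=selected,
        templates=templates,
        classifier=clf,
        pca=pca_params,
        decision_threshold=config.decision_threshold,
        training_sample_ids=list(train_table.sample_ids),
        pairwise=True,
    )


def fit_plain_classifier(
    train_table: FeatureTable,
    labels: Optional[np.ndarray] = None,
    family: str = "gaussian_nb",
    config: Optional[PipelineConfig] = None,
) -> TrainedPairwiseModel:
    """Non-pairwise baseline: same preprocessing, classifier on sample vectors."""
    config = (config or PipelineConfig()).replace(classifier=family)
    if labels is None:
        labels = train_table.labels
    if labels is None:
        raise PairlrError("training labels required")
    labels = np.asarray(labels, dtype=int)
    normalizer, pca_params, kept, selected, processed, _ = _preprocess_fit(
        train_table, labels, config
    )
    est = make_estimator(family, config.seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*converge.*")
        est.fit(processed.values, labels)
    return TrainedPairwiseModel(
        config=config,
        normalizer=normalizer,
        kept_features=kept,
        selected_features=selected,
        templates=None,
        classifier=PairClassifier(family=family, estimator=est),
        pca=pca_params,
        decision_threshold=config.decision_threshold,
        training_sample_ids=list(train_table.sample_ids),
        pairwise=False,
    )


def predict(model: TrainedPairwiseModel, table: FeatureTable) -> VoteResult:
    """Score new samples with a trained (pairwise or plain) model."""
    processed = _preprocess_apply(model, table)
    if not model.pairwise:
        probs = model.classifier.predict_ppp(processed.values)
        return VoteResult(
            sample_ids=list(processed.sample_ids),
            probabilities=probs,
            predicted=(probs >= model.decision_threshold).astype(int),
            contributions=None,
            threshold=model.decision_threshold,
        )
    templates: TemplateSet = model.templates
    n, t = processed.n_samples, templates.n_templates
    # pair every incoming sample with every stored template
    diffs = templates.vectors[None, :, :] - processed.values[:, None, :]
    if model.config.pair_mode == "absolute":
        diffs = np.abs(diffs)
    flat = diffs.reshape(n * t, -1)
    ppp = model.classifier.predict_ppp(flat).reshape(n, t)
    contributions = np.where(templates.labels[None, :] == 1, ppp, 1.0 - ppp)
    p_i = contributions.mean(axis=1)
    return VoteResult(
        sample_ids=list(processed.sample_ids),
        probabilities=p_i,
        predicted=(p_i >= model.decision_threshold).astype(int),
        contributions=contributions,
        threshold=model.decision_threshold,
    )


# ---------------------------------------------------------------------------
# Cross-validation and grid optimization
# ---------------------------------------------------------------------------

def crossvalidate(
    train_table: FeatureTable,
    labels: Optional[np.ndarray] = None,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Stratified k-fold CV, refitting the entire pipeline per fold.

    Screening, normalization and template selection are all refitted on the
    k−1 training folds only, so validation metrics carry no leakage. Returns
    per-fold and mean AUC/accuracy for both the fold-training and validation
    sides, plus the audited training ids per fold.
    """
    from .evaluation import confusion_metrics, roc_auc

    config = config or PipelineConfig()
    if labels is None:
        labels = train_table.labels
    if labels is None:
        raise PairlrError("labels required for cross-validation")
    labels = np.asarray(labels, dtype=int)
    counts = [(labels == c).sum() for c in np.unique(labels)]
    if min(counts) < config.cv_folds:
        raise PairlrError(
            f"a class has only {min(counts)} members; "
            f"use fewer than {config.cv_folds} folds"
        )
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    folds = []
    for fold, (tr, va) in enumerate(skf.split(train_table.values, labels)):
        sub_train = train_table.select_samples(tr)
        sub_val = train_table.select_samples(va)
        model = fit_pipeline(sub_train, labels[tr], config)
        res_tr = predict(model, sub_train)
        res_va = predict(model, sub_val)
        m_tr = confusion_metrics(res_tr.probabilities, labels[tr],
                                 config.decision_threshold)
        m_va = confusion_metrics(res_va.probabilities, labels[va],
                                 config.decision_threshold)
        folds.append({
            "fold": fold,
            "n_train": len(tr),
            "n_val": len(va),
            "auc_train": roc_auc(res_tr.probabilities, labels[tr]),
            "auc_val": roc_auc(res_va.probabilities, labels[va]),
            "acc_train": m_tr.accuracy,
            "acc_val": m_va.accuracy,
            "train_sample_ids": list(sub_train.sample_ids),
            "val_sample_ids": list(sub_val.sample_ids),
            "fitted_on": list(model.training_sample_ids),
        })
    return {
        "folds": folds,
        "mean_auc_val": float(np.mean([f["auc_val"] for f in folds])),
        "mean_auc_train": float(np.mean([f["auc_train"] for f in folds])),
        "mean_acc_val": float(np.mean([f["acc_val"] for f in folds])),
        "mean_acc_train": float(np.mean([f["acc_train"] for f in folds])),
    }


DEFAULT_GRID = {
    "normalization_scheme": ["unit", "zero_center", "unit_zero_center"],
    "reduction": ["pcc", "pca"],
    "screener": ["anova", "rfe", "relief"],
    "n_features": list(range(1, 21)),
    "classifier": list(
        ("gaussian_nb", "logistic", "svm_linear", "svm_rbf", "lda", "knn",
         "decision_tree", "random_forest", "adaboost", "gaussian_process")
    ),
}


def grid_optimize(
    train_table: FeatureTable,
    labels: Optional[np.ndarray] = None,
    grid: Optional[dict[str, list]] = None,
    config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, TrainedPairwiseModel]:
    """Exhaustive search over the scheme grid, scored by mean CV-validation AUC.

    Ties break by fewer features, then lexicographic config. Cells that fail
    are recorded with their error, not fatal. Returns the ranked results table
    (one row per cell with CV-train, CV-validation and full-train metrics) and
    the best model refitted on the full training table.
    """
    from .evaluation import confusion_metrics, roc_auc

    base = config or PipelineConfig()
    if seed is not None:
        base = base.replace(seed=seed)
    if labels is None:
        labels = train_table.labels
    if labels is None:
        raise PairlrError("labels required for grid optimization")
    labels = np.asarray(labels, dtype=int)
    grid = grid or DEFAULT_GRID
    if any(len(v) == 0 for v in grid.values()) or not grid:
        raise PairlrError("grid must be non-empty")
    keys = sorted(grid)
    rows = []
    for combo in product(*(grid[k] for k in keys)):
        cell = dict(zip(keys, combo))
        cfg = base.replace(**cell)
        row = {k: cell[k] for k in keys}
        try:
            cv = crossvalidate(train_table, labels, cfg)
            full = fit_pipeline(train_table, labels, cfg)
            res = predict(full, train_table)
            m = confusion_metrics(res.probabilities, labels, cfg.decision_threshold)
            row.update({
                "cv_auc_train": cv["mean_auc_train"],
                "cv_auc_val": cv["mean_auc_val"],
                "cv_acc_train": cv["mean_acc_train"],
                "cv_acc_val": cv["mean_acc_val"],
                "train_auc": roc_auc(res.probabilities, labels),
                "train_acc": m.accuracy,
                "status": "ok",
                "error": "",
            })
        except Exception as exc:  # record, keep searching
            row.update({
                "cv_auc_train": np.nan, "cv_auc_val": np.nan,
                "cv_acc_train": np.nan, "cv_acc_val": np.nan,
                "train_auc": np.nan, "train_acc": np.nan,
                "status": "failed", "error": str(exc),
            })
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table["status"] == "ok"]
    if ok.empty:
        raise PairlrError("every grid cell failed")
    config_key = ok.apply(
        lambda r: tuple(str(r[k]) for k in keys), axis=1
    )
    order = sorted(
        ok.index,
        key=lambda i: (-ok.loc[i, "cv_auc_val"],
                       ok.loc[i, "n_features"] if "n_features" in ok.columns else 0,
                       config_key.loc[i]),
    )
    ranked = pd.concat(
        [table.loc[order], table[table["status"] == "failed"]]
    ).reset_index(drop=True)
    best_values = {
        k: int(v) if isinstance(v, np.integer) else v
        for k, v in ((k, ranked.iloc[0][k]) for k in keys)
    }
    best_cfg = base.replace(**best_values)
    best = fit_pipeline(train_table, labels, best_cfg)
    return ranked, best
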