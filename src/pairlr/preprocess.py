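"""Normalization, redundancy reduction and feature screening.

Three normalization schemes are compared during model selection:

* ``unit`` — divide each feature by its Euclidean norm over the training
  samples;
* ``zero_center`` — subtract the training mean;
* ``unit_zero_center`` — subtract the mean, then divide by the Euclidean
  norm of the centred column.

Redundancy among the highly inter-correlated radiomics features is removed
either by a greedy Pearson-correlation filter (drop the later/lower-scored
member of any pair with \\|r\\| above a threshold) or by PCA. Screening ranks
the surviving features by per-feature one-way ANOVA F score, Relief weight,
or recursive-feature-elimination order.

All statistics here are fitted on the training partition only and frozen
into the model; applying them to new data reuses the stored parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.feature_selection import RFE, f_classif
from sklearn.linear_model import LogisticRegression

from .datamodel import FeatureTable, PairlrError

logger = logging.getLogger("pairlr")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizerParams:
    """Frozen per-feature centring/scaling statistics (training data only)."""

    scheme: str
    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    constant_features: list[str] = field(default_factory=list)


def fit_normalizer(table: FeatureTable, scheme: str) -> NormalizerParams:
    """Fit normalization statistics on a training table.

    Constant features get a scale fallback of 1 (mapping to all-zeros under
    the centred schemes) and are flagged in ``constant_features``.
    """
    if table.n_samples < 2:
        raise PairlrError("need at least 2 samples to fit a normalizer")
    x = table.values
    if scheme == "zero_center":
        center = x.mean(axis=0)
        scale = np.ones(table.n_features)
    elif scheme == "unit":
        center = np.zeros(table.n_features)
        scale = np.linalg.norm(x, axis=0)
    elif scheme == "unit_zero_center":
        center = x.mean(axis=0)
        scale = np.linalg.norm(x - center, axis=0)
    else:
        raise PairlrError(f"unknown normalization scheme {scheme!r}")
    constant = [table.feature_names[j]
                for j in np.flatnonzero(np.ptp(x, axis=0) == 0)]
    degenerate = scale == 0
    if degenerate.any():
        flagged = [table.feature_names[j] for j in np.flatnonzero(degenerate)]
        logger.warning("scale fallback 1 for zero-norm feature(s): %s", flagged)
        scale = np.where(degenerate, 1.0, scale)
    return NormalizerParams(
        scheme=scheme,
        feature_names=list(table.feature_names),
        center=center,
        scale=scale,
        constant_features=constant,
    )


def apply_normalizer(params: NormalizerParams, table: FeatureTable) -> FeatureTable:
    """Apply frozen normalization statistics to a (training or new) table."""
    if list(table.feature_names) != params.feature_names:
        missing = [f for f in params.feature_names if f not in table.feature_names]
        if missing:
            raise PairlrError(f"missing feature column(s): {missing}")
        table = table.select_features(params.feature_names)
    values = (table.values - params.center) / params.scale
    return FeatureTable(
        sample_ids=list(table.sample_ids),
        feature_names=list(table.feature_names),
        values=values,
        feature_kinds=list(table.feature_kinds),
        labels=None if table.labels is None else table.labels.copy(),
    )


# ---------------------------------------------------------------------------
# Redundancy reduction
# ---------------------------------------------------------------------------

def pcc_filter(
    table: FeatureTable,
    threshold: float = 0.99,
    score_hint: dict[str, float] | None = None,
) -> list[str]:
    """Greedy Pearson-correlation redundancy filter; returns kept names.

    Features are scanned in table order (or descending ``score_hint`` when
    provided); a feature is kept iff its absolute correlation with every
    previously kept feature is <= ``threshold``. Kept names are returned in
    original table order. The scan is idempotent and independent of sample
    order. Constant features correlate with nothing and are always kept.
    """
    if not (0 < threshold <= 1):
        raise PairlrError("threshold must be in (0, 1]")
    if table.n_samples < 3:
        raise PairlrError("need >= 3 samples for correlation filtering")
    names = table.feature_names
    x = table.values
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    # constant columns give nan correlations; treat as uncorrelated
    corr[~np.isfinite(corr)] = 0.0
    for j in np.flatnonzero(sd == 0):
        corr[j, :] = 0.0
        corr[:, j] = 0.0
    if score_hint is not None:
        order = sorted(range(len(names)),
                       key=lambda j: (-score_hint.get(names[j], -np.inf), j))
    else:
        order = list(range(len(names)))
    kept: list[int] = []
    for j in order:
        if all(abs(corr[j, k]) <= threshold for k in kept):
            kept.append(j)
    kept_set = set(kept)
    return [names[j] for j in range(len(names)) if j in kept_set]


@dataclass
class PCAParams:
    """Frozen PCA transform: training mean + component loadings."""

    mean: np.ndarray
    components: np.ndarray            # (n_components, d)
    explained_variance_ratio: np.ndarray
    input_features: list[str]

    @property
    def component_names(self) -> list[str]:
        return [f"pc{k + 1}" for k in range(self.components.shape[0])]

    def transform(self, table: FeatureTable) -> FeatureTable:
        if list(table.feature_names) != self.input_features:
            table = table.select_features(self.input_features)
        scores = (table.values - self.mean) @ self.components.T
        return FeatureTable(
            sample_ids=list(table.sample_ids),
            feature_names=self.component_names,
            values=scores,
            feature_kinds=["radiomics"] * self.components.shape[0],
            labels=None if table.labels is None else table.labels.copy(),
        )


def pca_reduce(table: FeatureTable, n_components: int) -> tuple[FeatureTable, PCAParams]:
    """PCA with a deterministic sign convention (largest-|loading| positive).

    Requests beyond the data rank are truncated with a warning.
    """
    max_comp = min(table.n_samples - 1, table.n_features)
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} exceeds rank bound {max_comp}; truncating",
            stacklevel=2,
        )
        n_components = max_comp
    if n_components < 1:
        raise PairlrError("need n_components >= 1 and >= 2 samples")
    est = PCA(n_components=n_components, svd_solver="full")
    scores = est.fit_transform(table.values)
    components = est.components_.copy()
    for k in range(components.shape[0]):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] *= -1
            scores[:, k] *= -1
    params = PCAParams(
        mean=est.mean_,
        components=components,
        explained_variance_ratio=est.explained_variance_ratio_,
        input_features=list(table.feature_names),
    )
    out = FeatureTable(
        sample_ids=list(table.sample_ids),
        feature_names=params.component_names,
        values=scores,
        feature_kinds=["radiomics"] * n_components,
        labels=None if table.labels is None else table.labels.copy(),
    )
    return out, params


# ---------------------------------------------------------------------------
# Feature screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    """Ranked features with per-feature scores, descending.

    Ties break lexicographically by feature name so rankings are
    deterministic regardless of input column order.
    """

    feature_names: list[str]
    scores: list[float]
    method: str

    def top(self, k: int) -> list[str]:
        if k > len(self.feature_names):
            raise PairlrError(
                f"requested {k} features but only {len(self.feature_names)} available"
            )
        return self.feature_names[:k]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"feature": self.feature_names, "score": self.scores})


def _ranked(names: list[str], scores: np.ndarray, method: str) -> ScreeningResult:
    order = sorted(range(len(names)), key=lambda j: (-scores[j], names[j]))
    return ScreeningResult(
        feature_names=[names[j] for j in order],
        scores=[float(scores[j]) for j in order],
        method=method,
    )


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise PairlrError("both classes must be present for screening")
    return labels


def anova_rank(table: FeatureTable, labels: np.ndarray) -> ScreeningResult:
    """Per-feature one-way ANOVA F score (two groups: F on df (1, n-2))."""
    labels = _check_two_classes(labels)
    for c in (0, 1):
        if (labels == c).sum() < 2:
            raise PairlrError(f"class {c} needs >= 2 samples for ANOVA")
    with np.errstate(invalid="ignore", divide="ignore"):
        f_scores, _ = f_classif(table.values, labels)
    f_scores = np.nan_to_num(f_scores, nan=0.0, posinf=np.finfo(float).max)
    return _ranked(table.feature_names, f_scores, "anova")


def relief_rank(
    table: FeatureTable,
    labels: np.ndarray,
    n_iterations: int | None = None,
    seed: int = 0,
) -> ScreeningResult:
    """Classic binary Relief weights (nearest hit / nearest miss).

    For each sampled instance the nearest same-class neighbour (hit) and
    nearest other-class neighbour (miss) are found by Euclidean distance over
    all features; each feature's weight moves away from the hit difference and
    toward the miss difference, with per-feature differences normalized by the
    feature's range. Default is one pass over every sample in seeded random
    order. An instance whose class has a single member has no hit and is
    skipped with a warning.
    """
    labels = _check_two_classes(labels)
    x = table.values
    n, d = x.shape
    m = n if n_iterations is None else int(n_iterations)
    if m < 1:
        raise PairlrError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    span = np.ptp(x, axis=0)
    safe_span = np.where(span == 0, 1.0, span)
    weights = np.zeros(d)
    visit = [int(i) for i in rng.permutation(n)]
    order = [visit[t % n] for t in range(m)]
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(dist, np.inf)
    skipped = 0
    for i in order:
        same = np.flatnonzero(labels == labels[i])
        same = same[same != i]
        other = np.flatnonzero(labels != labels[i])
        if same.size == 0:
            skipped += 1
            continue
        hit = same[np.argmin(dist[i, same])]
        miss = other[np.argmin(dist[i, other])]
        diff_hit = np.abs(x[i] - x[hit]) / safe_span
        diff_miss = np.abs(x[i] - x[miss]) / safe_span
        weights += (diff_miss - diff_hit) / m
    if skipped:
        logger.warning("relief: skipped %d instance(s) with no same-class hit", skipped)
    weights[span == 0] = 0.0
    return _ranked(table.feature_names, weights, "relief")


def rfe_rank(table: FeatureTable, labels: np.ndarray, step: int = 1,
             seed: int = 0) -> ScreeningResult:
    """Recursive feature elimination with an L2-regularized linear classifier.

    One feature is eliminated per step by smallest absolute coefficient; the
    score is the elimination order (the last survivor scores highest).
    """
    labels = _check_two_classes(labels)
    if table.n_features == 1:
        return ScreeningResult(list(table.feature_names), [1.0], "rfe")
    base = LogisticRegression(max_iter=2000, random_state=seed)  # l2 default
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*converge.*")
        rfe = RFE(base, n_features_to_select=1, step=step)
        rfe.fit(table.values, labels)
    # ranking_ == 1 for the survivor; invert so higher score = eliminated later
    scores = (table.n_features - rfe.ranking_ + 1).astype(float)
    return _ranked(table.feature_names, scores, "rfe")


def screen(table: FeatureTable, labels: np.ndarray, method: str,
           seed: int = 0) -> ScreeningResult:
    """Dispatch to the named screening method."""
    if method == "anova":
        return anova_rank(table, labels)
    if method == "relief":
        return relief_rank(table, labels, seed=seed)
    if method == "rfe":
        return rfe_rank(table, labels, seed=seed)
    raise PairlrError(f"unknown screener {method!r}")
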