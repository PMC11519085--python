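"""Diagnostic performance, calibration, clinical utility, cohort comparison.

* ROC AUC (Mann–Whitney concordance with half credit for ties) with a
  stratified percentile-bootstrap confidence interval;
* confusion-matrix rates at a probability threshold (PPV/NPV reported as
  missing, never 0, when undefined);
* Hosmer–Lemeshow goodness-of-fit over quantile bins of predicted risk;
* decision-curve analysis: net benefit of the model against treat-all and
  treat-none policies over a grid of threshold probabilities;
* two-cohort baseline comparison: Pearson chi-squared (no continuity
  correction) or Fisher's exact for categorical variables, two-sided
  Mann–Whitney U for continuous ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .datamodel import PairlrError

logger = logging.getLogger("pairlr")


@dataclass
class EvaluationReport:
    """Headline diagnostic metrics at a fixed decision threshold."""

    auc: float
    auc_ci: Optional[tuple[float, float]]
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    threshold: float
    n: int
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "auc_ci_lo": None if self.auc_ci is None else self.auc_ci[0],
            "auc_ci_hi": None if self.auc_ci is None else self.auc_ci[1],
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "threshold": self.threshold,
            "n": self.n,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }
        return d


@dataclass
class DCACurve:
    """Net-benefit curves over a threshold-probability grid."""

    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray  # identically zero

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "model": self.net_benefit_model,
            "treat_all": self.net_benefit_all,
            "treat_none": self.net_benefit_none,
        })


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise PairlrError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise PairlrError("both classes required")
    return scores, labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random event outscores a random non-event (ties 0.5)."""
    scores, labels = _check_scores_labels(scores, labels)
    return float(roc_auc_score(labels, scores))


def bootstrap_auc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling within each class."""
    scores, labels = _check_scores_labels(scores, labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, size=len(pos), replace=True)
        q = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([p, q])
        aucs[b] = roc_auc_score(labels[idx], scores[idx])
    alpha = (1 - level) / 2
    lo, hi = np.quantile(aucs, [alpha, 1 - alpha])
    return float(lo), float(hi)


def confusion_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    auc_ci: Optional[tuple[float, float]] = None,
) -> EvaluationReport:
    """Confusion-matrix rates for predictions ``score >= threshold``."""
    scores, labels = _check_scores_labels(scores, labels)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n = len(labels)
    return EvaluationReport(
        auc=roc_auc(scores, labels),
        auc_ci=auc_ci,
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=None if tp + fp == 0 else tp / (tp + fp),
        npv=None if tn + fn == 0 else tn / (tn + fn),
        threshold=threshold,
        n=n, tp=tp, fp=fp, tn=tn, fn=fn,
    )


def hosmer_lemeshow(
    probs: Sequence[float],
    labels: Sequence[int],
    n_groups: int = 10,
) -> tuple[float, int, float]:
    """Hosmer–Lemeshow chi-squared over quantile bins of predicted risk.

    Bins are deciles of the predicted probabilities with tied edges merged
    (so heavily tied predictions yield fewer groups and fewer degrees of
    freedom). Per group g with n_g cases, O_g observed and E_g expected
    events, the statistic is sum (O_g − E_g)^2 / (E_g (1 − E_g / n_g)),
    on groups − 2 degrees of freedom.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise PairlrError("probs and labels must have the same length")
    if len(np.unique(probs)) < 3:
        raise PairlrError("need >= 3 distinct probabilities to bin")
    if len(probs) < 2 * n_groups:
        warnings.warn(
            f"only {len(probs)} cases for {n_groups} calibration groups",
            stacklevel=2,
        )
    edges = np.quantile(probs, np.linspace(0, 1, n_groups + 1))
    edges = np.unique(edges)  # merge tied bin edges
    if len(edges) < 3:
        raise PairlrError("probabilities too tied to form calibration bins")
    # assign each case to a bin; right-closed so the max lands in the last bin
    bins = np.clip(np.searchsorted(edges, probs, side="left") - 1, 0,
                   len(edges) - 2)
    bins[probs <= edges[0]] = 0
    chi2 = 0.0
    groups = 0
    for g in range(len(edges) - 1):
        mask = bins == g
        n_g = int(mask.sum())
        if n_g == 0:
            continue
        groups += 1
        o = labels[mask].sum()
        e = probs[mask].sum()
        denom = e * (1 - e / n_g)
        if denom <= 0:
            # perfectly extreme predicted risk; only a discrepancy contributes
            if not np.isclose(o, e):
                chi2 += np.inf
            continue
        chi2 += (o - e) ** 2 / denom
    df = max(groups - 2, 1)
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p


def decision_curve(
    probs: Sequence[float],
    labels: Sequence[int],
    thresholds: Optional[Sequence[float]] = None,
) -> DCACurve:
    """Decision-curve analysis over a grid of threshold probabilities.

    Net benefit of calling positives at threshold p_t is
    ``TP/n − (FP/n) · p_t/(1 − p_t)``; the treat-all policy has
    ``prevalence − (1 − prevalence) · p_t/(1 − p_t)``; treat-none is zero.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise PairlrError("probs and labels must have the same length")
    if thresholds is None:
        thresholds = np.arange(0.01, 1.00, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    n = len(labels)
    prevalence = labels.mean()
    nb_model = np.empty_like(thresholds)
    nb_all = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        w = pt / (1 - pt)
        pred = probs >= pt
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        nb_model[i] = tp / n - (fp / n) * w
        nb_all[i] = prevalence - (1 - prevalence) * w
    return DCACurve(
        thresholds=thresholds,
        net_benefit_model=nb_model,
        net_benefit_all=nb_all,
        net_benefit_none=np.zeros_like(thresholds),
    )


def baseline_comparison(
    data,
    variable_type: str,
    use_fisher: bool = False,
) -> tuple[float, float, str]:
    """Compare a variable between two cohorts (e.g. training vs testing).

    Categorical: ``data`` is an r x 2 contingency table (levels x cohorts);
    Pearson chi-squared without continuity correction by default, Fisher's
    exact (2 x 2 only) by flag. A warning is logged when any expected count
    falls below 5. Continuous: ``data`` is a pair of value arrays; two-sided
    Mann–Whitney U with normal approximation and tie correction.

    Returns ``(statistic, p_value, test_name)``.
    """
    if variable_type == "categorical":
        table = np.asarray(data, dtype=float)
        if table.ndim != 2 or table.shape[1] != 2:
            raise PairlrError("categorical data must be an r x 2 table")
        if table.sum(axis=0).min() == 0:
            raise PairlrError("empty cohort in contingency table")
        if use_fisher:
            if table.shape != (2, 2):
                raise PairlrError("Fisher's exact test requires a 2 x 2 table")
            odds, p = stats.fisher_exact(table)
            return float(odds), float(p), "fisher_exact"
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        if (expected < 5).any():
            logger.warning(
                "chi-squared with expected count(s) < 5; consider use_fisher"
            )
        return float(chi2), float(p), "chi2"
    if variable_type == "continuous":
        a, b = (np.asarray(v, dtype=float) for v in data)
        if a.size == 0 or b.size == 0:
            raise PairlrError("empty cohort")
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic")
        return float(u), float(p), "mannwhitney"
    raise PairlrError("variable_type must be 'categorical' or 'continuous'")


def baseline_table(variables: dict[str, dict]) -> pd.DataFrame:
    """Cohort-comparison summary, one row per variable.

    ``variables`` maps a name to ``{"type": ..., "data": ...,
    "use_fisher": bool}`` in the form :func:`baseline_comparison` accepts.
    """
    rows = []
    for name, spec in variables.items():
        stat, p, test = baseline_comparison(
            spec["data"], spec["type"], spec.get("use_fisher", False)
        )
        rows.append({"variable": name, "statistic": stat, "p": p, "test": test})
    return pd.DataFrame(rows)


def evaluate(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvaluationReport:
    """Full report: AUC with bootstrap CI plus threshold metrics."""
    ci = bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    return confusion_metrics(scores, labels, threshold, auc_ci=ci)


# ---------------------------------------------------------------------------
# Plots (ROC / calibration / decision curves)
# ---------------------------------------------------------------------------

def plot_roc(scores, labels, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"AUC = {roc_auc(scores, labels):.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_calibration(probs, labels, path, n_groups: int = 10) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    edges = np.unique(np.quantile(probs, np.linspace(0, 1, n_groups + 1)))
    bins = np.clip(np.searchsorted(edges, probs, side="left") - 1, 0,
                   len(edges) - 2)
    xs, ys = [], []
    for g in range(len(edges) - 1):
        mask = bins == g
        if mask.any():
            xs.append(probs[mask].mean())
            ys.append(labels[mask].mean())
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(xs, ys, "o-")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed event rate")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_dca(curve: DCACurve, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.thresholds, curve.net_benefit_model, label="model")
    ax.plot(curve.thresholds, curve.net_benefit_all, label="treat all")
    ax.plot(curve.thresholds, curve.net_benefit_none, label="treat none")
    ax.set_ylim(bottom=max(-0.1, curve.net_benefit_model.min() - 0.05))
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
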