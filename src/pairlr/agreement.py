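"""Inter-observer segmentation agreement: Dice overlap and ICC(2,1).

Two readers delineate the same tumours; agreement is quantified by the Dice
coefficient on the binary masks and by the intraclass correlation
coefficient on derived shape measures (volume, surface area, diameters...).
The ICC variant is two-way random effects, absolute agreement, single rater
— Shrout–Fleiss ICC(2,1) — with the F test ``MSR/MSE`` on
``(n−1, (n−1)(k−1))`` degrees of freedom and the McGraw–Wong F-distribution
confidence bounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import PairlrError

logger = logging.getLogger("pairlr")


@dataclass
class PairedMeasurements:
    """One shape measure judged by two readers on the same subjects."""

    subject_ids: list[str]
    reader1: np.ndarray
    reader2: np.ndarray

    def __post_init__(self) -> None:
        self.reader1 = np.asarray(self.reader1, dtype=float)
        self.reader2 = np.asarray(self.reader2, dtype=float)
        if not (len(self.subject_ids) == len(self.reader1) == len(self.reader2)):
            raise PairlrError("subject ids and reader values must align")
        if len(self.subject_ids) < 3:
            raise PairlrError("need >= 3 subjects")
        if not (np.all(np.isfinite(self.reader1)) and np.all(np.isfinite(self.reader2))):
            raise PairlrError("non-finite measurement")

    @classmethod
    def from_csv(cls, path, subject_column="subject",
                 reader_columns=("reader1", "reader2")) -> "PairedMeasurements":
        df = pd.read_csv(path)
        return cls(
            subject_ids=df[subject_column].astype(str).tolist(),
            reader1=df[reader_columns[0]].to_numpy(dtype=float),
            reader2=df[reader_columns[1]].to_numpy(dtype=float),
        )


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` between two binary masks.

    Two empty masks agree perfectly by convention (returns 1.0 with a
    warning); a shape mismatch is an error.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise PairlrError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    size = a.sum() + b.sum()
    if size == 0:
        warnings.warn("both masks empty; Dice defined as 1.0", stacklevel=2)
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / size)


@dataclass
class ICCResult:
    icc: float
    ci_lo: float
    ci_hi: float
    f_stat: float
    p_value: float
    df1: int
    df2: int


def icc(pm: PairedMeasurements, level: float = 0.95) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    With subject mean square MSR, rater mean square MSC and residual MSE
    from the two-way ANOVA decomposition (n subjects, k raters):

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    F = MSR/MSE tests subject discriminability on (n−1, (n−1)(k−1)) df.
    """
    y = np.column_stack([pm.reader1, pm.reader2])
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise PairlrError("zero total variance; ICC undefined")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise PairlrError("degenerate variance decomposition; ICC undefined")
    icc_val = (msr - mse) / denom
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = msr / mse
        p = float(stats.f.sf(f_stat, df1, df2))
    lo, hi = _icc2_ci(icc_val, msr, msc, mse, n, k, level)
    return ICCResult(icc=float(icc_val), ci_lo=lo, ci_hi=hi,
                     f_stat=float(f_stat), p_value=p, df1=df1, df2=df2)


def _icc2_ci(icc_val, msr, msc, mse, n, k, level):
    """McGraw–Wong F-based confidence bounds for ICC(2,1)."""
    if mse == 0:
        return 1.0, 1.0
    alpha = 1 - level
    a = k * icc_val / (n * (1 - icc_val)) if icc_val < 1 else np.inf
    b = 1 + k * icc_val * (n - 1) / (n * (1 - icc_val)) if icc_val < 1 else np.inf
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(lo), float(hi)


def agreement_table(measures: dict[str, PairedMeasurements]) -> pd.DataFrame:
    """Shape-measure agreement summary: one row per measure (ICC, CI, F, p)."""
    rows = []
    for name, pm in measures.items():
        r = icc(pm)
        rows.append({
            "feature": name, "icc": r.icc, "ci_lo": r.ci_lo, "ci_hi": r.ci_hi,
            "F": r.f_stat, "p": r.p_value,
        })
    return pd.DataFrame(rows)


def load_mask(path) -> np.ndarray:
    """Load a binary 3-D mask from NIfTI/NRRD (requires SimpleITK)."""
    try:
        import SimpleITK as sitk
    except ImportError as exc:  # pragma: no cover
        raise PairlrError(
            "SimpleITK is required to read NIfTI/NRRD masks"
        ) from exc
    img = sitk.ReadImage(str(path))
    return sitk.GetArrayFromImage(img) > 0
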