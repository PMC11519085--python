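"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a small radiotherapy cohort: 130 patients at ~49%
event prevalence, a large block-correlated panel of continuous "radiomics"
features of which a handful are informative, plus a couple of clinical
covariates (a continuous wall-thickness-like measure and an ordinal
stage-like variable).

Radiomics features come in equicorrelated Gaussian blocks (within-block
correlation ρ) with unit marginal variance, so a class-1 mean shift of
``effect_size`` on the informative features is a standardized mean
difference. Labels are assigned by exact count (``round(prevalence · n)``
events), not by Bernoulli draws, so small-cohort tests are stable. Ordinal
clinical variables discretize a shifted latent Gaussian at its quantiles
(a proportional-odds-style construction).

Everything is reproducible from the single ``CohortSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import FeatureTable, PairlrError


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the study conditions: n = 130 with 64 events, 200
    radiomics features in blocks of 10 at ρ = 0.8, 5 informative features
    with a standardized mean difference of 1.0, one continuous and one
    4-level ordinal clinical covariate sharing that effect size.
    """

    n: int = 130
    d_radiomics: int = 200
    n_informative: int = 5
    effect_size: float = 1.0
    block_correlation: float = 0.8
    block_size: int = 10
    clinical: tuple[tuple, ...] = (("continuous",), ("ordinal", 4))
    prevalence: float = 64 / 130
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.d_radiomics:
            raise PairlrError("n_informative must be <= d_radiomics")
        if not (0 <= self.block_correlation < 1):
            raise PairlrError("block_correlation must be in [0, 1)")
        if self.block_size < 1:
            raise PairlrError("block_size must be >= 1")
        if not (0 < self.prevalence < 1):
            raise PairlrError("prevalence must be in (0, 1)")
        n_event = int(round(self.prevalence * self.n))
        if n_event < 2 or self.n - n_event < 2:
            raise PairlrError("each class needs >= 2 samples")

    @property
    def n_events(self) -> int:
        return int(round(self.prevalence * self.n))


def generate_cohort(spec: CohortSpec | None = None) -> FeatureTable:
    """Draw a labelled synthetic cohort from a :class:`CohortSpec`."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n, spec.d_radiomics
    n_event = spec.n_events
    labels = np.zeros(n, dtype=int)
    event_rows = rng.choice(n, size=n_event, replace=False)
    labels[event_rows] = 1

    rho = spec.block_correlation
    n_blocks = int(np.ceil(d / spec.block_size))
    x = np.empty((n, d))
    for b in range(n_blocks):
        lo = b * spec.block_size
        hi = min(lo + spec.block_size, d)
        width = hi - lo
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, width))
        # equicorrelated construction with unit marginal variance
        x[:, lo:hi] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise

    # informative features: one per block (spread so the correlation filter
    # cannot discard the signal wholesale), shifted in the event class
    for j in _informative_indices(spec):
        x[labels == 1, j] += spec.effect_size

    names = [f"radiomics_{j:03d}" for j in range(d)]
    kinds = ["radiomics"] * d
    columns = [x]
    for v, var in enumerate(spec.clinical):
        kind = var[0]
        latent = rng.standard_normal(n)
        latent[labels == 1] += spec.effect_size
        if kind == "continuous":
            columns.append(latent[:, None])
            names.append(f"clinical_cont_{v}")
        elif kind == "ordinal":
            levels = int(var[1])
            cuts = np.quantile(latent, np.linspace(0, 1, levels + 1)[1:-1])
            columns.append(np.digitize(latent, cuts)[:, None].astype(float))
            names.append(f"clinical_ord_{v}")
        else:
            raise PairlrError(f"unknown clinical variable kind {kind!r}")
        kinds.append("clinical")

    return FeatureTable(
        sample_ids=[f"s{i:04d}" for i in range(n)],
        feature_names=names,
        values=np.hstack(columns),
        feature_kinds=kinds,
        labels=labels,
    )


def _informative_indices(spec: CohortSpec) -> list[int]:
    """Column indices of the planted signal: one per block, then wrapping."""
    n_blocks = int(np.ceil(spec.d_radiomics / spec.block_size))
    indices = []
    for offset in range(spec.block_size):
        for b in range(n_blocks):
            j = b * spec.block_size + offset
            if j < spec.d_radiomics:
                indices.append(j)
            if len(indices) == spec.n_informative:
                return indices
    return indices


def informative_feature_names(spec: CohortSpec) -> list[str]:
    """Names of the planted informative radiomics features."""
    return [f"radiomics_{j:03d}" for j in _informative_indices(spec)]


def generate_mask_pair(
    shape: tuple[int, int, int] = (32, 32, 32),
    center: tuple[float, float, float] | None = None,
    radii: tuple[float, float, float] = (8.0, 6.0, 5.0),
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """An ellipsoid mask and a boundary-jittered copy (two-reader fixture).

    The second mask perturbs the ellipsoid centre and radii by Gaussian
    noise of scale ``jitter`` (voxels), so the expected Dice decreases as
    jitter grows; ``jitter = 0`` returns identical masks.
    """
    if min(radii) <= 0:
        raise PairlrError("ellipsoid radii must be positive")
    if center is None:
        center = tuple(s / 2 for s in shape)
    rng = np.random.default_rng(seed)
    grid = np.indices(shape).astype(float)

    def ellipsoid(c, r):
        q = sum(((grid[a] - c[a]) / r[a]) ** 2 for a in range(3))
        return q <= 1.0

    mask_a = ellipsoid(center, radii)
    if not mask_a.any():
        raise PairlrError("ellipsoid does not cover any voxel")
    if jitter == 0:
        return mask_a, mask_a.copy()
    center_b = tuple(c + jitter * rng.standard_normal() for c in center)
    radii_b = tuple(max(r + jitter * rng.standard_normal(), 0.5) for r in radii)
    mask_b = ellipsoid(center_b, radii_b)
    return mask_a, mask_b
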