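import numpy as np
import pytest

from pairlr import CohortSpec, FeatureTable, PipelineConfig, generate_cohort


@pytest.fixture
def small_table() -> FeatureTable:
    """Tiny deterministic labelled table for unit tests."""
    rng = np.random.default_rng(0)
    values = rng.standard_normal((10, 4))
    values[5:, 0] += 2.0  # feature f0 separates the classes
    return FeatureTable(
        sample_ids=[f"p{i}" for i in range(10)],
        feature_names=["f0", "f1", "f2", "f3"],
        values=values,
        labels=np.array([0] * 5 + [1] * 5),
    )


@pytest.fixture(scope="session")
def cohort() -> FeatureTable:
    """Default synthetic cohort: n = 130, 64 events, planted signal."""
    return generate_cohort(CohortSpec(seed=42))


@pytest.fixture
def fast_config() -> PipelineConfig:
    return PipelineConfig(n_features=5, seed=0)
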