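import numpy as np
import pytest

from metamark.synthetic import SyntheticConfig, generate_cohort
from metamark.table import FeatureTable


def make_table(values, groups, batches=None, markers=None, ids=None) -> FeatureTable:
    """Small hand-built feature table for unit tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return FeatureTable(
        sample_ids=ids or [f"s{i}" for i in range(n)],
        groups=np.asarray(groups, dtype=object),
        batches=np.asarray(batches if batches is not None else ["b1"] * n, dtype=object),
        markers=markers or [f"m{j}" for j in range(p)],
        intensities=values,
    )


@pytest.fixture
def small_cohort() -> FeatureTable:
    """Deterministic 20x12 cohort with 3 strongly planted markers."""
    return generate_cohort(
        SyntheticConfig(
            n_case=10, n_control=10, n_markers=12, n_informative=3,
            effect_log2fc=2.0, noise_sd=0.3, n_batches=2, seed=42,
        )
    )


@pytest.fixture
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=7)
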