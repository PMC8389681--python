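import numpy as np
import pytest

from sterolnet.synthetic import CohortSpec, SyntheticConfig


@pytest.fixture
def small_config():
    """Compact synthetic study: exact-oracle regime (no missed detections,
    noise confined to < min_sources sources by construction)."""
    return SyntheticConfig(
        seed=1,
        n_partners=60,
        n_planted_consensus=10,
        detection_prob=1.0,
        noise_edge_rate=5.0,
        cohort_specs=[CohortSpec("THYM", 50, 50)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
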