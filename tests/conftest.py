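import numpy as np
import pytest

from pdacsubtypes import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A small, well-separated planted cohort shared by unit tests."""
    cfg = synthetic.CohortConfig(
        n_genes=300,
        subtype_sizes=(20, 22, 8),
        markers_per_subtype=25,
        marker_log2_shift=2.0,
        noise_sd=0.5,
        survival_medians=(37.6, 19.2, 13.8),
        seed=42,
    )
    expr, clinical, truth = synthetic.simulate_cohort(cfg)
    return cfg, expr, clinical, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
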