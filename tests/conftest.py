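import numpy as np
import pytest

import uskit
from uskit.panel import GenePanel, HOUSEKEEPING_GENES


@pytest.fixture(scope="session")
def panel():
    return uskit.default_panel()


@pytest.fixture(scope="session")
def default_spec(panel):
    return uskit.default_cohort_spec(panel)


@pytest.fixture(scope="session")
def cohort(default_spec):
    """One noisy cohort at the default study conditions (22 vs 14)."""
    return uskit.generate_cohort(default_spec, seed=7)


@pytest.fixture(scope="session")
def noiseless_cohort(default_spec):
    return uskit.generate_cohort(default_spec.noiseless(), seed=7)


@pytest.fixture(scope="session")
def norm(cohort, panel):
    return uskit.normalize_delta_ct(cohort, panel)


@pytest.fixture(scope="session")
def tiny_panel():
    """Six-target toy panel for fast I/O and validation tests."""
    return GenePanel(
        target_genes=("BCL6", "IL23A", "CXCL2", "CRP", "CCL11", "TNFSF14"),
        housekeeping_genes=HOUSEKEEPING_GENES,
        panel_name="tiny",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240518)
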