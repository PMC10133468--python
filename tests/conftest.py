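import numpy as np
import pytest

from cifit.cohort import CohortConfig, generate_cohort
from cifit.tonotopy import ElectrodeGeometry


@pytest.fixture(scope="session")
def mean_geometry() -> ElectrodeGeometry:
    """The cohort-mean ear: CDL 35 mm, apical contact at 22 mm, 0.95 mm pitch."""
    return ElectrodeGeometry(
        insertion_depths=22.0 - 0.95 * np.arange(16),
        cochlear_duct_length=35.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A reproducible 14-subject simulated cohort (in memory only)."""
    return generate_cohort(CohortConfig(n_subjects=14, master_seed=20260925))
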