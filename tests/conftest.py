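import numpy as np
import pytest

from deltarad import synthetic


@pytest.fixture(scope="session")
def feature_cohort():
    """Default informative cohort (50 patients, effect 1.5, 10% informative)."""
    spec = synthetic.CohortSpec(seed=7)
    tables, labels, availability = synthetic.generate_feature_cohort(spec)
    return spec, tables, labels, availability


@pytest.fixture(scope="session")
def small_imaging_pair():
    """One synthetic patient pair (baseline, post-cycle-1) with DWI."""
    spec = synthetic.CohortSpec(n_patients=2, missing_adc_fraction=0.0, seed=5)
    studies, labels = synthetic.generate_imaging_cohort(spec)
    return studies[0], labels.iloc[0]


@pytest.fixture
def sphere_mask():
    """Digitized sphere of radius 10 mm on a 1 mm grid."""
    n = 25
    x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    return ((x - 12.0) ** 2 + (y - 12.0) ** 2 + (z - 12.0) ** 2 <= 100.0).astype(np.uint8)
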