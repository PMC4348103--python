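import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dipr.preprocess import qc_markers, standardize_fit
from dipr.simulate import make_fixture

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_dataset():
    """The canonical small simulated dataset (30 samples, 20 + 15 features)."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_standardized(tiny_dataset):
    """QC'd and fully standardized blocks plus the centered trait."""
    markers, _ = qc_markers(tiny_dataset.marker_table)
    Z1, _ = standardize_fit(markers.values)
    Z2, _ = standardize_fit(tiny_dataset.metabolite_table.values)
    y = tiny_dataset.trait_table.values[:, 0]
    return Z1, Z2, y - y.mean()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
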