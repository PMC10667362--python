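import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nerdcall import toy_signature_matrix
from nerdcall.simulate import SimulationConfig, generate_reference, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_sigs():
    return toy_signature_matrix()


@pytest.fixture(scope="session")
def engineered():
    """Engineered reference + locus registry (20 loci per channel)."""
    cfg = SimulationConfig(seed=11, loci_per_channel=20)
    return generate_reference(cfg)


@pytest.fixture(scope="session")
def rich_cohort(tmp_path_factory):
    """A simulated cohort exercising every exclusion path."""
    out = tmp_path_factory.mktemp("rich_cohort")
    cfg = SimulationConfig(
        seed=5,
        n_samples=14,
        mean_burden=120,
        n_wga=2,
        n_ffpe=1,
        n_msi=2,
        n_extra_patient_samples=2,
        n_low_burden=1,
    )
    return simulate_cohort(cfg, out)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
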