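import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from redpcr import assay_sim, quantify
from redpcr.site_model import SiteModel

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def model() -> SiteModel:
    return SiteModel()


@pytest.fixture(scope="session")
def layout():
    return assay_sim.generate_reference(seed=11)


@pytest.fixture(scope="session")
def sim_config() -> assay_sim.SimulationConfig:
    return assay_sim.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def cohort_run(sim_config):
    """One default cohort taken through simulate -> pool -> QC -> estimate."""
    states, counts = assay_sim.simulate_cohort_counts(sim_config)
    table, exclusions = quantify.quantify_samples(counts, spike_dilution=sim_config.spike_dilution)
    return states, counts, table, exclusions


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
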