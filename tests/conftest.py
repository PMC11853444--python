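import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper():
    from cfmrd.fixtures import load_paper_fixture

    return load_paper_fixture()


@pytest.fixture(scope="session")
def paper_trajectories(paper):
    from cfmrd.fixtures import fixture_trajectories

    return fixture_trajectories(paper)


@pytest.fixture(scope="session")
def risk_set():
    from cfmrd.risk_model import load_risk_gene_set

    return load_risk_gene_set()


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with ground truth, shared across tests."""
    from cfmrd.synthetic_cohort import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(seed=11, n_subjects=12))
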