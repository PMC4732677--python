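import pytest
from hypothesis import HealthCheck, settings

from beachmix.mixing import MCMCConfig
from beachmix.simulate import ScenarioConfig, simulate_scenario

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

#: Source centroids separated by >= 3 ‰ per isotope: the condition under
#: which diet proportions are identifiable from two tracers.
SEPARATED_SOURCES = {
    "mole_crab": (-12.0, 4.0),
    "amphipod": (-17.0, 10.0),
    "coquina": (-22.0, 7.0),
}

#: Short MCMC schedule for unit tests (keeps the retained-draw law nontrivial).
SHORT_MCMC = MCMCConfig(iterations=6_000, burn_in=1_000, thin=5, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """A 6-site synthetic study with one amphipod-free site (imputation path)."""
    cfg = ScenarioConfig(n_sites=6, seed=11, n_missing_amphipod_sites=1)
    return simulate_scenario(cfg)


@pytest.fixture(scope="session")
def separated_dataset():
    """A synthetic study with well-separated source centroids."""
    cfg = ScenarioConfig(
        n_sites=8, seed=5, source_mean_bases=dict(SEPARATED_SOURCES)
    )
    return simulate_scenario(cfg)
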