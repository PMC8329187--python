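import pytest

from protshift import SimulationConfig
from protshift.pipeline import simulate_and_profile


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced cohort used by fast unit tests."""
    return SimulationConfig(
        n_subjects=10, n_mgs=12, genes_per_mgs=551, n_marker_genes=20,
        sequencing_depth=30_000, seed=11,
    )


@pytest.fixture(scope="session")
def small_profile(small_config):
    """Full pipeline outputs on the reduced cohort (shared, read-only)."""
    return simulate_and_profile(small_config)


@pytest.fixture(scope="session")
def default_profile():
    """Pipeline outputs at the generator's default study conditions."""
    return simulate_and_profile(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def null_profile():
    """Default-sized cohort with no planted amino-acid shift."""
    return simulate_and_profile(SimulationConfig(seed=13, planted_aa_synthesis_log2fc=0.0))
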