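import pytest

from mimicline.synthetic_data import (
    SimulationConfig,
    simulate_coi_alignment,
    simulate_snp_matrix,
    simulate_specimens,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small but fully structured hybrid zone used across module tests."""
    return SimulationConfig(seed=1, n_specimens=300)


@pytest.fixture(scope="session")
def specimen_table(small_config):
    return simulate_specimens(small_config)


@pytest.fixture(scope="session")
def coi_alignment(small_config, specimen_table):
    return simulate_coi_alignment(specimen_table, small_config)


@pytest.fixture(scope="session")
def snp_data(small_config):
    return simulate_snp_matrix(small_config)


@pytest.fixture(scope="session")
def clean_snp_config() -> SimulationConfig:
    """Gradient-only SNP genome: no planted fixed sites, no bad calls."""
    return SimulationConfig(
        seed=2,
        n_snps=500,
        low_quality_call_fraction=0.0,
        non_biallelic_fraction=0.0,
        n_ancestry_fixed_snps=0,
        n_numt_intervals=0,
    )
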