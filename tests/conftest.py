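import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xscar import (
    SimConfig,
    build_fork_map,
    simulate_origins,
    simulate_scar_experiment,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# small genome for fast end-to-end tests: two contigs, two origins each
TINY_SIM = dict(
    contig_lengths={"chrA": 40_000, "chrB": 30_000},
    n_origins=2,
    n_chip_fragments=5_000,
    n_input_fragments=2_000,
    flank=2500,
)


@pytest.fixture
def tiny_sim_config():
    return SimConfig(seed=123, **TINY_SIM)


@pytest.fixture(scope="session")
def default_experiment():
    """One full-size simulated experiment (p_lead = 0.8) shared across tests."""
    config = SimConfig(seed=777, p_lead=0.8)
    origins = simulate_origins(config)
    forks = build_fork_map(origins, config.contig_lengths)
    parental, new, input_reads = simulate_scar_experiment(config, forks, origins)
    return {
        "config": config,
        "origins": origins,
        "forks": forks,
        "parental": parental,
        "new": new,
        "input": input_reads,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
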