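"""Shared fixtures: one full-scale simulation and one small one per session."""

import pytest

from mutartifacts import SimulationConfig, find_runs, simulate


@pytest.fixture(scope="session")
def default_sim():
    """The reference study conditions: ~5 Mb genome, default artifact mix."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_runs(default_sim):
    return find_runs(default_sim.genome, default_sim.config.min_run_length)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7, n_chromosomes=2, chrom_length=80_000, n_genes=12,
        n_true_mutations=150, n_bleed_errors=80, n_cluster_errors=6,
        n_recurrent_errors=3, n_samples=12, recurrent_sample_count=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate(small_config)
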