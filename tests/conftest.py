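import pytest

from replicheck.population_sim import SimConfig, simulate_population
from replicheck.reporting import PipelineConfig, run_pipeline_from_calls


@pytest.fixture(scope="session")
def default_sim():
    """The reference study conditions: 50 lines, 2 Mb, 500 mutations/line."""
    return simulate_population(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    report, catalogs, masked = run_pipeline_from_calls(default_sim.calls)
    return report, catalogs, masked


@pytest.fixture(scope="session")
def small_sim():
    """A fast, smaller population for unit-level checks."""
    cfg = SimConfig(
        seed=3,
        genome_length=100_000,
        n_chroms=2,
        n_lines=8,
        mutations_per_line=60,
        n_repeat_families=6,
        repeat_length=300,
        copies_per_family=2,
        paralog_divergence_rate=0.03,
        n_error_positions=20,
        n_contaminated_pairs=1,
    )
    return simulate_population(cfg)
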