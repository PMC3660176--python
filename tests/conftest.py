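import pytest
from hypothesis import HealthCheck, settings

from cqkit.pipeline import run_simulation_pipeline
from cqkit.sexsim import SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on a default ~320 kb simulation at 20x coverage.

    Shared across tests: the genome has 5 autosomes of 50 kb, one 50 kb X
    and one 20 kb Y, with two softmasked repeat families and two
    95%-identity duplications onto the Y; reads are error-free 100-mers.
    """
    return run_simulation_pipeline(SimulationConfig(seed=20260109))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast simulated genome + reads for unit-level tests."""
    from cqkit.sexsim import simulate_genome, simulate_reads

    cfg = SimulationConfig(
        seed=11,
        n_autosomal_seqs=2,
        autosomal_length=8_000,
        x_length=8_000,
        y_length=5_000,
        repeat_family_count=1,
        repeat_copies_per_compartment=2,
        repeat_copies_y=3,
        n_duplications=1,
        male_coverage=8.0,
        female_coverage=8.0,
        n_expressed_y_genes=1,
    )
    genome, truth = simulate_genome(cfg)
    male, female, transcriptome = simulate_reads(genome, truth, cfg)
    return cfg, genome, truth, male, female, transcriptome
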