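import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fqpack",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fqpack")


@pytest.fixture(scope="session")
def small_sim():
    """A small SE dataset reused by several suites (50 kbp genome, 10x)."""
    from fqpack.simdata import SimSpec, sample_reads, simulate_genome

    spec = SimSpec(genome_length=50_000, coverage=10, read_length=100,
                   error_rate=0.002, seed=11)
    genome = simulate_genome(spec.genome_length, spec.seed)
    return genome, sample_reads(genome, spec)


@pytest.fixture(scope="session")
def small_pairs():
    """A small PE dataset (30 kbp genome, 20x, insert 300 +/- 30)."""
    from fqpack.simdata import SimSpec, sample_reads, simulate_genome

    spec = SimSpec(genome_length=30_000, coverage=20, read_length=100,
                   error_rate=0.001, paired=True, insert_mean=300.0,
                   insert_sd=30.0, seed=12)
    genome = simulate_genome(spec.genome_length, spec.seed)
    return genome, sample_reads(genome, spec)
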