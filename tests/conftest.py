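import pytest

from crisedit import fixtures, locus_scan


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic genome (seed 42): 3 genes, one planted array."""
    return fixtures.simulate_genome(fixtures.FixtureConfig(seed=42))


@pytest.fixture(scope="session")
def default_arrays(default_sim):
    return locus_scan.detect_arrays(default_sim.genome)
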