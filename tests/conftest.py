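import pytest

from repeatspan import DEFAULT_CATALOG, random_flanks, simulate_sample


@pytest.fixture(scope="session")
def catalog():
    return DEFAULT_CATALOG


@pytest.fixture(scope="session")
def flanks():
    """Seed-fixed synthetic 200 bp flank pair used across the suite."""
    return random_flanks(200, seed=11)


@pytest.fixture(scope="session")
def noisy_sample(flanks):
    """One moderate-size noisy sample shared by classification tests."""
    left, right = flanks
    return simulate_sample("shared", left, right, mean_core=200,
                           jitter_sd=30, interruption_fraction=0.02,
                           coverage=25, error_rate=0.10, seed=424242)
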