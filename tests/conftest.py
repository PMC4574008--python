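import pytest

from splicevents import edge_case_suite, make_scenario


@pytest.fixture(scope="session")
def edge_cases():
    return edge_case_suite()


@pytest.fixture(scope="session")
def small_scenario():
    """A compact planted-event study shared across unit tests."""
    return make_scenario(
        n_genes=24, coverage=30, alt_fraction=0.2, n_samples=3, seed=7
    )
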