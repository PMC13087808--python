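import pytest

from leadtuner.synthetic_data import SeriesSpec, generate_series


@pytest.fixture(scope="session")
def small_series():
    """24-molecule congeneric series, 4 inactives; shared across tests."""
    return generate_series(SeriesSpec(n_molecules=24, n_inactive=4, seed=17))


@pytest.fixture(scope="session")
def series_160():
    """Prospective-scale series: 160 molecules with stability, 20 inactive."""
    return generate_series(SeriesSpec(n_molecules=160, n_inactive=20, seed=5))


@pytest.fixture()
def records_by_id(small_series):
    return {r.id: r for r in small_series}
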