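import pytest
from hypothesis import settings

from sdpsearch import FixtureSpec, SearchConfig, make_fixture_set

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SearchConfig:
    return SearchConfig()


@pytest.fixture(scope="session")
def small_fixture_set(tmp_path_factory):
    """A compact proteome + 30 spiked spectra with ground truth."""
    out = tmp_path_factory.mktemp("fixtures")
    spec = FixtureSpec(n_proteins=12, n_spike_spectra=30, seed=7)
    return make_fixture_set(spec, out)
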