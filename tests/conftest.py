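import warnings

import pytest

from targetrank.synthetic import WorldConfig, make_world, write_fixtures


@pytest.fixture(scope="session")
def default_world():
    """One default synthetic world shared by read-only tests."""
    return make_world(WorldConfig(seed=11))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_world):
    """The default world written out as fixture files."""
    d = tmp_path_factory.mktemp("fixtures")
    write_fixtures(default_world, d, force=True)
    return d


@pytest.fixture(autouse=True)
def _quiet_empty_subnetwork_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*no gene passes.*")
        yield
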