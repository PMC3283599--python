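import warnings

import pytest

import paleoamp as pa


@pytest.fixture(scope="session")
def default_config():
    return pa.SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_refs(default_config):
    return pa.generate_references(default_config)


@pytest.fixture(scope="session")
def default_library(default_config, default_refs):
    return pa.simulate_clone_library(default_config, default_refs)


@pytest.fixture(autouse=True)
def _quiet_screen_warnings():
    """The screen's advisory warnings (inconsistent nuclear outcomes etc.)
    are expected in bulk simulation; tests assert them explicitly where
    they matter."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
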