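import numpy as np
import pytest

from actidose import load_fixture_bundle, run_scenario, synth_scenario


@pytest.fixture(scope="session")
def bundle():
    return load_fixture_bundle()


@pytest.fixture(scope="session")
def default_config():
    return synth_scenario("default")


@pytest.fixture(scope="session")
def default_result(bundle, default_config):
    """The study scenario (Table-2 parameter set, packaged fixtures), run
    once per session and shared across tests."""
    return run_scenario(default_config, bundle)


@pytest.fixture(scope="session")
def tiny_config():
    return synth_scenario("tiny")


@pytest.fixture(scope="session")
def tiny_result(bundle, tiny_config):
    return run_scenario(tiny_config, bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
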