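import pytest

from isogly.model_assembly import build_model, load_config, load_tables
from isogly.simulate import steady_state


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def model0(tables, config):
    return build_model(0, tables=tables, config=config)


@pytest.fixture(scope="session")
def model18(tables, config):
    return build_model(18, tables=tables, config=config)


@pytest.fixture(scope="session")
def ss18(model18):
    ss = steady_state(model18)
    assert ss.converged
    return ss


@pytest.fixture(scope="session")
def profile18(model18, ss18):
    from isogly.mca import control_profile

    return control_profile(model18, base=ss18)


@pytest.fixture(scope="session")
def trace_and_models(tables, config):
    from isogly.pipeline import run_iterations

    return run_iterations(tables=tables, config=config, rank=False)
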