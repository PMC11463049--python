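import pytest

from pharmdyn.causal_graph import reference_graph
from pharmdyn.pharmacy_model import build_pharmacy_model, reference_parameters
from pharmdyn.sd_engine import SimConfig, simulate


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_config():
    return SimConfig(start_time=0.0, stop_time=24.0, dt=0.25)


@pytest.fixture(scope="session")
def ref_model(ref_params):
    return build_pharmacy_model(ref_params)


@pytest.fixture(scope="session")
def ref_trajectory(ref_model, ref_params, ref_config):
    return simulate(ref_model, ref_params.to_dict(), ref_config)


@pytest.fixture(scope="session")
def ref_graph():
    return reference_graph()
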