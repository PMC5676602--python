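import pytest

from bansim.config import load_reference_config
from bansim.synth import generate_ecg


@pytest.fixture(scope="session")
def ref_config():
    """The shipped case-study configuration (costs, devices, contexts)."""
    return load_reference_config()


@pytest.fixture(scope="session")
def sd_graph(ref_config):
    return ref_config.application_graph()


@pytest.fixture(scope="session")
def devices(ref_config):
    return ref_config.device_profiles()


@pytest.fixture(scope="session")
def cost_model(ref_config):
    return ref_config.reference_cost_model()


@pytest.fixture(scope="session")
def clean_ecg_60bpm():
    """10 s of noise-free synthetic ECG at 60 beats/min with ground truth."""
    return generate_ecg(60.0, 10.0, seed=7)
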