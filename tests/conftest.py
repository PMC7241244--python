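import pytest

from emmfilter.chem_core import parse_structure
from emmfilter.emm_builder import build_emm
from emmfilter.fixtures import COMPOUND_PANEL, ToySpec, make_toy_model
from emmfilter.operator_miner import build_operator_library


@pytest.fixture(scope="session")
def panel():
    """Parsed molecules of the hard-coded compound panel."""
    return {name: parse_structure(smi) for name, smi in COMPOUND_PANEL.items()}


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec(seed=17)


@pytest.fixture(scope="session")
def toy_model(toy_spec):
    model, truth = make_toy_model(toy_spec)
    return model, truth


@pytest.fixture(scope="session")
def toy_library(toy_model):
    model, _ = toy_model
    return build_operator_library(model.reactions)


@pytest.fixture(scope="session")
def toy_emm(toy_model, toy_library):
    model, _ = toy_model
    return build_emm(model, toy_library)
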