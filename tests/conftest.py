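import pytest

from clonalqn.breast_model import build_breast_model, clone_configs
from clonalqn.screen import run_screen


@pytest.fixture(scope="session")
def in_vivo():
    return build_breast_model("in_vivo")


@pytest.fixture(scope="session")
def in_vitro():
    return build_breast_model("in_vitro")


@pytest.fixture(scope="session")
def clones():
    return clone_configs()


@pytest.fixture(scope="session")
def druggable_screen(in_vivo, clones):
    """The full druggable-target screen, shared across tests (seed 1)."""
    return run_screen(in_vivo, clones, seed=1)
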