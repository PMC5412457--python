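import warnings

import pytest

import thermoglyc as tg

# LSODA emits chatter when it hands stiff corners to the BDF fallback
warnings.filterwarnings("ignore", message=".*lsoda.*")


@pytest.fixture(scope="session")
def ssol_base_model():
    return tg.build_model("sulfolobus", "base")


@pytest.fixture(scope="session")
def ssol_base_steady(ssol_base_model):
    return tg.find_steady_state(ssol_base_model)


@pytest.fixture(scope="session")
def ssol_gapn_model():
    return tg.build_model("sulfolobus", "with_gapn")


@pytest.fixture(scope="session")
def ssol_gapn_steady(ssol_gapn_model):
    return tg.find_steady_state(ssol_gapn_model)


@pytest.fixture(scope="session")
def yeast_base_steady():
    return tg.find_steady_state(tg.build_model("yeast", "base"))
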