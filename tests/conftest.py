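import pytest

from oacea import load_fixture_model, load_published_base_case
from oacea.synthetic import toy_model_3cycle, toy_model_2state


@pytest.fixture(scope="session")
def fixture_model():
    """The packaged Thai knee-OA model (published inputs)."""
    return load_fixture_model()


@pytest.fixture(scope="session")
def published_base_case():
    """Published per-strategy (cost THB, QALY) pairs, in table order."""
    return load_published_base_case()


@pytest.fixture()
def toy3():
    return toy_model_3cycle()


@pytest.fixture()
def toy2():
    return toy_model_2state()
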