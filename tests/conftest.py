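import warnings

import pytest

from phobr import build_full_model, build_reduced_model


@pytest.fixture(scope="session")
def full_model():
    return build_full_model()


@pytest.fixture(scope="session")
def reduced_model():
    return build_reduced_model()


@pytest.fixture(autouse=True)
def _quiet_equilibrium_warnings():
    # steady-state probes in tests intentionally run off-equilibrium cases
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*equilibrium may not be reached.*"
        )
        yield
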