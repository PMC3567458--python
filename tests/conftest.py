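import numpy as np
import pytest

import raasim


@pytest.fixture(scope="session")
def raas_params():
    return raasim.load_raas_parameters()


@pytest.fixture(scope="session")
def body():
    return raasim.build_reference_body()


@pytest.fixture(scope="session")
def system(body, raas_params):
    """Shared default coupled system; tests must not mutate it."""
    return raasim.assemble_system(body, raas_params)


@pytest.fixture(scope="session")
def steady_state(system):
    """Pre-administration steady state of the default parameterisation."""
    return raasim.solve_steady_state(system)
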