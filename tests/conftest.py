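import numpy as np
import pytest

from sfekinetics import get_preset


@pytest.fixture(scope="session")
def pennyroyal():
    """Pennyroyal scenario: the fully parameterized reference system."""
    return get_preset("Mentha pulegium")


@pytest.fixture(scope="session")
def grid_5h():
    """25-point sampling grid over 0-5 h, the standard round-trip design."""
    return np.linspace(0.0, 5 * 3600.0, 25)
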