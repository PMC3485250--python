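import numpy as np
import pytest

from karstabc.synth import make_toy_fixtures


@pytest.fixture(scope="session")
def toy():
    """Committed miniature inputs with hand-computed expected values."""
    return make_toy_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(20120917)
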