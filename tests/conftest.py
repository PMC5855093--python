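import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="axonquant")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def circle_outline():
    """Closed circular outline, radius 5 um."""
    theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    return np.stack([5 * np.cos(theta), 5 * np.sin(theta)], axis=1)
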