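import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230123)


@pytest.fixture
def log_layout():
    from timecausal.layout import logarithmic_levels

    return logarithmic_levels(16.0, 2.0, 3)
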