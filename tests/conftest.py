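import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def const_beats():
    """Beat train at exactly 60 bpm for 5 min (no modulation, no noise)."""
    from cvawear.simulate import gen_rr_series

    return gen_rr_series(300.0, 60.0, 0.0, 0.0, 0.0, seed=0)
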