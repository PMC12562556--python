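import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_gradient(fn, x0, eps=1e-2):
    """Central-difference gradient of a scalar-valued fn of one array."""
    num = np.zeros_like(x0, dtype=np.float64)
    it = np.nditer(x0, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x0.copy()
        xp[i] += eps
        xm = x0.copy()
        xm[i] -= eps
        num[i] = (fn(xp) - fn(xm)) / (2 * eps)
    return num
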