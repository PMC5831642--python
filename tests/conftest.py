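import numpy as np
import pytest

from hiermut import make_architecture


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def arch_n3_half():
    """Four-compartment hierarchy with interior self-renewal 1/2."""
    return make_architecture(3, (65, 65, 65, 65), 0.5)


@pytest.fixture
def small_n2():
    return make_architecture(2, (4, 8, 12), 0.5)


def random_architecture(rng, n, size_range=(5, 50)):
    sizes = tuple(int(s) for s in rng.integers(*size_range, n + 1))
    v = [1.0] + list(rng.uniform(0.0, 1.0, max(n - 1, 0))) + [0.0]
    return make_architecture(n, sizes, v)
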