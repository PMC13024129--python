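import numpy as np
import pytest

from radarbp.synth import DatasetSpec, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Clean 6-subject cohort with short windows (fast to generate)."""
    return make_dataset(6, 8, corrupt_fraction=0.0, rng_seed=11,
                        spec=DatasetSpec(window_len=256))


@pytest.fixture(scope="session")
def corrupted_dataset():
    """10-subject cohort, 30% corrupted at severity >= 0.5."""
    return make_dataset(10, 12, corrupt_fraction=0.3, rng_seed=23,
                        spec=DatasetSpec(window_len=512))


def numeric_gradient(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
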