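import numpy as np
import pytest

from rectseg.imgio import SegMask
from rectseg.phantom import PhantomConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 4+4-subject phantom cohort on disk, shared across tests."""
    out = tmp_path_factory.mktemp("cohort")
    config = PhantomConfig(seed=7)
    records = generate_cohort(config, 4, 4, out)
    return config, records, out


def random_mask(rng, shape=(12, 12, 12), p=0.2, spacing=(1.0, 1.0, 1.0)):
    values = rng.random(shape) < p
    if not values.any():
        values[tuple(s // 2 for s in shape)] = True
    return SegMask(values=values, spacing=spacing)
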