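import dataclasses

import numpy as np
import pytest

from wbcseg import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scenes():
    """Twelve 64x64 scenes with ground truth, shared across tests."""
    spec = synthetic.SceneSpec.for_size(64)
    seeds = np.random.SeedSequence(777).generate_state(12) % (2 ** 31)
    return [synthetic.generate_scene(dataclasses.replace(spec, seed=int(s)))
            for s in seeds]
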