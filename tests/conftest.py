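import numpy as np
import pytest

from omicforest import SimSpec, generate


@pytest.fixture(scope="session")
def tiny_sim():
    """Small balanced three-modality dataset with a clear planted signal."""
    return generate(
        SimSpec(
            n_per_class=(12, 12, 12),
            dims=(40, 40, 20),
            n_informative=(10, 10, 6),
            effect_size=2.5,
            seed=7,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
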