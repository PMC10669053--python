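import numpy as np
import pytest

from cardioseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_case():
    """One default-resolution phantom (16, 96, 96), deterministic."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def small_phantom_case():
    """A reduced-resolution phantom for fast network tests."""
    return generate_phantom(
        PhantomSpec(shape=(8, 64, 64), spacing=(5.0, 1.5, 1.5), seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
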