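import numpy as np
import pytest

from pectseg import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_phantom():
    """One default upper-left phantom: (GrayImage, muscle truth, breast truth)."""
    return phantom.generate(phantom.PhantomSpec())


@pytest.fixture(scope="session")
def fold_phantom():
    """Default phantom plus a sharp skin fold parallel to the muscle edge."""
    a, b, c = 3e-4, -0.441, 118.0
    fold = phantom.SkinFold(
        p0=(36, int(a * 36**2 + b * 36 + c + 40)),
        p1=(96, int(a * 96**2 + b * 96 + c + 40)),
        contrast=40.0,
    )
    spec = phantom.PhantomSpec(skin_fold=fold)
    return phantom.generate(spec), spec
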