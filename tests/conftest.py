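import numpy as np
import pytest

from immunoseg import PhantomSpec, generate_bilevel, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def bilevel_half():
    """Noiseless 64x64 image, exactly half pixels at 10 and half at 200 —
    the fixture whose Otsu variance is hand-checkable (9025)."""
    return generate_bilevel(64, 64, 10, 200, 0.5, seed=11)


@pytest.fixture
def four_class_phantom():
    """32x32 phantom with class means 30/90/150/220 and noise sigma 8."""
    return generate_phantom(
        PhantomSpec(
            height=32, width=32, class_means=(30, 90, 150, 220),
            noise_sigma=8.0, seed=5,
        )
    )
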