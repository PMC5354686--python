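import numpy as np
import pytest

import bpeq


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom: geometry and masks are exact."""
    spec = bpeq.PhantomSpec(shape=(96, 96, 32), sigma_noise=0.0, seed=1)
    pre, posts, truth = bpeq.generate_phantom(spec)
    return spec, pre, posts, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom at 5% of fat-intensity noise (the study's stress condition)."""
    spec = bpeq.PhantomSpec(shape=(96, 96, 32), sigma_noise=5.0, seed=2)
    pre, posts, truth = bpeq.generate_phantom(spec)
    return spec, pre, posts, truth


@pytest.fixture(scope="session")
def clean_breast_masks(clean_phantom):
    _, pre, _, _ = clean_phantom
    return bpeq.segment_whole_breast(pre)


@pytest.fixture(scope="session")
def noisy_breast_masks(noisy_phantom):
    _, pre, _, _ = noisy_phantom
    return bpeq.segment_whole_breast(pre)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())
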