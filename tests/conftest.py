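import numpy as np
import pytest

from wsimil.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(n_patients=12, rng_seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def toy_mask() -> np.ndarray:
    """A deterministic 2048x2048 label mask with known composition.

    Quadrants of the first 1024-block: pure stroma; the rest mixes classes
    so every filtering/cluster branch is exercised.
    """
    mask = np.zeros((2048, 2048), dtype=np.uint8)
    mask[:1024, :1024] = 1  # all stroma
    mask[:1024, 1024:] = 2  # all epithelium
    mask[1024:, :1024:2] = 1  # half stroma, half background (columns)
    # bottom-right: half stroma / half epithelium
    mask[1024:, 1024:] = 1
    mask[1024 + 512 :, 1024:] = 2
    return mask


@pytest.fixture(scope="session")
def toy_image(toy_mask) -> np.ndarray:
    rng = np.random.default_rng(0)
    img = rng.integers(0, 256, size=(*toy_mask.shape, 3), dtype=np.uint8)
    return img
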