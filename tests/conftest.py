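import numpy as np
import pytest

from petrad.images import ROIMask, SUVImage
from petrad.phantom import PhantomSpec, generate_lesion_image


@pytest.fixture(scope="session")
def phantom_image():
    """One default phantom shared across tests (deterministic)."""
    image, voi = generate_lesion_image(PhantomSpec(seed=42))
    return image, voi


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(values, spacing=(4.0, 4.0, 4.0)):
    return SUVImage(np.asarray(values, dtype=float), spacing=spacing)


def make_mask(values, spacing=(4.0, 4.0, 4.0), role="VOI"):
    return ROIMask(np.asarray(values, dtype=bool), spacing=spacing, role=role)


def full_voi(shape, spacing=(4.0, 4.0, 4.0)):
    return make_mask(np.ones(shape, dtype=bool), spacing=spacing)


def random_level_grid(rng, max_side=6, max_ng=6):
    """Random small level grid with a random mask, 0 outside the mask."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    ng = int(rng.integers(2, max_ng + 1))
    lev = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[0] = True
    lev[~mask] = 0
    # re-compact so the maximum level present equals ng as the engine assumes
    present = np.unique(lev[lev > 0])
    remap = {g: k + 1 for k, g in enumerate(present)}
    out = np.zeros_like(lev)
    for g, k in remap.items():
        out[lev == g] = k
    return out, len(present)


def disc_from_levels(lev, ng):
    """Wrap a ready-made level grid as a DiscretizedROI for matrix tests."""
    from petrad.segmentation import DiscretizedROI

    lev = np.asarray(lev, dtype=np.int32)
    mask = ROIMask(lev > 0, spacing=(4.0, 4.0, 4.0), role="VOI")
    return DiscretizedROI(
        level_grid=lev, mask=mask, ng=int(ng), method="fixed_bin_count",
        n_bins=int(ng), raw_bins=np.arange(1, int(ng) + 1),
    )
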