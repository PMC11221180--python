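import numpy as np
import pytest

from pneumostage import maskops, phantom, preprocess


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 128-px phantom with mixed profusion grades."""
    spec = phantom.PhantomSpec(image_size=128, profusion_per_subregion=(1, 0, 2, 0, 3, 0), seed=7)
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def two_ellipse_mask():
    """A clean two-lung mask at 128 px."""
    spec = phantom.PhantomSpec(image_size=128, seed=3)
    return phantom.generate_phantom(spec).mask


@pytest.fixture(scope="session")
def profusion_crop_bank():
    """500 subregion crops at 32 px with uniform grade mix, grouped by phantom.

    Returns (crops, levels, owner_index); splitting by owner avoids
    leaking crops of one phantom across train/validation.
    """
    rng = np.random.default_rng(123)
    crops, levels, owner = [], [], []
    n_ph = 0
    while len(crops) < 500:
        lv = tuple(int(v) for v in rng.integers(0, 4, 6))
        spec = phantom.PhantomSpec(image_size=128, profusion_per_subregion=lv,
                                   seed=int(rng.integers(0, 2 ** 31 - 1)))
        s = phantom.generate_phantom(spec)
        regions = maskops.partition_six(s.mask, s.image)
        for key, level in zip(maskops.SUBREGION_KEYS, s.profusions):
            crops.append(preprocess.downsample(regions.crops[key].astype(np.float32), 32))
            levels.append(level)
            owner.append(n_ph)
        n_ph += 1
    return crops[:500], np.asarray(levels[:500]), np.asarray(owner[:500])
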