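import numpy as np
import pytest

from nucleotex.segmentation import RegionPatch
from nucleotex.synthetic import ClassRecipe, generate_dataset_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def stair_patch():
    """3x3 binary-staircase patch used in several worked examples."""
    levels = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=np.int32)
    return levels


@pytest.fixture
def region_patch(rng):
    """A 7x7 region patch with an irregular mask and smooth gray values."""
    gray = rng.uniform(0.2, 0.8, size=(7, 7))
    mask = np.ones((7, 7), dtype=bool)
    mask[0, 0] = mask[6, 6] = mask[0, 6] = False
    return RegionPatch(gray=gray, mask=mask, region_id=1,
                       area=int(mask.sum()), bbox=(0, 0, 7, 7))


@pytest.fixture(scope="session")
def small_recipes():
    """Shrunken separable recipes for fast end-to-end tests."""
    return (
        ClassRecipe(name="PV", n_nuclei=(6, 9), radius=(3.0, 5.0),
                    intensity_mean=0.30, intensity_sd=0.09, grain=0.7,
                    clustering=0.15),
        ClassRecipe(name="ET", n_nuclei=(3, 5), radius=(7.0, 10.0),
                    intensity_mean=0.45, intensity_sd=0.05, grain=2.5,
                    clustering=0.85),
        ClassRecipe(name="MF", n_nuclei=(5, 7), radius=(4.0, 6.0),
                    intensity_mean=0.38, intensity_sd=0.13, grain=1.5,
                    clustering=0.4, bg_sigma=(2.0, 16.0)),
    )


@pytest.fixture(scope="session")
def mini_dataset(small_recipes):
    """10 tiles/class at side 96: enough nuclei for separable features."""
    return generate_dataset_arrays(small_recipes, n_per_class=10, side=96,
                                   seed=11)
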