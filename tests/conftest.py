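"""Shared fixtures: the toy gray matrix and a few synthetic lesions.

Everything is generated programmatically; module-scoped fixtures keep the
expensive renders (224 px lesions, hair pairs) to one per session.
"""

import numpy as np
import pytest

from dermaug import SyntheticLesionSpec, generate_lesion_image, toy_gray_matrix
from dermaug.features import GrayLesion, quantize_and_mask


@pytest.fixture(scope="session")
def toy_gl() -> GrayLesion:
    """The fixed 4x4, 4-level oracle matrix as a fully-masked GrayLesion."""
    toy = toy_gray_matrix()
    return GrayLesion(gray=toy, mask=np.ones_like(toy, dtype=bool), Ng=4)


@pytest.fixture(scope="session")
def disk_sample():
    """Symmetric disk lesion: eccentricity 1, no waviness, no asymmetry."""
    return generate_lesion_image(SyntheticLesionSpec(seed=1))


@pytest.fixture(scope="session")
def textured_sample():
    """Melanoma-style lesion with texture and colour variegation, no hair."""
    return generate_lesion_image(SyntheticLesionSpec(
        image_size=224, texture_noise_sigma=6.0, variegation_spots=3,
        class_label=1, seed=7))


@pytest.fixture(scope="session")
def hair_pair():
    """(hairless, hairy) renders of the same lesion; only strokes differ."""
    kwargs = dict(image_size=224, texture_noise_sigma=6.0, variegation_spots=3,
                  class_label=1, seed=3)
    clean = generate_lesion_image(SyntheticLesionSpec(n_hairs=0, **kwargs))
    hairy = generate_lesion_image(SyntheticLesionSpec(n_hairs=10, **kwargs))
    return clean, hairy


@pytest.fixture(scope="session")
def hair_pair_plain():
    """(hairless, hairy) pair without colour variegation, for checks that
    isolate the hair operator from spot-edge structure."""
    kwargs = dict(image_size=224, texture_noise_sigma=6.0, variegation_spots=0,
                  class_label=1, seed=5)
    clean = generate_lesion_image(SyntheticLesionSpec(n_hairs=0, **kwargs))
    hairy = generate_lesion_image(SyntheticLesionSpec(n_hairs=10, **kwargs))
    return clean, hairy


@pytest.fixture(scope="session")
def textured_gl(textured_sample) -> GrayLesion:
    return quantize_and_mask(textured_sample.image, textured_sample.mask, Ng=32)
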