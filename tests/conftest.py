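import warnings

import numpy as np
import pytest

from sliceatlas import phantom as ph
from sliceatlas.core_data import Rotation, rotate_and_reslice

warnings.filterwarnings("ignore", message="mask has .* boundary components")


@pytest.fixture(scope="session")
def atlas_pair():
    """Default synthetic reference volume + annotation."""
    return ph.make_atlas(ph.PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def atlas_volume(atlas_pair):
    return atlas_pair[0]


@pytest.fixture(scope="session")
def atlas_annotation(atlas_pair):
    return atlas_pair[1]


@pytest.fixture(scope="session")
def native_reslice(atlas_pair):
    """Unrotated coronal planes of the reference volume + annotation."""
    volume, annotation = atlas_pair
    return (
        rotate_and_reslice(volume, Rotation(0.0, 0.0)),
        rotate_and_reslice(annotation, Rotation(0.0, 0.0)),
    )


@pytest.fixture(scope="session")
def mid_plane(native_reslice):
    """A central textured plane with its coherent/empty masks."""
    atlas, ann = native_reslice
    j = len(atlas) // 2
    plane = atlas.slices[j] / atlas.slices[j].max()
    r_e = np.isin(ann.slices[j], [0, ph.VENTRICLE_LABEL])
    return plane, ~r_e, r_e


@pytest.fixture(scope="session")
def tilted_stack(atlas_pair):
    """Stack sectioned at (0, +4) degrees with the default corruption."""
    volume, annotation = atlas_pair
    return ph.make_sectioned_stack(volume, annotation, 0.0, 4.0, seed=1)
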