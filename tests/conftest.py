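"""Shared fixtures: phantoms at desk scale, rendered images, tmp artifacts."""

import numpy as np
import pytest

from grainmri.io import IntensityVolume, LabelVolume
from grainmri.phantom import NoiseSpec, PhantomSpec, generate_phantom, render_intensity

GRID = (112, 72, 72)
INSTANCE_SHAPE = (96, 64, 64)


@pytest.fixture(scope="session")
def default_phantom():
    """Canonical-pose grain phantom with truth (session cached)."""
    return generate_phantom(PhantomSpec(), GRID)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Solid digital sphere of radius 20, single (endosperm) class."""
    spec = PhantomSpec(semi_axes=(20, 20, 20), exponent=2, pericarp_thickness=0,
                       aleurone_thickness=0, embryo_fraction=0, crease_depth=0)
    return generate_phantom(spec, (48, 48, 48))


@pytest.fixture()
def clean_image(default_phantom):
    """Noise-free rendering of the default phantom."""
    labels, _ = default_phantom
    return render_intensity(labels, NoiseSpec(noise_sd=0, faulty_frame_prob=0))


@pytest.fixture()
def noisy_image(default_phantom):
    """Default-noise rendering (SD 3 on class gaps >= 30, 2% faulty frames)."""
    labels, _ = default_phantom
    return render_intensity(labels, NoiseSpec(seed=7))


@pytest.fixture()
def cube_volume():
    """10x10x10 solid cube of endosperm in a 16^3 grid at r=0.04 mm."""
    data = np.zeros((16, 16, 16), dtype=np.uint8)
    data[3:13, 3:13, 3:13] = 2
    return LabelVolume(data, voxel_size=0.04, source_id="cube")


def as_intensity(lab: LabelVolume) -> IntensityVolume:
    return render_intensity(lab, NoiseSpec(noise_sd=0, faulty_frame_prob=0))
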