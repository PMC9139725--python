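import numpy as np
import pytest

from pefquant.imaging_io import CTVolume, SegMask
from pefquant.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def hemo_phantom():
    """One 300 mL hemopericardium phantom with a pleural confounder."""
    spec = PhantomSpec(
        effusion_class="hemopericardium",
        target_volume_ml=300.0,
        contrast=True,
        pleural_effusion=True,
        seed=7,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def simple_phantom():
    spec = PhantomSpec(
        effusion_class="simple_pef", target_volume_ml=200.0, seed=11
    )
    return spec, *generate_phantom(spec)


@pytest.fixture
def flat_volume():
    """Uniform soft-tissue volume (no lungs, no effusion)."""
    return CTVolume(np.full((32, 32, 32), 40, dtype=np.int16), (2.0, 2.0, 2.0))


def make_mask(shape, spacing, where=None, label="reference"):
    data = np.zeros(shape, dtype=np.uint8)
    if where is not None:
        data[where] = 1
    return SegMask(data, spacing, label=label)
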