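import numpy as np
import pytest

from liverseg.imaging_io import ImageVolume, MaskVolume, VolumeGeometry, normalize_intensity
from liverseg.model import ModelConfig, build_model
from liverseg.phantom import PhantomConfig, generate_phantom


def make_mask(shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0), fg=None):
    """MaskVolume with voxels listed in ``fg`` (index tuples) set to 1."""
    vox = np.zeros(shape, dtype=np.uint8)
    if fg is not None:
        for idx in fg:
            vox[idx] = 1
    return MaskVolume(vox, VolumeGeometry(spacing_mm=spacing))


def random_mask(rng, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), p=0.3, nonempty=True):
    vox = rng.random(shape) < p
    if nonempty and not vox.any():
        vox[tuple(rng.integers(0, s) for s in shape)] = True
    return MaskVolume(vox, VolumeGeometry(spacing_mm=spacing))


@pytest.fixture(scope="session")
def separable_cases():
    """Noiseless, lesion-free phantoms: trivially separable by threshold."""
    cases = []
    for seed in range(4):
        img, mask = generate_phantom(PhantomConfig(
            grid_shape=(48, 48, 32), liver_volume_ml=300,
            lesion_count=0, confounder_count=0, noise_sigma=0.0, seed=seed))
        cases.append((normalize_intensity(img), mask))
    return cases


@pytest.fixture(scope="session")
def textured_phantom():
    """One phantom with lesions, confounders and noise."""
    return generate_phantom(PhantomConfig(
        grid_shape=(48, 48, 32), liver_volume_ml=300, lesion_count=2,
        confounder_count=2, noise_sigma=0.02, seed=11))


@pytest.fixture(scope="session")
def small_model():
    return build_model(ModelConfig.small(), seed=0)
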