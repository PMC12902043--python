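import numpy as np
import pytest

from pollenholo import (FieldGeometry, ComplexField, NoiseModel,
                        normalize_hologram, render_phantom, simulate_hologram)

STUDY_H_UM = 2546.0


@pytest.fixture
def geometry_small() -> FieldGeometry:
    return FieldGeometry(n_x=128, n_y=128, pitch=2.0, wavelength=0.658)


@pytest.fixture
def geometry_scene() -> FieldGeometry:
    return FieldGeometry(n_x=512, n_y=512, pitch=2.0, wavelength=0.658)


def gaussian_field(geometry: FieldGeometry, waist_um: float) -> ComplexField:
    """Centred Gaussian amplitude spot with 1/e radius `waist_um`."""
    y = (np.arange(geometry.n_y) - geometry.n_y / 2) * geometry.pitch
    x = (np.arange(geometry.n_x) - geometry.n_x / 2) * geometry.pitch
    r2 = y[:, None] ** 2 + x[None, :] ** 2
    return ComplexField(geometry, np.exp(-r2 / waist_um**2).astype(complex))


@pytest.fixture
def disk_scene(geometry_scene):
    """A small noiseless pollen scene with its normalised hologram."""
    scene = render_phantom(None, geometry_scene, n_grains=4, rng_seed=3)
    holo = normalize_hologram(simulate_hologram(scene, STUDY_H_UM))
    return scene, holo
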