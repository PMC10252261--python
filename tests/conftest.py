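import numpy as np
import pytest

from lacs import CTVolume, PhantomSpec, PlaqueSpec, generate_phantom_pair

AXIS_XY_MM = (44.45, 44.45)  # physical center of the default 128x0.7 grid


def crisp_spec(plaques, **overrides):
    """A noiseless, blur-free phantom spec with constant-HU compartments."""
    kwargs = dict(
        plaques=plaques,
        blur_fwhm_mm=0.0,
        noise_sd_hu=0.0,
        contrast_lumen=(350.0, 0.0),
        noncontrast_lumen=(40.0, 0.0),
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


THREE_PLAQUES = (
    PlaqueSpec(center=(AXIS_XY_MM[0] + 9, AXIS_XY_MM[1], 15.0),
               semi_axes=(3.0, 3.0, 3.0), hu_mean=700.0),
    PlaqueSpec(center=(AXIS_XY_MM[0] - 9, AXIS_XY_MM[1], 30.0),
               semi_axes=(4.0, 3.0, 2.5), hu_mean=900.0),
    PlaqueSpec(center=(AXIS_XY_MM[0], AXIS_XY_MM[1] + 9, 45.0),
               semi_axes=(2.0, 2.0, 2.0), hu_mean=500.0),
)


@pytest.fixture(scope="session")
def crisp_pair():
    """Noiseless, blur-free 128x128x80 phantom with three plaques."""
    return generate_phantom_pair(crisp_spec(THREE_PLAQUES))


@pytest.fixture
def rng():
    return np.random.default_rng(20230601)


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(values), spacing)
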