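import numpy as np
import pytest

from dhmwound import OpticalConfig, PhaseImage


@pytest.fixture
def cfg():
    """Default optics: 532 nm, medium 1.339, alpha 2e-4 m^3/kg, 0.5 um pitch."""
    return OpticalConfig()


@pytest.fixture
def fine_cfg():
    """Finer sampling used for single-cell fitting tests."""
    return OpticalConfig(pixel_pitch_um=0.25)


def uniform_image(value: float, shape=(20, 20), pitch=0.5, time_min=None) -> PhaseImage:
    return PhaseImage(values=np.full(shape, float(value)), pixel_pitch_um=pitch, time_min=time_min)


@pytest.fixture
def full_mask():
    def _make(img: PhaseImage) -> np.ndarray:
        return np.ones(img.shape, dtype=bool)

    return _make
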