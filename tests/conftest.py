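import numpy as np
import pytest

from paramuscle import ImageSlice, PhantomSpec, ROISet, generate_phantom


@pytest.fixture
def small_phantom():
    """Noiseless, bias-free 64x64 phantom with exact ground truth."""
    spec = PhantomSpec(
        shape=(64, 64),
        spacing=(0.5, 0.5),
        left_ellipse=(40, 20, 12, 9),
        right_ellipse=(40, 44, 12, 9),
        endplate_ellipse=(14, 32, 7, 10),
        fat_fraction=0.3,
        noise_sd=0.0,
        bias_amplitude=0.0,
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture
def flat_slice():
    return ImageSlice(pixels=np.full((32, 32), 100.0), spacing_row=0.5, spacing_col=0.5)


def make_roi(shape=(32, 32), labels=((1, slice(4, 12), slice(4, 12)),
                                     (2, slice(4, 12), slice(20, 28)),
                                     (3, slice(20, 28), slice(12, 20)))):
    mask = np.zeros(shape, dtype=np.int16)
    for lab, rs, cs in labels:
        mask[rs, cs] = lab
    return ROISet(mask=mask)
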