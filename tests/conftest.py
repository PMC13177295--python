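import numpy as np
import pytest

from mirsiprep import PhantomConfig, TissueMask, generate_roi, make_spectral_axis


@pytest.fixture(scope="session")
def axis():
    """The instrument's 950-1800 cm^-1 axis at 2 cm^-1 (426 points)."""
    return make_spectral_axis(950.0, 1800.0, 2.0)


@pytest.fixture(scope="session")
def liver_ff_roi():
    """One default FF liver phantom ROI with its ground truth."""
    return generate_roi(PhantomConfig("liver", "FF", roi_shape=(64, 64), seed=11))


def truth_mask(truth) -> TissueMask:
    """Wrap a phantom's planted mask as a TissueMask."""
    return TissueMask(mask=truth.mask, threshold_used=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)
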