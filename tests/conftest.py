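import numpy as np
import pytest

from phantomnoise import (
    AlignmentParams,
    Aligner,
    NoiseSpec,
    blob_phantom,
    make_dataset,
)


@pytest.fixture(scope="session")
def phantom32():
    """Small asymmetric blob phantom used by fast unit tests."""
    return blob_phantom(12, 32, rng=np.random.default_rng(5))


@pytest.fixture(scope="session")
def phantom48():
    """Medium phantom shared by alignment/validation tests."""
    return blob_phantom(14, 48, rng=np.random.default_rng(5))


@pytest.fixture(scope="session")
def aligner48(phantom48):
    """Shared 12-degree aligner for the 48-box phantom."""
    p = AlignmentParams(angular_step=12.0, inplane_step=4.0, max_shift=8.0)
    return Aligner(phantom48, p)


@pytest.fixture(scope="session")
def noisefree500(phantom32):
    """500 noise-free projections of the small phantom with ground truth."""
    return make_dataset(phantom32, 500, NoiseSpec(np.inf), rng=np.random.default_rng(11))
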