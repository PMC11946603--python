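import numpy as np
import pytest

from tmjjsw import LabelMask, PhantomSpec, generate_cohort


@pytest.fixture
def make_mask():
    """Factory wrapping a 2D label array in a LabelMask with given spacing."""
    def _make(labels, spacing_mm=(1.0, 1.0), id="case"):
        return LabelMask(labels=np.asarray(labels, dtype=np.uint8),
                         spacing_mm=spacing_mm, id=id)
    return _make


@pytest.fixture(scope="session")
def cohort20():
    """A small default-geometry phantom cohort shared across tests."""
    return generate_cohort(20, jsw_range_mm=(0.8, 4.0), seed=101)


@pytest.fixture(scope="session")
def toy_cohort():
    """64x64 phantoms sized for quick network training."""
    base = PhantomSpec(image_size=(64, 64), band_thickness_px=4)
    return generate_cohort(25, jsw_range_mm=(0.6, 1.8), base_spec=base, seed=11)
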