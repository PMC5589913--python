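import numpy as np
import pytest

from epiratchet.geometry import ImagingMetadata, TissueFrame


@pytest.fixture
def meta():
    return ImagingMetadata(pixel_size=0.164, frame_interval=1.0)


@pytest.fixture
def unit_meta():
    return ImagingMetadata(pixel_size=1.0, frame_interval=1.0)


def three_cell_labels(size=60):
    """Three mutually adjacent cells meeting at one interior point."""
    lab = np.zeros((size, size), dtype=np.int64)
    h = size // 2
    lab[:h, :h] = 1
    lab[:h, h:] = 2
    lab[h:, :] = 3
    return lab


def quad_labels(size=40):
    """2x2 block of four cells meeting at a single 4-fold junction."""
    lab = np.zeros((size, size), dtype=np.int64)
    h = size // 2
    lab[:h, :h] = 1
    lab[:h, h:] = 2
    lab[h:, :h] = 3
    lab[h:, h:] = 4
    return lab


@pytest.fixture
def three_cell_frame(unit_meta):
    return TissueFrame.from_labels(three_cell_labels(), 0, unit_meta)


@pytest.fixture
def static_tissue():
    from epiratchet.synth import synth_tissue

    return synth_tissue(mode="static", n_frames=2, membrane_noise=0.0,
                        seed=11)
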