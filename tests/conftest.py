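import numpy as np
import pytest

from blastoquant import pipeline as pl
from blastoquant import synthgen as sg
from blastoquant.config import PipelineConfig
from blastoquant.core import Channel
from blastoquant.staging import TimeClass


@pytest.fixture(scope="session")
def gt_domains():
    """Three-boundary giant-like pattern: anterior lobe + central domain."""
    return sg.default_domains("gt", Channel.NBT_BCIP)


@pytest.fixture(scope="session")
def geometry():
    return sg.EmbryoGeometry(300.0, 120.0, (350.0, 175.0), rotation_deg=17.0)


@pytest.fixture(scope="session")
def clean_embryo(geometry, gt_domains):
    """Noise-free rotated synthetic embryo with its ground-truth entry."""
    return sg.generate_embryo(
        geometry, gt_domains, TimeClass(14, 4), noise_sd=0.0, seed=42
    )


@pytest.fixture(scope="session")
def clean_result(clean_embryo):
    """Full pipeline output for the noise-free embryo."""
    record, _ = clean_embryo
    return pl.process_embryo(record, PipelineConfig())


@pytest.fixture()
def rect_mask():
    """Factory for rectangular masks of given height/width at offset."""
    from blastoquant.segmentation import EmbryoMask

    def make(height, width=600, top=10, left=50, canvas=None):
        shape = canvas or (height + 2 * top, width + 2 * left)
        m = np.zeros(shape, dtype=bool)
        m[top : top + height, left : left + width] = True
        return EmbryoMask(m)

    return make
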