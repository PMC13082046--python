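import numpy as np
import pytest

from txseg.io_types import PixelFrame
from txseg.pseudoimage import build_stack
from txseg.simulate import SimulationParams, simulate_tissue


@pytest.fixture(scope="session")
def tissue():
    """Shared desk-scale tissue: packed elongated cells with off-center
    nuclei — the regime where fixed-radius nuclear expansion struggles."""
    return simulate_tissue(
        SimulationParams(
            seed=1,
            frame=PixelFrame(384, 384, pixel_size=0.25),
            n_cells=55,
            nucleus_offset_fraction=0.3,
            cell_elongation_range=(1.0, 3.0),
        )
    )


@pytest.fixture(scope="session")
def tissue_stack(tissue):
    return build_stack(tissue.dapi, tissue.transcripts, tissue.cell_mask.frame)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
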