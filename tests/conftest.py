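import numpy as np
import pytest

from metaseg.fcn_model import ModelSpec, build_modified_fcn
from metaseg.synthetic_wsi import SynthConfig, generate_slide

#: narrow channel widths keeping the 5-block / 13-conv topology
TINY_BLOCKS = ((2, 2), (2, 2), (3, 4), (3, 4), (3, 4))


@pytest.fixture(scope="session")
def small_synth_config():
    """Desk-scale slide: 512 px at 8 um/px so all three focus classes fit."""
    return SynthConfig(width_px=512, height_px=512, mpp=8.0,
                       n_macro=1, n_micro=1, n_itc=2,
                       tissue_fraction=0.6, seed=7)


@pytest.fixture(scope="session")
def small_slide(small_synth_config):
    return generate_slide(small_synth_config)


@pytest.fixture(scope="session")
def tiny_model():
    """Width-reduced network with 64 px tiles for fast forward passes."""
    spec = ModelSpec(input_size=64, pad=16, blocks=TINY_BLOCKS)
    return build_modified_fcn(spec, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
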