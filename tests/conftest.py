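import numpy as np
import pytest

import graftdcs as g
from graftdcs.pipeline import geometry_for_config, scaled_phantom_config
from graftdcs.synthetic import ImagingConfig


@pytest.fixture(scope="session")
def half_config():
    """Half-scale phantom: same anatomy, ~1/8 the voxels, ~200 cells."""
    return scaled_phantom_config(scale=0.5).replace(n_cells=200, truth_grid_um=15.0)


@pytest.fixture(scope="session")
def half_geometry(half_config):
    return geometry_for_config(half_config, pixel_size_um=10.32)


@pytest.fixture(scope="session")
def half_phantom(half_config):
    return g.generate_phantom(half_config, seed=11)


@pytest.fixture(scope="session")
def half_dataset(half_phantom, half_geometry):
    return g.section_phantom(half_phantom, half_geometry, seed=12)


@pytest.fixture(scope="session")
def noiseless_biased(half_config, half_geometry):
    """Noise-free, strongly dorsally biased phantom and its sections."""
    cfg = half_config.replace(dorsal_bias=0.8, n_cells=0)
    phantom = g.generate_phantom(cfg, seed=21)
    ds = g.section_phantom(phantom, half_geometry, imaging=ImagingConfig(noise_sd=0.0), seed=22)
    return phantom, ds
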