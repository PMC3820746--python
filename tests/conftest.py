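import logging

import pytest

from furrowseg import IntensityImage, SimulationConfig, segment
from furrowseg.simulate import simulate_embryo

# the pipeline deliberately logs sufficiency warnings on small fixtures
logging.getLogger("furrowseg").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def wt_noiseless():
    """Small intact embryo, noiseless: (image, lattice, ground truth)."""
    cfg = SimulationConfig(
        image_size_px=(512, 512), n_nuclei=100, noise_sd=0.0, seed=1
    )
    return simulate_embryo(cfg) + (cfg,)


@pytest.fixture(scope="session")
def wt_noiseless_seg(wt_noiseless):
    img, lattice, gt, cfg = wt_noiseless
    return segment(IntensityImage(img, cfg.pixel_size_um))


@pytest.fixture(scope="session")
def mutant_noiseless():
    """Small embryo with ~10% planted furrow failures, noiseless."""
    cfg = SimulationConfig(
        image_size_px=(512, 512), n_nuclei=100, noise_sd=0.0,
        failure_fraction=0.1, seed=3,
    )
    return simulate_embryo(cfg) + (cfg,)
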