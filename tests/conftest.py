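import numpy as np
import pytest

from varcnn.backbone import ArchitectureSpec, BlockSpec
from varcnn.synthetic import PhantomConfig, make_cohort


def small_arch(input_shape, channels=(2, 4, 8, 8, 16)):
    """Five-block backbone with reduced widths for fast tests."""
    return ArchitectureSpec(tuple(BlockSpec(out_channels=c) for c in channels),
                            input_shape=tuple(input_shape))


@pytest.fixture(scope="session")
def tiny_cohort():
    """20 phantoms at (8,12,8): enough to exercise the full pipeline in seconds."""
    cfg = PhantomConfig(shape=(8, 12, 8), n_per_class=10, signal_radius_nc=1.5,
                        atrophy_fraction=0.3, noise_sd=0.5, n_redundant_blobs=2,
                        morph_effect=(1.5, 1.5, 1.5), seed=11)
    return cfg, make_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
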