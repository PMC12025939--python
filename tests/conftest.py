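import numpy as np
import pytest

from tendont2 import PhantomConfig, TendonMask, generate_phantom
from tendont2.pipeline import run_phantom_subject

# Table-style echo train used throughout (ms)
ECHO_TRAIN = (11.4, 22.8, 34.2, 45.6, 57.0, 68.4, 79.8, 91.2)


def straight_config(**overrides) -> PhantomConfig:
    """Straight horizontal band: analytic length coordinate available."""
    base = dict(
        grid_shape=(48, 220),
        centerline=((24.0, 10.0), (24.0, 209.0)),
        half_thickness=4.0,
        noise_sigma=0.0,
        seed=7,
    )
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def noiseless_phantom():
    cfg = PhantomConfig(noise_sigma=0.0, seed=11)
    image, truth = generate_phantom(cfg)
    return image, truth


@pytest.fixture(scope="session")
def noiseless_run():
    """Full noiseless pipeline run on the default curved phantom."""
    return run_phantom_subject(PhantomConfig(noise_sigma=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_run():
    """Pipeline run at the default 2% Rician noise level."""
    return run_phantom_subject(PhantomConfig(seed=5))


def mask_of(truth) -> TendonMask:
    return TendonMask(
        voxels=truth.mask,
        lateral_seed=truth.lateral_seed,
        medial_seed=truth.medial_seed,
    )
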