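"""Shared fixtures: scaled-down phantoms so the imaging tests run fast."""

import numpy as np
import pytest

from lungntcp.phantom import PhantomConfig, generate_ct_pair
from lungntcp.volume import RigidTransform

#: Geometry scaled for a 65^3 grid: lungs ~14 cm^3, 33 mm dose block.
SMALL_KW = dict(
    shape=(65, 65, 65),
    body_semiaxes=(28.0, 26.0, 29.0),
    lung_semiaxes=(10.5, 15.0, 21.0),
    lung_offset_mm=15.0,
    dose_block_size_mm=32.0,
    r50_mm=12.0,
)
#: Segmentation size floor matching the small lungs.
SMALL_MIN_LUNG_CM3 = 10.0


def small_config(**overrides) -> PhantomConfig:
    kw = dict(SMALL_KW)
    kw.update(overrides)
    return PhantomConfig(**kw)


@pytest.fixture(scope="session")
def small_noiseless():
    """Noiseless, perfectly aligned small phantom."""
    cfg = small_config(
        hu_noise_sd=0.0, misalignment=RigidTransform(), seed=101
    )
    planning, followup, dose, truth = generate_ct_pair(cfg)
    return cfg, planning, followup, dose, truth


@pytest.fixture(scope="session")
def small_shifted():
    """Small phantom with HU noise and a (+4, -2, +3) mm mis-alignment."""
    cfg = small_config(seed=202)
    planning, followup, dose, truth = generate_ct_pair(cfg)
    return cfg, planning, followup, dose, truth


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size 96^3 phantom with the default study conditions."""
    cfg = PhantomConfig(seed=303)
    planning, followup, dose, truth = generate_ct_pair(cfg)
    return cfg, planning, followup, dose, truth
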