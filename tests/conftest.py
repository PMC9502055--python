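"""Shared fixtures: noise-free and default-noise simulated limb trials."""

import numpy as np
import pytest

from fetlock import GaitParams, RunConfig, simulate_limb

NOISE_FREE = dict(gyro_noise_sd_dps=0.0, marker_noise_sd_m=0.0,
                  soft_tissue_amp_m=0.0, orientation_noise_sd_deg=0.0)


def noise_free_params(gait: str, rom_deg: float, **kw) -> GaitParams:
    merged = dict(NOISE_FREE, gait=gait, rom_deg=rom_deg, n_strides=5, seed=1)
    merged.update(kw)
    return GaitParams(**merged)


@pytest.fixture(scope="session")
def clean_trot_recording():
    """Zero-noise trot limb with the study-default front-limb ROM."""
    return simulate_limb(noise_free_params("trot", 83.0), "LF")


@pytest.fixture(scope="session")
def clean_walk_recording():
    return simulate_limb(noise_free_params("walk", 58.0), "LF")


@pytest.fixture(scope="session")
def noisy_trot_recording():
    """Default-noise trot limb (the study conditions)."""
    return simulate_limb(GaitParams(gait="trot", rom_deg=83.0, n_strides=5, seed=3), "LF")


@pytest.fixture()
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def session_rng():
    return np.random.default_rng(20220825)
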