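"""Shared fixtures: phantom configurations and pre-generated sequences.

Heavy artifacts (volume sequences, tracked sets) are session-scoped so the
suite generates each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from cine4d import flow as fl
from cine4d import phantom as ph


def roi_box_for(config: ph.PhantomConfig, margin_mm: float = 16.0) -> np.ndarray:
    c = np.asarray(config.tumor_center_mm)
    return np.stack([c - margin_mm, c + margin_mm], axis=1)


@pytest.fixture(scope="session")
def quiet_config() -> ph.PhantomConfig:
    """Default study phantom without noise (16 mm, 5 s, 64^3 at 2 mm)."""
    return ph.PhantomConfig(ct_noise_sd=0.0, mr_noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_config() -> ph.PhantomConfig:
    """Default study phantom with its nominal noise levels."""
    return ph.PhantomConfig()


@pytest.fixture(scope="session")
def small_config() -> ph.PhantomConfig:
    """Downscaled phantom for fast pipeline-level tests (48^3, 10 mm motion)."""
    return ph.PhantomConfig(
        grid_shape=(48, 48, 48), spacing_mm=(2.0, 2.0, 2.0),
        period_s=4.0, amplitude_mm=10.0,
        tumor_center_mm=(47.0, 47.0, 52.0), tumor_radius_mm=6.0,
        diaphragm_z0_mm=30.0, ct_noise_sd=0.0, mr_noise_sd=0.0)


@pytest.fixture(scope="session")
def cycle_ct(quiet_config):
    """One full noiseless cycle at cine cadence: (frames, truth)."""
    return ph.generate_4d(quiet_config, 21, 0.25, modality="ct")


@pytest.fixture(scope="session")
def tracked64(quiet_config, cycle_ct):
    frames, _ = cycle_ct
    return fl.select_tracked_voxels(frames[0], roi_box_for(quiet_config), 64)
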