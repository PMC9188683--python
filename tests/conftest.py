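"""Shared fixtures: small simulated cines reused across the suite.

Session scope keeps the expensive simulations and map extractions to a
single run each.
"""

from __future__ import annotations

import numpy as np
import pytest

import ceusrad as cr


SMALL = dict(n_frames=60, height=96, width=96, lesion_radius=14)


@pytest.fixture(scope="session")
def clean_cine():
    """Noise-free, motionless lesion cine with ground truth."""
    cfg = cr.SimConfig(**SMALL, speckle_on=False, seed=1)
    return cr.generate_cine(cfg)


@pytest.fixture(scope="session")
def speckled_cine():
    """Speckled but motionless cine."""
    cfg = cr.SimConfig(**SMALL, seed=2)
    return cr.generate_cine(cfg)


@pytest.fixture(scope="session")
def motion_cine():
    """Cine with rigid shifts and out-of-plane dropout frames."""
    cfg = cr.SimConfig(**SMALL, shift_sd_px=1.0, large_motion_prob=0.12, seed=0)
    cine, truth, ann = cr.generate_cine(cfg)
    assert len(truth.large_motion_frames) >= 3
    return cine, truth, ann


@pytest.fixture(scope="session")
def small_config():
    """Pipeline configuration scaled to the 96 px test grids."""
    return cr.PipelineConfig(min_roi_side=48, max_roi_side=96)


@pytest.fixture(scope="session")
def clean_maps(clean_cine, small_config):
    """Full 137-map stack for the clean cine."""
    cine, truth, ann = clean_cine
    maps, roi, fid = cr.lesion_map_stack(cine, ann, small_config)
    return maps, roi, fid, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
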