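import logging

import numpy as np
import pytest

import pleurastrain as ps
from pleurastrain.simulate import ScattererField, make_scatterer_field, render_rf_frame

logging.getLogger("pleurastrain").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def geometry():
    return ps.AcquisitionGeometry()


@pytest.fixture(scope="session")
def small_zero_loop(geometry):
    """Zero-motion cineloop, small enough for per-test estimation."""
    return ps.simulate_cineloop(geometry, ps.MotionProfile(), n_frames=20,
                                seed=2, shape=(180, 72), pleura_row=40)


@pytest.fixture(scope="session")
def strained_frame_pair(geometry):
    """Two rendered frames whose scatterers differ by exactly 0.5% uniform
    lateral strain about the frame center (the ground-truth warp)."""
    e = 0.005
    fld = make_scatterer_field((256, 128), 0.03, 80, seed=5)
    xc = (128 - 1) / 2.0
    f0 = render_rf_frame(fld, geometry)
    warped = ScattererField(fld.shape, fld.axial_px,
                            xc + (fld.lateral_px - xc) * (1 + e),
                            fld.amplitude, 80)
    f1 = render_rf_frame(warped, geometry)
    return f0, f1, e


@pytest.fixture(scope="session")
def shifted_frame_pair(geometry):
    """Two rendered frames differing by a rigid 0.3 px lateral shift."""
    fld = make_scatterer_field((256, 128), 0.03, 80, seed=8)
    f0 = render_rf_frame(fld, geometry)
    warped = ScattererField(fld.shape, fld.axial_px, fld.lateral_px + 0.3,
                            fld.amplitude, 80)
    f1 = render_rf_frame(warped, geometry)
    return f0, f1, 0.3


def random_motion_field(seed, n_pairs=12, n_windows=7, invalid_fraction=0.1):
    """Random InstantaneousMotionField for parameter-pipeline tests."""
    rng = np.random.default_rng(seed)
    shape = (n_pairs, n_windows)
    valid = rng.random(shape) > invalid_fraction
    return ps.InstantaneousMotionField(
        lateral_shift_mm=rng.normal(0, 0.05, shape),
        axial_shift_mm=rng.normal(0, 0.02, shape),
        lateral_strain_pct=rng.normal(0, 0.3, shape),
        axial_strain_pct=rng.normal(0, 0.2, shape),
        lateral_shear_pct=rng.normal(0, 0.3, shape),
        axial_shear_pct=rng.normal(0, 0.2, shape),
        valid=valid,
        correlation=rng.uniform(0.7, 1.0, shape),
        frame_rate_hz=30.0,
    )
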