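from dataclasses import replace

import numpy as np
import pytest

import petfsv as p


@pytest.fixture(scope="session")
def acetate_schedule() -> p.FrameSchedule:
    return p.FrameSchedule.from_preset("acetate_27min")


@pytest.fixture(scope="session")
def worked_tac() -> p.TimeActivityCurve:
    """Hand-checkable 6-frame TAC: mid-times 5..30 s, 5 s frames."""
    schedule = p.FrameSchedule(np.arange(2.5, 32.5, 5.0), np.full(6, 5.0))
    return p.TimeActivityCurve.from_schedule(
        schedule, np.array([0.0, 100.0, 60.0, 40.0, 34.0, 30.0])
    )


@pytest.fixture(scope="session")
def small_phantom_config() -> p.PhantomConfig:
    """Downscaled geometry so pipeline tests run in a couple of seconds."""
    return p.PhantomConfig(
        grid_shape=(32, 32, 16),
        arterial_center_xy=(9, 16),
        venous_center_xy=(23, 16),
        blood_radius_vox=4.0,
        myo_inner_radius_vox=4.0,
        myo_outer_radius_vox=6.0,
        z_range=(4, 12),
        body_semiaxes_frac=(0.45, 0.45),
    )


@pytest.fixture(scope="session")
def small_noiseless_phantom(small_phantom_config):
    config = replace(small_phantom_config, recirculation_fraction=0.0)
    series, truth = p.simulate_dynamic_series(config)
    return series, truth, config


@pytest.fixture(scope="session")
def default_noiseless_phantom():
    """Full-size blur-free, noise-free, recirculation-free phantom."""
    config = p.PhantomConfig(recirculation_fraction=0.0)
    series, truth = p.simulate_dynamic_series(config)
    return series, truth, config
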