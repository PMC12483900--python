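import numpy as np
import pytest

import saddlefit as sf


@pytest.fixture(scope="session")
def profile():
    """One plausible rider: GTH 880 mm, effective segments per the sampler
    default ratios."""
    return sf.AnthropometricProfile(
        greater_trochanter_height=880.0, thigh_length=560.0,
        shank_length=530.0, ankle_pedal_offset=80.0, subject_id=1)


@pytest.fixture(scope="session")
def rig():
    return sf.RigGeometry(crank_length=170.0, saddle_height=880.0,
                          seat_tube_angle=73.0)


@pytest.fixture(scope="session")
def noiseless_config():
    return sf.SimulationConfig(
        cadence_jitter_sd=0.0, sagittal_noise_sd=0.0, sagittal_cycle_sd=0.0,
        offplane_cycle_sd=0.0, offplane_sd_base=0.0, offplane_sd_slope=0.0,
        rank_noise_sd=0.0, n_cycles=5, seed=0)


def recording_at(profile, fraction, level, config):
    lvl = sf.SaddleLevel(level, fraction)
    r = sf.RigGeometry(saddle_height=fraction * profile.greater_trochanter_height)
    return sf.simulate_recording(profile, r, lvl, config)


@pytest.fixture(scope="session")
def noiseless_recording(profile, noiseless_config):
    return recording_at(profile, 1.0, 2, noiseless_config)


@pytest.fixture(scope="session")
def small_cohort_table():
    """Feature table from a 6-subject, 10-cycle cohort (fast fixture for
    model-level tests)."""
    cfg = sf.SimulationConfig(n_cycles=10, seed=0)
    cycles = []
    for rec in sf.generate_cohort(6, cfg):
        cs, _ = sf.segment_recording(rec)
        cycles.extend(cs)
    return sf.build_feature_table(cycles)


@pytest.fixture(scope="session")
def default_cohort_results():
    """The canonical 16-subject study-scale run (seed 0): full pipeline fit.

    Session-scoped because it underpins several cohort-level checks and
    takes tens of seconds.
    """
    cfg = sf.SimulationConfig(n_cycles=30, seed=0)
    cycles = []
    for rec in sf.generate_cohort(16, cfg):
        cs, _ = sf.segment_recording(rec)
        cycles.extend(cs)
    table = sf.build_feature_table(cycles)
    return sf.SaddleHeightModel(table).fit(seed=0)
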