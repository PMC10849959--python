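"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from gliasleep import synth


@pytest.fixture(scope="session")
def short_sleep_session():
    """A 10-min EEG/EMG session with the default state separations."""
    cfg = synth.SleepSynthConfig(duration_s=600.0, seed=7)
    rec, truth = synth.gen_sleep_session(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def calcium_benchmark():
    """The standard detection benchmark: 40-min, 10-ROI sets, seeds 0-4."""
    sets = []
    for seed in range(5):
        cfg = synth.CalciumSynthConfig(seed=seed)
        traces, truth = synth.gen_calcium(cfg)
        sets.append((cfg, traces, truth))
    return sets


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo_config():
    """A small end-to-end pipeline configuration exercising every stage."""
    return {
        "seed": 5,
        "synth": {
            "sleep": {"duration_s": 600.0},
            "calcium": {"duration_s": 1200.0, "n_rois": 5},
            "sensor": {
                "duration_s": 6600.0,
                "treatment_time_s": 2400.0,
                "effect_size_z": -2.0,
                "state_coupling": {"W": 1.0, "N": 0.0},
            },
            "volume": {
                "shape_voxels": [16, 32, 32],
                "n_spheres": 5,
                "n_boutons": 100,
            },
        },
        "sleep": {"bin_s": 300.0},
        "calcium": {},
        "align": {},
        "sensor": {},
        "distance": {},
        "stats": {},
    }
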