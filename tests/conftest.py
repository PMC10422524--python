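import numpy as np
import pytest

import bioradar as br
from bioradar.ranging import decompose_ranges, highpass_filter


@pytest.fixture(scope="session")
def radar():
    return br.RadarConfig()


def make_breathing_scene(
    f_resp=0.3,
    x_max=0.005,
    phase0=0.0,
    range_bin=2,
    coupling=1.0,
    amplitude=1.0,
    noise_sigma=0.02,
    drift=0.05,
    disturbance=None,
):
    """One clean with-person scene with a single breathing path."""
    return br.SceneConfig(
        label=br.WITH_PERSON,
        motion=br.ChestMotionParams(x_max=x_max, f_resp=f_resp, phase0=phase0),
        paths=(br.MultipathComponent(range_bin, amplitude, coupling),),
        clutter_amplitudes=(0.0, 0.2, 0.2, 0.2, 0.2, 0.2),
        drift=drift,
        noise_sigma=noise_sigma,
        disturbance=disturbance,
    )


def breathing_subsignal(f_resp=0.3, seed=0, **kwargs):
    """Filtered range-2 sub-signal of a clean breathing scene."""
    scene = make_breathing_scene(f_resp=f_resp, **kwargs)
    m = br.simulate_measurement(scene, seed=seed)
    m.metadata["measurement_id"] = "fix"
    return highpass_filter(decompose_ranges(m, 5)[1])


@pytest.fixture(scope="session")
def clean_breathing_sub():
    return breathing_subsignal()


@pytest.fixture(scope="session")
def synthetic_dataset():
    """200 + 200 scene dataset with its feature table (shared, expensive)."""
    measurements, manifest = br.generate_dataset(200, 200, seed=0)
    table = br.feature_table(measurements)
    return measurements, manifest, table


@pytest.fixture(scope="session")
def feature_table_small():
    """20 + 20 scene feature table for fast model-layer tests."""
    measurements, _ = br.generate_dataset(20, 20, seed=1)
    return br.feature_table(measurements)
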