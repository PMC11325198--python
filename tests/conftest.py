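import numpy as np
import pytest

from emsims import (
    AcquisitionParams,
    SceneSpec,
    build_scene,
    simulate_acquisition,
)

SMALL_COUNTS = {
    "myelin": 1,
    "axon": 2,
    "neurite": 3,
    "mitochondrion": 3,
    "presynapse": 4,
    "postsynapse": 4,
    "active_zone": 4,
    "PSD": 4,
}


@pytest.fixture(scope="session")
def small_scene():
    """A compact 256 px scene used by fast structural tests."""
    spec = SceneSpec(
        field_size_um=7.5,
        pixels_per_side=256,
        structure_counts=dict(SMALL_COUNTS),
        seed=42,
    )
    truth = build_scene(spec)
    pair = simulate_acquisition(truth, AcquisitionParams(seed=43))
    return truth, pair


@pytest.fixture(scope="session")
def default_scene():
    """The default acquisition geometry (512 px, 800 counts/px)."""
    spec = SceneSpec(seed=7)
    truth = build_scene(spec)
    acq = AcquisitionParams(seed=8)
    pair = simulate_acquisition(truth, acq)
    return truth, acq, pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
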