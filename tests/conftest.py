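import numpy as np
import pytest

from motionval import TriaxialRecord, WalkScenario, generate_walk, random_rotation_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_accel_record():
    """10 s of quiet 1 g accelerometry at 50 Hz."""
    fs = 50.0
    t = np.arange(0, 10, 1 / fs)
    return TriaxialRecord(
        t, np.zeros_like(t), np.zeros_like(t), np.ones_like(t), "accelerometer", fs
    )


@pytest.fixture
def walk_record():
    """A 20 s walk flanked by rest, with a random fixed device orientation."""
    rot = random_rotation_matrix(np.random.default_rng(7))
    return generate_walk(
        WalkScenario(
            schedule=(("rest", 10.0), ("walk", 20.0), ("rest", 10.0)),
            orientation=rot,
            seed=7,
        )
    )
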