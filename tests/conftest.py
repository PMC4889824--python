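import numpy as np
import pytest

from gesturekit import GeneratorConfig, generate_recording, generate_segments


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down generation protocol: 6 gestures x 4 reps, short rests."""
    return GeneratorConfig(reps_per_gesture=4, rest_seconds=1.0, rng_seed=11)


@pytest.fixture(scope="session")
def small_recording(small_cfg):
    return generate_recording(small_cfg)


@pytest.fixture(scope="session")
def small_segments(small_cfg):
    return generate_segments(small_cfg)


@pytest.fixture(scope="session")
def blobs6():
    """Six well-separated 2-D Gaussian clusters with labels, 20 points each."""
    rng = np.random.default_rng(3)
    centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8], [16, 0], [0, 16]], dtype=float)
    labels = ["HC", "HO", "WF", "WE", "IF", "T"]
    X = np.vstack([c + rng.normal(0, 0.5, size=(20, 2)) for c in centers])
    y = np.repeat(labels, 20)
    return X, y
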