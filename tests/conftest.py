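import numpy as np
import pytest

from neomotion.pose_io import N_LANDMARKS, LandmarkSequence

EPOCH = 1_700_000_000_000


def make_seq(coords, gap_ms=100, subject_id="test", landmark_indices=None):
    """Sequence with regular timestamps from an (n, k, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    ts = EPOCH + gap_ms * np.arange(n, dtype=np.int64)
    if landmark_indices is None:
        landmark_indices = np.arange(coords.shape[1])
    return LandmarkSequence(
        subject_id=subject_id,
        timestamps_ms=ts,
        coords=coords,
        landmark_indices=np.asarray(landmark_indices),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_seq(rng):
    """20-frame full-body sequence of small random motion around mid-image."""
    coords = 0.5 + 0.02 * rng.standard_normal((20, N_LANDMARKS, 3))
    return make_seq(coords)


@pytest.fixture
def constant_seq():
    coords = np.tile(np.linspace(0.2, 0.8, N_LANDMARKS)[None, :, None], (10, 1, 3))
    return make_seq(coords)
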