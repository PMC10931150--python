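import numpy as np
import pytest

from nucoloc import Roi, make_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_roi():
    return Roi(0.0, 0.0, 1000.0, 1000.0)


@pytest.fixture
def small_table(square_roi):
    """Five localizations on a 1 um square ROI."""
    return make_table(
        [100.0, 250.0, 400.0, 700.0, 900.0],
        [150.0, 300.0, 500.0, 650.0, 800.0],
        frame=[1, 1, 2, 3, 3],
        uncertainty_nm=15.0,
        roi_bounds=square_roi,
        n_frames=10,
        channel_label="A",
    )


def brute_force_nnd(source_xy: np.ndarray, target_xy: np.ndarray) -> np.ndarray:
    """Exhaustive all-pairs nearest-neighbor distances (independent oracle)."""
    diff = source_xy[:, None, :] - target_xy[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)
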