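import numpy as np
import pandas as pd
import pytest

from spatmsi.core import FeatureTable, PIXEL_COLUMNS


def grid_coords(nrows: int, ncols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def make_feature_table(matrix: np.ndarray, coords: np.ndarray, centers=None,
                       model_id="M1", slice_id="S1", treatment="none") -> FeatureTable:
    n = matrix.shape[0]
    if centers is None:
        centers = 300.0 + np.arange(matrix.shape[1])
    pixels = pd.DataFrame(
        {
            "x": coords[:, 1],
            "y": coords[:, 0],
            "model_id": np.resize(np.atleast_1d(model_id), n),
            "slice_id": np.resize(np.atleast_1d(slice_id), n),
            "treatment": np.resize(np.atleast_1d(treatment), n),
        }
    )[PIXEL_COLUMNS]
    return FeatureTable(matrix=np.asarray(matrix, dtype=float),
                        centers=np.asarray(centers, dtype=float), pixels=pixels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def grid6():
    return grid_coords(6, 6)
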