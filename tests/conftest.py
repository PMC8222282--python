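import numpy as np
import pytest

from mvtip import (
    SyntheticCellParams,
    generate_cell_image,
    segment_cell,
)


@pytest.fixture(scope="session")
def default_params():
    return SyntheticCellParams(seed=1)


@pytest.fixture(scope="session")
def default_cell(default_params):
    """One default synthetic cell with ground truth, shared across tests."""
    return generate_cell_image(default_params)


@pytest.fixture(scope="session")
def segmented_cell(default_cell):
    """Segmentation of the shared default cell."""
    image, gt = default_cell
    return image, gt, segment_cell(image)


def match_tips(detected_nm, truth_nm, radius_nm=150.0):
    """(precision, recall) of detected tips vs ground truth at a match radius."""
    from scipy.spatial import cKDTree

    detected = np.asarray(detected_nm, dtype=float)
    truth = np.asarray(truth_nm, dtype=float)
    if len(detected) == 0:
        return 0.0, 0.0
    d_det = cKDTree(truth).query(detected)[0]
    d_tru = cKDTree(detected).query(truth)[0]
    return float((d_det < radius_nm).mean()), float((d_tru < radius_nm).mean())
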