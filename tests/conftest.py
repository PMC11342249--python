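import numpy as np
import pandas as pd
import pytest

from strokeconn import ROIAtlas, default_truth, simulate_cohort


def make_atlas(centroids, volumes=None, hemispheres=None, region_ids=None):
    """Build a small atlas from raw centroid coordinates."""
    centroids = np.asarray(centroids, float)
    n = len(centroids)
    if volumes is None:
        volumes = np.full(n, 1000.0)
    if hemispheres is None:
        hemispheres = ["L" if c[0] < 0 else "R" for c in centroids]
    if region_ids is None:
        region_ids = np.arange(1, n + 1)
    return ROIAtlas(
        pd.DataFrame(
            {
                "region_id": region_ids,
                "name": [f"region_{r}" for r in region_ids],
                "hemisphere": hemispheres,
                "centroid_x": centroids[:, 0],
                "centroid_y": centroids[:, 1],
                "centroid_z": centroids[:, 2],
                "volume_mm3": volumes,
            }
        )
    )


@pytest.fixture
def square_atlas():
    """Four regions at the corners of a square of side 10 in the x-y plane."""
    return make_atlas(
        [[-10, 0, 0], [-10, 10, 0], [-20, 0, 0], [-20, 10, 0]],
        hemispheres=["L"] * 4,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One fixed planted-effect cohort, shared by read-only tests."""
    return simulate_cohort(
        default_truth(11, n_subjects=60, n_regions_per_hemisphere=10)
    )
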