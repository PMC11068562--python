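import numpy as np
import pytest

from orgcompete import (SyntheticParams, default_marker_models,
                        generate_nucleus_field, mixed_organoid_params,
                        render_stack)


@pytest.fixture(scope="session")
def small_params():
    """Small noiseless organoid used by several pipeline tests."""
    return SyntheticParams(
        image_shape=(30, 192, 192),
        voxel_size=(2.5, 1.0, 1.0),
        n_nuclei_initial=50,
        min_separation_um=14.0,
        nucleus_radius_um=4.0,
        nucleus_radius_sd_um=0.3,
        geometry="solid",
        seed=11,
        marker_models=default_marker_models(("DAPI", "mTmG", "Dendra2")),
    )


@pytest.fixture(scope="session")
def mixed_truth_and_stack():
    """Noiseless mixed organoid: ground truth plus rendered stack."""
    params = mixed_organoid_params(
        image_shape=(30, 192, 192),
        voxel_size=(2.5, 1.0, 1.0),
        n_nuclei_initial=60,
        min_separation_um=12.0,
        nucleus_radius_um=4.0,
        nucleus_radius_sd_um=0.3,
        compaction_factor=1.0,
        seed=7,
        marker_models=default_marker_models(("DAPI", "mTmG", "Dendra2")),
    )
    truth = generate_nucleus_field(params)
    stack = render_stack(truth, params)
    return params, truth, stack


def pairwise_min_distance(points: np.ndarray) -> float:
    """Brute-force all-pairs minimum Euclidean distance."""
    n = points.shape[0]
    best = np.inf
    for i in range(n - 1):
        d = np.sqrt(np.sum((points[i + 1:] - points[i]) ** 2, axis=1))
        best = min(best, d.min())
    return float(best)
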