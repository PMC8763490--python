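import numpy as np
import pytest

from pulmostage.acm import LevelSetParams, segment_volume
from pulmostage.phantom import PhantomSpec, generate_phantom, generate_dataset, dataset_to_arrays


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.astype(bool), b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.sum(a & b) / denom if denom else 1.0


@pytest.fixture(scope="session")
def disc_phantom_2d():
    """Zero-noise 12 mm disc on a 64x64 1 mm grid."""
    spec = PhantomSpec(nodule_diameter_mm=12, contrast=40, noise_sigma=0,
                       slab_shape=(64, 64), voxel_spacing_mm=(1.0, 1.0))
    return generate_phantom(spec, seed=1)


@pytest.fixture(scope="session")
def benchmark_profile():
    """Segmentation parameters used for the large synthetic benchmark."""
    return LevelSetParams(dt=6.0, epsilon=1.0, max_iter=150)


@pytest.fixture(scope="session")
def benchmark_data(benchmark_profile):
    """The 9-class size-binned benchmark: 100 slabs per class, segmented.

    Built once per session; shared by the cross-validation and ablation
    checks.  Returns (dataset, masks, X_masked, y).
    """
    ds = generate_dataset(100, seed=42)
    masks = [segment_volume(v, benchmark_profile).mask for v in ds.volumes]
    X, y = dataset_to_arrays(ds, masks=masks)
    return ds, masks, X, y
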