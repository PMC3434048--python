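import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mrvolumetry import ImageVolume, SegMask


@pytest.fixture
def two_class_image():
    """5-slice image: a bright 6x6 block (intensity 100) centred in each
    slice on a dark background (intensity 20)."""
    data = np.full((5, 12, 12), 20.0)
    truth = np.zeros((5, 12, 12), dtype=bool)
    truth[:, 3:9, 3:9] = True
    data[truth] = 100.0
    return ImageVolume(data, (700.0, 150.0, 200.0)), truth


@pytest.fixture
def annulus_mask():
    """Single-slice ring of tumour voxels with an enclosed hole."""
    labels = np.zeros((1, 16, 16), dtype=bool)
    rr, cc = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
    r = np.hypot(rr - 8, cc - 8)
    labels[0] = (r >= 3) & (r <= 6)
    return SegMask(labels, (160.0, 160.0, 160.0), [{"op": "synthetic"}])
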