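import numpy as np
import pytest

from callidx.segmentation import default_template, extract_midsagittal_slices
from callidx.synthetic import CCShapeSpec, generate_cc_mask


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def fine_phantom():
    """Jitter-free half-annulus R=10, t=2 at 0.25 mm voxels (analytic CCI 0.300)."""
    spec = CCShapeSpec(
        outer_radius=10.0,
        thickness=2.0,
        voxel_size=(0.25, 0.25, 0.25),
        n_slices=9,
        margin_mm=6.0,
    )
    return spec, *generate_cc_mask(spec)


@pytest.fixture(scope="session")
def fine_stack(fine_phantom):
    _, vol, _ = fine_phantom
    return extract_midsagittal_slices(vol, n_slices=7)


def half_disk(radius_mm: float = 8.0, voxel: float = 0.25) -> np.ndarray:
    """Filled semicircle (flat side down) — violates arch topology."""
    n = int(2 * radius_mm / voxel) + 8
    y = (np.arange(n) - n / 2 + 0.5) * voxel
    z = (np.arange(n) - 4 + 0.5) * voxel
    Y, Z = np.meshgrid(y, z, indexing="ij")
    return (np.hypot(Y, Z) <= radius_mm) & (Z >= 0)
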