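import numpy as np
import pytest

from fibremech.core import BinaryMask, ImageStack


def make_ball_mask(
    radius_vox: float = 10.0,
    shape=(64, 64, 64),
    center=None,
    voxel_size=(1.0, 1.0, 1.0),
    label="cell",
) -> BinaryMask:
    """Digital ball: voxel centers within radius_vox voxels of the center."""
    if center is None:
        center = tuple(n // 2 for n in shape)
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = (
        ((zz - center[0]) * voxel_size[0]) ** 2
        + ((yy - center[1]) * voxel_size[1]) ** 2
        + ((xx - center[2]) * voxel_size[2]) ** 2
    )
    return BinaryMask(
        r2 <= (radius_vox * min(voxel_size)) ** 2, voxel_size_um=voxel_size, label=label
    )


def make_capsule(mask: BinaryMask, start, direction, length, radius) -> BinaryMask:
    """Union the mask with a capsule (physical units) and return it."""
    vs = np.asarray(mask.voxel_size_um)
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in mask.shape], indexing="ij")
    pts = np.stack([zz * vs[0], yy * vs[1], xx * vs[2]], axis=-1)
    a = np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    b = a + length * d
    ab = b - a
    t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
    closest = a + t[..., None] * ab
    dist2 = ((pts - closest) ** 2).sum(-1)
    return mask.with_data(mask.data | (dist2 <= radius**2))


@pytest.fixture
def ball64():
    """Ball of radius 10 voxels centered at (32, 32, 32) in 64³, 1 µm voxels."""
    return make_ball_mask(10.0, (64, 64, 64), (32, 32, 32))


@pytest.fixture
def fused_balls():
    """Two balls fused at a neck plus a nuclei stack with one seed per ball."""
    shape = (48, 64, 48)
    c1, c2 = (24, 22, 24), (24, 42, 24)
    m = make_ball_mask(11.0, shape, c1)
    m = m.with_data(m.data | make_ball_mask(11.0, shape, c2).data)
    nuclei = np.zeros(shape)
    nz, ny, nx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    for c in (c1, c2):
        nuclei[((nz - c[0]) ** 2 + (ny - c[1]) ** 2 + (nx - c[2]) ** 2) <= 16] = 100.0
    nuclei += np.random.default_rng(0).normal(0, 0.5, shape)
    return m, ImageStack(nuclei, (1.0, 1.0, 1.0), "nuclei"), c1, c2


@pytest.fixture(scope="session")
def textured_stack():
    """A fiber-like random texture, 64³, for drift/registration fixtures."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(7)
    data = gaussian_filter(rng.random((64, 64, 64)), 1.2)
    return ImageStack(data, (1.0, 1.0, 1.0), "fiber")
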