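"""Dense 3D displacement recovery and per-cell decay profiling.

The matrix displacement field between the stressed (cell contracting) and
relaxed (after cytochalasin D) states is recovered by free-form-deformation
image registration: a multi-resolution cubic B-spline control-point lattice
is optimised to maximise the normalised correlation coefficient (NCC)
between the relaxed image and the warped stressed image.  The optimiser is
stochastic gradient descent with per-parameter adaptive step estimation
(Adam): every iteration draws a fresh seeded random sample of voxel
positions, evaluates the NCC and its analytic gradient with respect to the
control points there, and updates the lattice.  The per-iteration cost is
set by the sample count, not the volume, so 128³ stacks register in
seconds.  The control-point field is finally densified to a per-voxel
displacement in physical micrometres.

Sign convention: the recovered vectors map relaxed positions to stressed
positions, so a cell pulling the matrix inward yields vectors pointing
toward the cell.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import (
    BinaryMask,
    DecayProfile,
    DisplacementField,
    ImageStack,
    require_same_geometry,
)
from .ffd import BSplineLattice

__all__ = [
    "RegistrationError",
    "register_ffd",
    "max_displacement",
    "decay_profile",
]


class RegistrationError(RuntimeError):
    """Raised when FFD registration cannot proceed or diverges."""


def _ncc_and_grad(f: np.ndarray, m: np.ndarray) -> tuple[float, np.ndarray]:
    """NCC of two sample vectors and its gradient w.r.t. the second.

    Both inputs are mean-centred internally; the returned gradient already
    accounts for the centring (it is orthogonal to the constant vector).
    """
    fc = f - f.mean()
    mc = m - m.mean()
    fn = float(np.linalg.norm(fc))
    mn = float(np.linalg.norm(mc))
    if fn == 0.0 or mn == 0.0:
        raise RegistrationError(
            "no overlapping intensity content: correlation undefined"
        )
    ncc = float(fc @ mc) / (fn * mn)
    grad = (fc - (float(fc @ mc) / mn**2) * mc) / (fn * mn)
    return ncc, grad


def register_ffd(
    stressed_fiber: ImageStack,
    relaxed_fiber: ImageStack,
    grid_spacing_vox: int = 8,
    n_levels: int = 2,
    iterations: int = 200,
    seed: int = 0,
    n_samples: int = 20000,
    learning_rate_vox: float = 0.1,
) -> DisplacementField:
    """Recover the relaxed→stressed displacement field by B-spline FFD.

    Parameters
    ----------
    stressed_fiber, relaxed_fiber : ImageStack
        Drift-corrected fiber channels of identical geometry.
    grid_spacing_vox : int
        Control-point spacing at the finest level, in voxels.  Coarser
        levels double the spacing and smooth the images.
    n_levels : int
        Multi-resolution depth (coarse-to-fine lattice refinement).
    iterations : int
        Stochastic-gradient iterations per level.
    seed : int
        Seed of the random voxel sampler: identical inputs and seed give a
        bit-identical field.
    n_samples : int
        Voxel positions drawn per iteration for the NCC estimate.
    learning_rate_vox : float
        Adam base step, in voxels.

    Returns a :class:`DisplacementField` whose ``valid_mask`` excludes a
    border of one control-grid spacing, where the B-spline support is
    truncated.

    Raises :class:`RegistrationError` for content-free images (correlation
    undefined) or if the similarity decreases over the finest level.
    """
    require_same_geometry(stressed_fiber, relaxed_fiber, "fiber stacks")
    fixed = np.asarray(relaxed_fiber.data, dtype=float)
    moving = np.asarray(stressed_fiber.data, dtype=float)
    for name, arr in (("stressed", moving), ("relaxed", fixed)):
        if float(np.std(arr)) == 0.0:
            raise RegistrationError(
                f"{name} fiber image has no intensity content; correlation undefined"
            )

    shape = fixed.shape
    rng = np.random.default_rng(seed)
    # relative epsilon: parameters whose gradient is weak compared with the
    # lattice-wide RMS take proportionally small steps, so texture-poor
    # regions do not random-walk under the stochastic sampling noise
    beta1, beta2, rel_eps = 0.9, 0.999, 0.1

    spacings = [grid_spacing_vox * 2**lvl for lvl in range(n_levels - 1, -1, -1)]
    sigmas = [float(lvl) for lvl in range(n_levels - 1, -1, -1)]

    lattice: BSplineLattice | None = None
    finest_ncc: list[float] = []
    for spacing, sigma in zip(spacings, sigmas):
        f_img = gaussian_filter(fixed, sigma) if sigma > 0 else fixed
        m_img = gaussian_filter(moving, sigma) if sigma > 0 else moving
        m_grad = np.gradient(m_img)  # intensity change per voxel, axes (z, y, x)

        lat = BSplineLattice(shape, spacing)
        if lattice is not None:
            lat.refine_from(lattice)
        m1 = np.zeros_like(lat.coeffs)
        m2 = np.zeros_like(lat.coeffs)

        ncc_trace: list[float] = []
        for it in range(int(iterations)):
            pts = rng.uniform(0.0, 1.0, size=(n_samples, 3)) * (
                np.asarray(shape, dtype=float) - 1.0
            )
            support = lat.support(pts)
            flat_idx, w = support
            u = np.einsum(
                "nk,nkd->nd", w, lat.coeffs.reshape(-1, 3)[flat_idx]
            )
            warped = (pts + u).T
            m_s = map_coordinates(m_img, warped, order=1, mode="nearest")
            f_s = map_coordinates(f_img, pts.T, order=1, mode="nearest")
            ncc, d_m = _ncc_and_grad(f_s, m_s)
            ncc_trace.append(ncc)
            if ncc > 1.0 - 1e-9:
                # numerically perfect correlation (e.g. identical inputs):
                # the residual gradient is floating-point dust, which the
                # scale-invariant step normalisation would amplify
                continue

            g_vec = np.stack(
                [map_coordinates(g, warped, order=1, mode="nearest") for g in m_grad],
                axis=1,
            ) * d_m[:, None]
            grad = lat.scatter_gradient(g_vec, support)

            # Adam-style ascent on the NCC with a linearly decaying base step
            m1 = beta1 * m1 + (1 - beta1) * grad
            m2 = beta2 * m2 + (1 - beta2) * grad**2
            t = it + 1
            m1_hat = m1 / (1 - beta1**t)
            m2_hat = m2 / (1 - beta2**t)
            rms = np.sqrt(m2_hat)
            lr_t = learning_rate_vox * (1.0 - it / iterations)
            lat.coeffs = lat.coeffs + lr_t * m1_hat / (rms + rel_eps * rms.mean() + 1e-30)
        lattice = lat
        finest_ncc = ncc_trace

    # divergence check: the similarity must not end worse than it started
    # over the finest level; means damp the sampling noise
    if len(finest_ncc) >= 10:
        head = float(np.mean(finest_ncc[:5]))
        tail = float(np.mean(finest_ncc[-5:]))
        if tail < head - 0.02:
            raise RegistrationError(
                f"similarity decreased over the finest level "
                f"(NCC {head:.5f} -> {tail:.5f}); registration diverged"
            )

    dense_vox = lattice.densify()  # (z, y, x) components, voxels
    vs = stressed_fiber.voxel_size_um
    vectors = np.stack(
        [dense_vox[..., 2] * vs[2], dense_vox[..., 1] * vs[1], dense_vox[..., 0] * vs[0]],
        axis=-1,
    )  # (x, y, z) components, µm

    valid = np.zeros(shape, dtype=bool)
    b = int(grid_spacing_vox)
    bz = min(b, shape[0] // 2)
    by = min(b, shape[1] // 2)
    bx = min(b, shape[2] // 2)
    valid[bz:-bz or None, by:-by or None, bx:-bx or None] = True

    return DisplacementField(
        vectors, voxel_size_um=stressed_fiber.voxel_size_um, valid_mask=valid
    )


def max_displacement(field: DisplacementField, percentile: float = 100.0) -> float:
    """Percentile of |u| over the trusted voxels (µm); default the true max.

    ``percentile=99`` is the robust variant used when single-voxel outliers
    are a concern.
    """
    if not field.valid_mask.any():
        raise ValueError("empty valid_mask")
    mags = field.magnitude()[field.valid_mask]
    return float(np.percentile(mags, percentile))


def decay_profile(
    field: DisplacementField,
    cell_mask: BinaryMask,
    bin_width_um: float = 5.0,
    max_dist_um: float = 150.0,
) -> DecayProfile:
    """Mean |u| vs distance from the cell surface, in 5 µm half-open bins.

    Every trusted voxel outside the cell is assigned to the bin
    ``[k·w, (k+1)·w)`` of its Euclidean distance to the cell surface
    (anisotropy-aware distance transform of the cell-mask complement,
    voxel-center convention).  Bins reach up to ``max_dist_um`` (150 µm by
    default, about as far as displacements remain measurable within a
    typical field of view); per-bin mean, population SD, and voxel count
    are reported.
    """
    require_same_geometry(field, cell_mask, "field and cell mask")
    if not cell_mask.data.any():
        raise ValueError("empty cell mask")
    if bin_width_um <= 0 or max_dist_um <= 0:
        raise ValueError("bin width and max distance must be positive")

    dist = ndi.distance_transform_edt(~cell_mask.data, sampling=cell_mask.voxel_size_um)
    select = field.valid_mask & ~cell_mask.data & (dist < max_dist_um)
    edges = np.arange(0.0, max_dist_um + 1e-9, bin_width_um)
    if edges[-1] < max_dist_um - 1e-9:  # trailing partial bin up to the cap
        edges = np.append(edges, max_dist_um)
    nbins = len(edges) - 1

    mags = field.magnitude()[select]
    bin_idx = np.floor(dist[select] / bin_width_um).astype(int)
    bin_idx = np.clip(bin_idx, 0, nbins - 1)

    counts = np.bincount(bin_idx, minlength=nbins)
    sums = np.bincount(bin_idx, weights=mags, minlength=nbins)
    sq_sums = np.bincount(bin_idx, weights=mags**2, minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
        var = sq_sums / counts - means**2
    sds = np.sqrt(np.clip(var, 0.0, None))
    means[counts == 0] = np.nan
    sds[counts == 0] = np.nan

    return DecayProfile(
        bin_edges_um=edges, mean_mag_um=means, sd_um=sds, n_voxels=counts
    )
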