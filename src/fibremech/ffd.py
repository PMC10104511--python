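"""Cubic B-spline free-form deformation (FFD) lattice.

A displacement field is parameterised by a regular lattice of control
points with spacing ``h`` voxels per axis; the field at voxel position x is
the tensor-product cubic B-spline interpolation of the 4×4×4 surrounding
control points:

    u(x) = Σ_{l,m,n=0..3} B_l(s_z) B_m(s_y) B_n(s_x) · c[i+l, j+m, k+n]

with (i, j, k) = floor(x/h) − 1 and s = x/h − floor(x/h).  Control values
``c`` carry one displacement vector per lattice node, in voxel units per
array axis (z, y, x).  The lattice extends one node beyond the volume on
each side so every voxel has full support.

The module provides evaluation at scattered sample points (with the weights
needed to back-propagate a metric gradient onto the lattice) and dense
evaluation over the whole volume via separable banded matrices.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BSplineLattice"]


def _bspline3_weights(t: np.ndarray) -> np.ndarray:
    """The four cubic B-spline basis values at fractional offset t ∈ [0, 1).

    Returns an array of shape (4,) + t.shape.
    """
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ]
    )


class BSplineLattice:
    """FFD control lattice over a ``shape``-voxel volume, spacing ``h`` voxels.

    ``coeffs`` has shape ``(ncz, ncy, ncx, 3)``: a (z, y, x)-ordered
    displacement vector in voxels at every control node.  Node index 0 sits
    at lattice position −h (one spacing outside the volume).
    """

    def __init__(self, shape: tuple[int, int, int], spacing_vox: float):
        if spacing_vox <= 0:
            raise ValueError("control spacing must be positive")
        self.shape = tuple(int(n) for n in shape)
        self.h = float(spacing_vox)
        # node i covers lattice coordinate (i - 1)·h; need floor(x/h)+2 max
        self.nc = tuple(int(np.floor((n - 1) / self.h)) + 4 for n in self.shape)
        self.coeffs = np.zeros(self.nc + (3,), dtype=float)

    # -- scattered evaluation -------------------------------------------------

    def support(self, pts_vox: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-point support indices and weights.

        ``pts_vox``: (n, 3) voxel coordinates.  Returns ``(flat_idx, w)``
        where ``flat_idx`` (n, 64) are flattened lattice-node indices and
        ``w`` (n, 64) the tensor-product basis weights (each row sums to 1).
        """
        pts = np.asarray(pts_vox, dtype=float)
        g = pts / self.h
        base = np.floor(g).astype(int)  # node index of B1 = base (offset +1 in storage)
        frac = g - base
        idx_axis = []
        w_axis = []
        for ax in range(3):
            w = _bspline3_weights(frac[:, ax])  # (4, n)
            idx = base[:, ax][None, :] + np.arange(4)[:, None]  # lattice idx − storage offset
            idx_axis.append(idx)  # storage index = lattice idx + 1 − 1 ... see below
            w_axis.append(w)
        # storage node 0 is lattice position −h, i.e. storage = lattice_index + 1;
        # here base is floor(x/h), contributing nodes are base−1 .. base+2 in
        # lattice terms → base .. base+3 in storage terms, handled by idx above.
        ncz, ncy, ncx = self.nc
        iz, iy, ix = idx_axis
        wz, wy, wx = w_axis
        n = pts.shape[0]
        flat = (
            iz[:, None, None, :] * (ncy * ncx)
            + iy[None, :, None, :] * ncx
            + ix[None, None, :, :]
        ).reshape(64, n)
        w = (wz[:, None, None, :] * wy[None, :, None, :] * wx[None, None, :, :]).reshape(64, n)
        return flat.T, w.T

    def evaluate(self, pts_vox: np.ndarray) -> np.ndarray:
        """Displacement vectors (voxels, (z, y, x) order) at sample points."""
        flat_idx, w = self.support(pts_vox)
        c = self.coeffs.reshape(-1, 3)
        return np.einsum("nk,nkd->nd", w, c[flat_idx])

    def scatter_gradient(
        self,
        grad_vec: np.ndarray,
        support: tuple[np.ndarray, np.ndarray],
    ) -> np.ndarray:
        """Adjoint of :meth:`evaluate`: accumulate per-sample vector gradients
        onto the lattice.  ``support`` is the pair returned by
        :meth:`support` for the same points.  Returns an array shaped like
        ``coeffs``."""
        flat_idx, w = support
        size = int(np.prod(self.nc))
        flat = flat_idx.reshape(-1)
        out = np.empty((size, 3))
        for d in range(3):
            contrib = (w * grad_vec[:, d : d + 1]).reshape(-1)
            out[:, d] = np.bincount(flat, weights=contrib, minlength=size)
        return out.reshape(self.coeffs.shape)

    # -- dense evaluation -----------------------------------------------------

    def _axis_matrix(self, ax: int) -> np.ndarray:
        """(N, nc) matrix of basis weights for all voxel centers along axis."""
        n, nc = self.shape[ax], self.nc[ax]
        x = np.arange(n, dtype=float) / self.h
        base = np.floor(x).astype(int)
        w = _bspline3_weights(x - base)  # (4, N)
        mat = np.zeros((n, nc))
        rows = np.arange(n)
        for l in range(4):
            mat[rows, base + l] = w[l]
        return mat

    def densify(self) -> np.ndarray:
        """Dense per-voxel displacement (voxels, (z, y, x) components)."""
        az = self._axis_matrix(0)
        ay = self._axis_matrix(1)
        ax = self._axis_matrix(2)
        out = np.tensordot(az, self.coeffs, axes=(1, 0))  # (Nz, ncy, ncx, 3)
        out = np.tensordot(ay, out, axes=(1, 1)).transpose(1, 0, 2, 3)  # (Nz, Ny, ncx, 3)
        out = np.tensordot(ax, out, axes=(1, 2)).transpose(1, 2, 0, 3)  # (Nz, Ny, Nx, 3)
        return out

    # -- refinement -----------------------------------------------------------

    def refine_from(self, coarse: "BSplineLattice") -> None:
        """Initialise this lattice so it reproduces a coarser lattice's field.

        Each fine control node takes the coarse field evaluated at its
        lattice position (clamped into the volume near the margins) — an
        interpolating approximation adequate for a multi-resolution warm
        start.
        """
        grids = np.meshgrid(
            *[(np.arange(nc) - 1) * self.h for nc in self.nc], indexing="ij"
        )
        pts = np.stack([g.ravel() for g in grids], axis=1)
        for ax in range(3):
            pts[:, ax] = np.clip(pts[:, ax], 0.0, self.shape[ax] - 1.0)
        self.coeffs = coarse.evaluate(pts).reshape(self.coeffs.shape)
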