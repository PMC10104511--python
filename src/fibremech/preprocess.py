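"""Denoising, contrast stretching, and stage-drift correction.

The denoiser is a penalized least-squares (Whittaker) smoother realised in
the DCT domain: for a gridded image the penalized normal equations
``(I + s·Δ'Δ)·ẑ = y`` diagonalise under the type-II discrete cosine
transform, so smoothing is a per-frequency shrinkage ``DCT(y)/(1 + s·Λ²)``
with Λ the Laplacian eigenvalues.  The penalty ``s`` can be chosen
automatically by generalized cross-validation (GCV).

Drift between the relaxed and stressed acquisitions is estimated by phase
correlation on the fiber channel only, and the same shift is applied to
every channel.  Integer-voxel shifts (the default) are recovered exactly
for circular shifts; an optional Fourier-upsampled subvoxel mode refines to
a tenth of a voxel and applies the correction by trilinear interpolation.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
from scipy.fft import dctn, idctn
from scipy.ndimage import shift as nd_shift
from scipy.optimize import minimize_scalar
from skimage.registration import phase_cross_correlation

from .core import ImageStack, require_same_geometry

__all__ = ["denoise_pls", "stretch_contrast", "correct_drift"]


def _laplacian_eigenvalues(shape) -> np.ndarray:
    """Eigenvalues of the 3D discrete Laplacian under DCT-II boundary rules."""
    lam = np.zeros(shape)
    for ax, n in enumerate(shape):
        idx = [None] * len(shape)
        idx[ax] = slice(None)
        lam = lam + (2.0 - 2.0 * np.cos(np.pi * np.arange(n) / n))[tuple(idx)]
    return lam


def denoise_pls(stack: ImageStack, smoothing: float | str = "auto") -> ImageStack:
    """Penalized least-squares denoising of a 3D stack.

    Parameters
    ----------
    stack : ImageStack
    smoothing : positive float, 0, or "auto"
        The roughness penalty ``s``.  ``0`` returns the input unchanged;
        ``"auto"`` selects ``s`` by generalized cross-validation.

    The DC component is untouched, so the mean intensity is preserved
    exactly.
    """
    y = np.asarray(stack.data, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("stack contains non-finite values")

    lam2 = _laplacian_eigenvalues(y.shape) ** 2
    dct_y = dctn(y, norm="ortho")

    if isinstance(smoothing, str):
        if smoothing != "auto":
            raise ValueError(f"smoothing must be a number or 'auto', got {smoothing!r}")
        s = _gcv_penalty(dct_y, lam2)
    else:
        s = float(smoothing)
        if s < 0:
            raise ValueError("smoothing penalty must be >= 0")
        if s == 0:
            return stack.with_data(y.copy())

    gamma = 1.0 / (1.0 + s * lam2)
    smoothed = idctn(dct_y * gamma, norm="ortho")
    return stack.with_data(smoothed)


def _gcv_penalty(dct_y: np.ndarray, lam2: np.ndarray) -> float:
    """Penalty minimising the GCV score, searched over log10 s ∈ [-8, 8]."""
    n = dct_y.size
    dct_y2 = dct_y**2

    def gcv(log_s: float) -> float:
        s = 10.0**log_s
        gamma = 1.0 / (1.0 + s * lam2)
        rss = float(np.sum(dct_y2 * (1.0 - gamma) ** 2))
        tr_h = float(np.sum(gamma))
        return n * rss / (n - tr_h) ** 2

    res = minimize_scalar(gcv, bounds=(-8.0, 8.0), method="bounded")
    return 10.0**res.x


def stretch_contrast(
    stack: ImageStack, p_low: float = 0.1, p_high: float = 99.9
) -> ImageStack:
    """Linearly rescale ``[P(p_low), P(p_high)]`` to [0, 1], clipping outside.

    A constant stack (degenerate percentile window) yields an all-zero
    output with a warning rather than an error.
    """
    if not p_low < p_high:
        raise ValueError(f"need p_low < p_high, got {p_low} >= {p_high}")
    data = np.asarray(stack.data, dtype=float)
    lo, hi = np.percentile(data, [p_low, p_high])
    if hi <= lo:
        warnings.warn(
            "degenerate intensity window (constant stack?); output is all zeros",
            stacklevel=2,
        )
        return stack.with_data(np.zeros_like(data))
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return stack.with_data(out)


def correct_drift(
    moving: Mapping[str, ImageStack],
    reference_fiber: ImageStack,
    fiber_channel: str = "fiber",
    subvoxel: bool = False,
) -> tuple[dict[str, ImageStack], np.ndarray]:
    """Estimate stage drift on the fiber channel; undo it on every channel.

    The shift is found by phase correlation between the moving and reference
    fiber images — exact for integer circular shifts — and the inverse shift
    is applied to all channels of ``moving``.  With ``subvoxel=True`` the
    correlation peak is refined by ×10 Fourier upsampling and the correction
    uses trilinear interpolation instead of a circular roll.

    Returns ``(corrected_channels, shift_vox)`` with the estimated drift in
    voxels, array order (z, y, x): ``moving ≈ reference shifted by shift_vox``.
    """
    if fiber_channel not in moving:
        raise KeyError(f"moving stacks have no {fiber_channel!r} channel")
    mov_fiber = moving[fiber_channel]
    require_same_geometry(mov_fiber, reference_fiber, "fiber channels")
    if not np.any(reference_fiber.data) or not np.any(mov_fiber.data):
        raise ValueError("all-zero fiber channel: no correlation peak")

    # whitened ("phase") normalization is exact for integer circular shifts;
    # for subvoxel refinement on band-limited images the plain cross
    # correlation is less biased
    shift, _, _ = phase_cross_correlation(
        reference_fiber.data.astype(float),
        mov_fiber.data.astype(float),
        upsample_factor=10 if subvoxel else 1,
        normalization=None if subvoxel else "phase",
    )
    # phase_cross_correlation returns the shift mapping moving -> reference;
    # the drift applied to the moving stack is its negation
    drift = -np.asarray(shift, dtype=float)

    corrected: dict[str, ImageStack] = {}
    for name, stk in moving.items():
        if subvoxel:
            data = nd_shift(stk.data.astype(float), shift, order=1, mode="reflect")
        else:
            data = np.roll(stk.data, tuple(int(s) for s in shift), axis=(0, 1, 2))
        corrected[name] = stk.with_data(data)
    return corrected, drift
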