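"""Core containers shared by every analysis stage.

Axis convention
---------------
All voxel arrays are ordered ``(z, y, x)`` (plane, row, column), the natural
order of a confocal z-stack loaded with :mod:`tifffile`.  Vector quantities
(displacements, drift shifts) are stored with components in ``(x, y, z)``
order and in physical micrometres, which is the convention of the exported
files (VTK, CSV).  Conversion between the two orderings is centralised in
:func:`zyx_to_xyz` / :func:`xyz_to_zyx` — nothing else is allowed to reorder
axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ImageStack",
    "BinaryMask",
    "DisplacementField",
    "DecayProfile",
    "zyx_to_xyz",
    "xyz_to_zyx",
]


def zyx_to_xyz(vec: Sequence[float]) -> tuple[float, float, float]:
    """Reorder a per-axis quantity from array order (z, y, x) to (x, y, z)."""
    z, y, x = vec
    return (x, y, z)


def xyz_to_zyx(vec: Sequence[float]) -> tuple[float, float, float]:
    """Reorder a per-axis quantity from (x, y, z) to array order (z, y, x)."""
    x, y, z = vec
    return (z, y, x)


def _validate_voxel_size(voxel_size_um) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in np.broadcast_to(voxel_size_um, (3,)))
    if any(v <= 0 for v in vs):
        raise ValueError(f"voxel sizes must be positive, got {vs}")
    return vs


@dataclass
class ImageStack:
    """A single-channel 3D scalar image with physical voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar voxel values, finite.
    voxel_size_um : 3-tuple of float
        Physical voxel edge length per array axis, ordered (z, y, x), µm.
    channel : str
        Channel tag, e.g. ``"fiber"``, ``"cell"``, ``"nuclei"``.
    time_h : float, optional
        Acquisition time in hours relative to encapsulation.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (0.57, 0.57, 0.57)
    channel: str = ""
    time_h: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D stack, got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("stack contains non-finite values")
        self.voxel_size_um = _validate_voxel_size(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """A copy of this stack carrying new voxel values, same geometry."""
        return replace(self, data=data)


@dataclass
class BinaryMask:
    """A 3D boolean mask sharing an :class:`ImageStack`'s geometry."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (0.57, 0.57, 0.57)
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.data.shape}")
        self.voxel_size_um = _validate_voxel_size(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    @property
    def volume_um3(self) -> float:
        """Physical volume: voxel count × voxel volume."""
        return float(self.data.sum()) * self.voxel_volume_um3

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return replace(self, data=data)


@dataclass
class DisplacementField:
    """A dense per-voxel 3D displacement field in physical micrometres.

    ``vectors`` has shape ``(nz, ny, nx, 3)`` with the component axis ordered
    ``(x, y, z)``; vectors map relaxed positions to stressed positions, so a
    cell pulling the matrix inward yields vectors pointing toward the cell.
    ``valid_mask`` flags the voxels where the registration is trusted.
    """

    vectors: np.ndarray
    voxel_size_um: tuple[float, float, float] = (0.57, 0.57, 0.57)
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"expected vectors of shape (nz, ny, nx, 3), got {self.vectors.shape}"
            )
        if not np.isfinite(self.vectors).all():
            raise ValueError("displacement field contains non-finite values")
        self.voxel_size_um = _validate_voxel_size(self.voxel_size_um)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.vectors.shape[:3], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.vectors.shape[:3]:
                raise ValueError("valid_mask shape does not match vectors")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean magnitude |u| in µm."""
        return np.sqrt((self.vectors ** 2).sum(axis=-1))


@dataclass
class DecayProfile:
    """Mean displacement magnitude binned by distance from the cell surface.

    Bins are half-open ``[edge_i, edge_{i+1})`` with a default step of 5 µm,
    capped at 150 µm.
    """

    bin_edges_um: np.ndarray
    mean_mag_um: np.ndarray
    sd_um: np.ndarray
    n_voxels: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges_um = np.asarray(self.bin_edges_um, dtype=float)
        self.mean_mag_um = np.asarray(self.mean_mag_um, dtype=float)
        self.sd_um = np.asarray(self.sd_um, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        if np.any(np.diff(self.bin_edges_um) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        nbins = len(self.bin_edges_um) - 1
        for arr, name in [
            (self.mean_mag_um, "mean_mag_um"),
            (self.sd_um, "sd_um"),
            (self.n_voxels, "n_voxels"),
        ]:
            if len(arr) != nbins:
                raise ValueError(f"{name} must have {nbins} entries")

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])


def require_same_geometry(a, b, what: str = "inputs") -> None:
    """Raise if two stacks/masks/fields disagree in shape or voxel size."""
    if a.shape != b.shape:
        raise ValueError(f"{what} have different shapes: {a.shape} vs {b.shape}")
    if not np.allclose(a.voxel_size_um, b.voxel_size_um):
        raise ValueError(
            f"{what} have different voxel sizes: "
            f"{a.voxel_size_um} vs {b.voxel_size_um}"
        )
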