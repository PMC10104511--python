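"""Matrix densification metrics: volume, spatial range, and plasticity.

A contracting cell locally concentrates the fibrous matrix; the densified
region is segmented from the fiber channel (see
:func:`fibremech.segmentation.segment_polymer`) and summarised here:

* **densified volume** — voxels of the polymer mask times voxel volume,
  minus the cell volume;
* **remodeling range** — for every voxel on the cell surface, the distance
  to the nearest point of the densified-region boundary, plus the farthest
  extent of densified matrix from the cell surface;
* **retained fraction** — after abolishing contraction, the densified
  volume partially relaxes; the plateau volume over the initial volume
  measures how much of the remodeling is plastic (irreversible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .core import BinaryMask, require_same_geometry

__all__ = [
    "RemodelingReport",
    "densified_volume",
    "remodeling_range",
    "relaxation_timeseries",
    "surface_voxels",
]

# 6-connectivity cross: a voxel is on the surface if a face neighbor is outside
_STRUCT_6 = ndi.generate_binary_structure(3, 1)


@dataclass
class RemodelingReport:
    """Densification metrics of one time point."""

    time_h: float
    densified_volume_um3: float
    range_distribution_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    extent_max_um: float = 0.0

    def __post_init__(self) -> None:
        self.range_distribution_um = np.asarray(self.range_distribution_um, dtype=float)
        if self.densified_volume_um3 < 0:
            raise ValueError("densified volume must be >= 0")
        if np.any(self.range_distribution_um < 0):
            raise ValueError("distances must be >= 0")


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one 6-neighbor outside the mask."""
    eroded = ndi.binary_erosion(mask, structure=_STRUCT_6, border_value=0)
    return mask & ~eroded


def densified_volume(polymer_mask: BinaryMask, cell_mask: BinaryMask) -> float:
    """Densified matrix volume: polymer-mask volume minus cell volume (µm³).

    Follows the literal definition (the full cell volume is subtracted, not
    just the overlap).  A negative result is floored at zero with a warning.
    """
    require_same_geometry(polymer_mask, cell_mask, "polymer and cell masks")
    vol = polymer_mask.volume_um3 - cell_mask.volume_um3
    if vol < 0:
        warnings.warn(
            f"cell volume exceeds polymer-mask volume ({vol:.1f} µm³); flooring at 0",
            stacklevel=2,
        )
        vol = 0.0
    return float(vol)


def remodeling_range(
    polymer_mask: BinaryMask, cell_mask: BinaryMask
) -> tuple[np.ndarray, float]:
    """Distances from the cell surface to the densified region.

    Returns ``(range_distribution_um, extent_max_um)``:

    * for each voxel on the cell surface, the Euclidean distance (µm) to
      the nearest voxel of the polymer-mask boundary (outer shell) — the
      distribution of how close densified matrix sits to the cell;
    * the maximum over densified voxels of their distance to the cell
      surface — how far the densification extends.

    An empty polymer mask yields an empty distribution and extent 0 with a
    warning.
    """
    require_same_geometry(polymer_mask, cell_mask, "polymer and cell masks")
    if not cell_mask.data.any():
        raise ValueError("empty cell mask")
    vs = np.asarray(cell_mask.voxel_size_um)
    if not polymer_mask.data.any():
        warnings.warn("empty polymer mask; no densified region detected", stacklevel=2)
        return np.empty(0), 0.0

    cell_surf = np.argwhere(surface_voxels(cell_mask.data)) * vs
    poly_surf = np.argwhere(surface_voxels(polymer_mask.data)) * vs
    tree = cKDTree(poly_surf)
    distances, _ = tree.query(cell_surf, k=1)

    dist_to_cell = ndi.distance_transform_edt(~cell_mask.data, sampling=vs)
    extent_max = float(dist_to_cell[polymer_mask.data].max())
    return np.asarray(distances, dtype=float), extent_max


def relaxation_timeseries(
    reports: list[RemodelingReport],
    plateau_window: int = 3,
    plateau_rel_tol: float = 0.02,
) -> float:
    """Retained (plastic) fraction of densified volume after relaxation.

    The first report is the pre-relaxation state (volume V₀).  A plateau is
    detected when the final ``plateau_window`` samples vary by less than
    ``plateau_rel_tol`` relative spread; the retained fraction is then the
    mean plateau volume over V₀.  Without a plateau the last-point ratio is
    returned with a warning.  The complementary reversible fraction is
    ``1 − retained``.
    """
    if len(reports) < 3:
        raise ValueError("need at least 3 time points")
    times = [r.time_h for r in reports]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("reports must be ordered in time")
    volumes = np.asarray([r.densified_volume_um3 for r in reports], dtype=float)
    v0 = volumes[0]
    if v0 <= 0:
        raise ValueError("initial densified volume must be positive")

    k = min(plateau_window, len(volumes) - 1)
    tail = volumes[-k:]
    mean_tail = float(tail.mean())
    spread = float(tail.max() - tail.min())
    if mean_tail > 0 and spread / mean_tail < plateau_rel_tol:
        v_plateau = mean_tail
    elif mean_tail == 0.0:
        v_plateau = 0.0
    else:
        warnings.warn(
            "no plateau detected in the relaxation series; using the last point",
            stacklevel=2,
        )
        v_plateau = float(volumes[-1])
    return float(np.clip(v_plateau / v0, 0.0, 1.0))
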