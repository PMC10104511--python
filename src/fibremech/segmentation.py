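"""Cell, nuclei, and polymer/densified-matrix segmentation.

* Cells: global Otsu threshold followed by small-object removal
  (26-connectivity, physical volume criterion).
* Touching cells: marker-controlled watershed on the negated Euclidean
  distance transform of the cell mask, seeded with the nuclei masks.
* Densified polymer: intensity threshold at the 99th percentile of the
  outer image frame (the x–y border band of every z-slice), which adapts
  per stack; followed by small-object removal and hole filling.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .core import BinaryMask, ImageStack, require_same_geometry

__all__ = ["segment_cell", "split_clumped_cells", "segment_polymer", "frame_band"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _remove_small(mask: np.ndarray, min_object_um3: float, voxel_volume_um3: float) -> np.ndarray:
    """Drop 26-connected components with physical volume < min_object_um3."""
    max_size = int(np.ceil(min_object_um3 / voxel_volume_um3)) - 1
    if max_size < 1:
        return mask
    return remove_small_objects(mask, max_size=max_size, connectivity=3)


def segment_cell(cell_stack: ImageStack, min_object_um3: float = 100.0) -> BinaryMask:
    """Otsu-threshold the cell channel and drop small debris.

    Connected components (26-connectivity) with physical volume below
    ``min_object_um3`` are removed.  Raises ``ValueError("no cell found")``
    if nothing survives.
    """
    data = np.asarray(cell_stack.data, dtype=float)
    thr = threshold_otsu(data)
    mask = data > thr
    mask = _remove_small(mask, min_object_um3, cell_stack.voxel_volume_um3)
    if not mask.any():
        raise ValueError("no cell found")
    return BinaryMask(mask, voxel_size_um=cell_stack.voxel_size_um, label="cell")


def segment_nuclei(nuclei_stack: ImageStack, min_object_um3: float = 30.0) -> BinaryMask:
    """Otsu + small-object removal on the nuclei channel."""
    data = np.asarray(nuclei_stack.data, dtype=float)
    mask = data > threshold_otsu(data)
    mask = _remove_small(mask, min_object_um3, nuclei_stack.voxel_volume_um3)
    if not mask.any():
        raise ValueError("no nuclei found")
    return BinaryMask(mask, voxel_size_um=nuclei_stack.voxel_size_um, label="nucleus")


def split_clumped_cells(
    cell_mask: BinaryMask,
    nuclei_stack: ImageStack,
    min_nucleus_um3: float = 30.0,
) -> list[BinaryMask]:
    """Split touching cells with a nuclei-seeded watershed.

    The nuclei channel is segmented (Otsu + small-object removal) and each
    nucleus seeds one basin of a watershed run on the negated Euclidean
    distance transform of the cell mask (anisotropy-aware).  Returns one
    mask per nucleus; masks are pairwise disjoint and their union is the
    cell mask restricted to seeded basins.

    With a single nucleus the input mask is returned unchanged.
    """
    require_same_geometry(cell_mask, nuclei_stack, "cell mask and nuclei stack")
    nuclei = segment_nuclei(nuclei_stack, min_object_um3=min_nucleus_um3)
    markers, n_nuclei = ndi.label(nuclei.data, structure=_STRUCT_26)
    if n_nuclei == 0:
        raise ValueError("no nuclei found")
    if n_nuclei == 1:
        return [cell_mask]

    edt = ndi.distance_transform_edt(cell_mask.data, sampling=cell_mask.voxel_size_um)
    markers = np.where(cell_mask.data, markers, 0)
    labels = watershed(-edt, markers=markers, mask=cell_mask.data)
    return [
        BinaryMask(labels == i, voxel_size_um=cell_mask.voxel_size_um, label="cell")
        for i in range(1, n_nuclei + 1)
        if np.any(labels == i)
    ]


def frame_band(shape: tuple[int, int, int], frame_fraction: float) -> np.ndarray:
    """Boolean mask of the x–y border band of every z-slice.

    The band width along each lateral axis is ``frame_fraction`` × that
    axis' extent (at least one voxel); the z-faces are not framed, matching
    confocal stacks that are shallow in z.
    """
    if not 0.0 < frame_fraction < 0.5:
        raise ValueError("frame_fraction must lie in (0, 0.5)")
    nz, ny, nx = shape
    wy = max(1, int(round(frame_fraction * ny)))
    wx = max(1, int(round(frame_fraction * nx)))
    band = np.zeros(shape, dtype=bool)
    band[:, :wy, :] = True
    band[:, -wy:, :] = True
    band[:, :, :wx] = True
    band[:, :, -wx:] = True
    return band


def segment_polymer(
    fiber_stack: ImageStack,
    frame_fraction: float = 0.10,
    percentile: float = 99.0,
    min_object_um3: float = 10.0,
    fill_holes: bool = True,
) -> BinaryMask:
    """Segment densified polymer by an adaptive frame-percentile threshold.

    The threshold is the given percentile (linear interpolation between
    order statistics) of the intensities in the outer frame of the image —
    far from the cell, hence representative of undensified matrix.  Voxels
    strictly above the threshold form the mask, which is then cleaned by
    small-object removal and (optionally) hole filling.  Because the frame
    is re-sampled per stack, the threshold adapts across time points.
    """
    band = frame_band(fiber_stack.shape, frame_fraction)
    frame_values = np.asarray(fiber_stack.data, dtype=float)[band]
    if frame_values.size == 0:
        raise ValueError("empty frame: cannot estimate a threshold")
    thr = np.percentile(frame_values, percentile)
    mask = np.asarray(fiber_stack.data, dtype=float) > thr
    mask = _remove_small(mask, min_object_um3, fiber_stack.voxel_volume_um3)
    if fill_holes:
        mask = ndi.binary_fill_holes(mask)
    return BinaryMask(mask, voxel_size_um=fiber_stack.voxel_size_um, label="polymer")
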