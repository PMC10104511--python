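"""Readers and writers: OME-TIFF stacks, masks, VTK vector fields, CSV tables.

Conventions: arrays are (z, y, x); vector components are written in
(x, y, z) order in physical µm.  OME-TIFF channel stacks are stored CZYX
with named channels and PhysicalSize metadata carrying the voxel size.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .core import BinaryMask, DecayProfile, DisplacementField, ImageStack

__all__ = [
    "MatrixDescriptor",
    "MATRIX_LIBRARY",
    "read_stack",
    "read_channels",
    "write_channels",
    "write_mask",
    "read_mask",
    "write_field_vtk",
    "read_field_vtk",
    "write_decay_profile_csv",
]


@dataclass
class MatrixDescriptor:
    """Experiment metadata describing a gel formulation (not used in any
    computation; attached to outputs for provenance)."""

    name: str
    contour_length_nm: float | None = None
    concentration_mg_ml: float | None = None
    rgd_density_per_um: float | None = None
    shear_modulus_Pa: float | None = None
    critical_stress_Pa: float | None = None

    def __post_init__(self) -> None:
        for f in (
            "contour_length_nm",
            "concentration_mg_ml",
            "rgd_density_per_um",
            "shear_modulus_Pa",
            "critical_stress_Pa",
        ):
            v = getattr(self, f)
            if v is not None and v <= 0:
                raise ValueError(f"{f} must be positive when present")


#: Characterisation of the gel library used throughout: polyisocyanide (PIC)
#: gels of short/long polymers with varying adhesive-peptide density, plus
#: the biological reference matrices.
MATRIX_LIBRARY: dict[str, MatrixDescriptor] = {
    "PIC-short-noRGD": MatrixDescriptor("PIC-short-noRGD", 154, 1.0, None, 47, 10.6),
    "PIC-short-RGD": MatrixDescriptor("PIC-short-RGD", 154, 1.0, 3.7, 46, 8.6),
    "PIC-short-RGD+": MatrixDescriptor("PIC-short-RGD+", 154, 1.0, 31.4, 45, 7.7),
    "PIC-long-RGD+": MatrixDescriptor("PIC-long-RGD+", 229, 1.0, 31.4, 93, 19.9),
    "PIC-short-RGD+-1.5x": MatrixDescriptor("PIC-short-RGD+-1.5x", 154, 1.5, 47.1, 89, 11.6),
    "collagen": MatrixDescriptor("collagen", None, 1.2, None, 60, 3.5),
    "matrigel": MatrixDescriptor("matrigel", None, 9.5, None, 28, 6.9),
}


# ---------------------------------------------------------------------------
# OME-TIFF channel stacks

_OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


def write_channels(
    channels: Mapping[str, ImageStack], path: str | Path, time_h: float | None = None
) -> None:
    """Write a multi-channel stack as OME-TIFF (CZYX, named channels)."""
    path = Path(path)
    names = list(channels)
    first = channels[names[0]]
    data = np.stack([np.asarray(channels[n].data, dtype=np.float32) for n in names])
    vz, vy, vx = first.voxel_size_um
    metadata = {
        "axes": "CZYX",
        "Channel": {"Name": names},
        "PhysicalSizeX": vx,
        "PhysicalSizeY": vy,
        "PhysicalSizeZ": vz,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZUnit": "µm",
    }
    tifffile.imwrite(path, data, ome=True, metadata=metadata)


def _parse_ome(path: Path) -> tuple[list[str], tuple[float, float, float] | None]:
    with tifffile.TiffFile(path) as tf:
        xml = tf.ome_metadata
    names: list[str] = []
    voxel = None
    if xml:
        root = ET.fromstring(xml)
        pixels = root.find(f"{_OME_NS}Image/{_OME_NS}Pixels")
        if pixels is not None:
            for ch in pixels.findall(f"{_OME_NS}Channel"):
                names.append(ch.get("Name") or f"channel{len(names)}")
            try:
                voxel = (
                    float(pixels.get("PhysicalSizeZ")),
                    float(pixels.get("PhysicalSizeY")),
                    float(pixels.get("PhysicalSizeX")),
                )
            except (TypeError, ValueError):
                voxel = None
    return names, voxel


def read_channels(
    path: str | Path, voxel_size_um: tuple[float, float, float] | None = None
) -> dict[str, ImageStack]:
    """Read an OME-TIFF written by :func:`write_channels` into named stacks.

    ``voxel_size_um`` overrides the file metadata; if the metadata carries
    no voxel size and no override is given, an error is raised.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[None]
    names, voxel = _parse_ome(path)
    if not names:
        names = [f"channel{i}" for i in range(data.shape[0])]
    if voxel_size_um is not None:
        voxel = tuple(float(v) for v in voxel_size_um)
    if voxel is None:
        raise ValueError(
            f"{path} carries no voxel-size metadata; pass voxel_size_um explicitly"
        )
    return {
        name: ImageStack(np.asarray(data[i], dtype=float), voxel_size_um=voxel, channel=name)
        for i, name in enumerate(names)
    }


def read_stack(
    path: str | Path,
    channel: str | int = 0,
    voxel_size_um: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read one channel (by name or index) of an OME-TIFF stack."""
    channels = read_channels(path, voxel_size_um=voxel_size_um)
    if isinstance(channel, int):
        try:
            return list(channels.values())[channel]
        except IndexError:
            raise KeyError(f"{path} has no channel index {channel}") from None
    if channel not in channels:
        raise KeyError(f"{path} has no channel named {channel!r}; has {list(channels)}")
    return channels[channel]


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit single-channel OME-TIFF."""
    stack = ImageStack(
        mask.data.astype(np.uint8) * 255, voxel_size_um=mask.voxel_size_um,
        channel=mask.label or "mask",
    )
    write_channels({stack.channel: stack}, path)


def read_mask(path: str | Path, label: str = "", **kw) -> BinaryMask:
    stack = read_stack(path, 0, **kw)
    return BinaryMask(stack.data > 0, voxel_size_um=stack.voxel_size_um, label=label)


# ---------------------------------------------------------------------------
# legacy-VTK vector fields (ParaView-compatible, plain text)


def write_field_vtk(field: DisplacementField, path: str | Path, name: str = "displacement_um") -> None:
    """Write a displacement field as a legacy ASCII VTK structured-points
    file with one VECTORS array (µm), loadable in ParaView."""
    nz, ny, nx = field.shape
    vz, vy, vx = field.voxel_size_um
    vec = field.vectors.reshape(-1, 3)  # x fastest when iterating C-order (z,y,x)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("matrix displacement field (um)\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {vx:.6g} {vy:.6g} {vz:.6g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"VECTORS {name} float\n")
        np.savetxt(fh, vec, fmt="%.6e")


def read_field_vtk(path: str | Path) -> DisplacementField:
    """Read a field written by :func:`write_field_vtk`."""
    with open(path) as fh:
        lines = fh.readlines()
    dims = spacing = None
    start = None
    for i, line in enumerate(lines):
        if line.startswith("DIMENSIONS"):
            dims = [int(v) for v in line.split()[1:4]]
        elif line.startswith("SPACING"):
            spacing = [float(v) for v in line.split()[1:4]]
        elif line.startswith("VECTORS"):
            start = i + 1
    if dims is None or spacing is None or start is None:
        raise ValueError(f"{path} is not a structured-points vector file")
    nx, ny, nz = dims
    vec = np.loadtxt(lines[start : start + nx * ny * nz])
    vectors = vec.reshape(nz, ny, nx, 3)
    return DisplacementField(
        vectors, voxel_size_um=(spacing[2], spacing[1], spacing[0])
    )


# ---------------------------------------------------------------------------
# CSV tables


def write_decay_profile_csv(profile: DecayProfile, path: str | Path) -> None:
    """Columns: bin_lo_um, bin_hi_um, mean_mag_um, sd_um, n_voxels."""
    pd.DataFrame(
        {
            "bin_lo_um": profile.bin_edges_um[:-1],
            "bin_hi_um": profile.bin_edges_um[1:],
            "mean_mag_um": profile.mean_mag_um,
            "sd_um": profile.sd_um,
            "n_voxels": profile.n_voxels,
        }
    ).to_csv(path, index=False)


def read_decay_profile_csv(path: str | Path) -> DecayProfile:
    df = pd.read_csv(path)
    edges = np.append(df["bin_lo_um"].to_numpy(), df["bin_hi_um"].iloc[-1])
    return DecayProfile(
        bin_edges_um=edges,
        mean_mag_um=df["mean_mag_um"].to_numpy(),
        sd_um=df["sd_um"].to_numpy(),
        n_voxels=df["n_voxels"].to_numpy(),
    )
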