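"""Configuration and the end-to-end pipeline driver.

The pipeline chains preprocess → segment → morphology → displacement →
remodeling over one relaxed/stressed stack pair and writes every artifact
into a fresh run directory together with a manifest (inputs, parameters,
seed, package version, content hashes).  Given an identical configuration
the tabular outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ImageStack
from .displacement import decay_profile, max_displacement, register_ffd
from .io import (
    read_channels,
    write_decay_profile_csv,
    write_field_vtk,
    write_mask,
)
from .morphology import cell_metrics
from .preprocess import correct_drift, denoise_pls, stretch_contrast
from .remodeling import densified_volume, remodeling_range
from .segmentation import segment_cell, segment_polymer, split_clumped_cells

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("fibremech")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run.

    Unknown keys in a YAML file are rejected, and cross-field constraints
    (e.g. cell splitting requires a nuclei channel) are checked before any
    stage executes.
    """

    relaxed_path: str = ""
    stressed_path: str = ""
    out_dir: str = "runs"
    voxel_size_um: tuple[float, float, float] | None = None
    fiber_channel: str = "fiber"
    cell_channel: str = "cell"
    nuclei_channel: str | None = "nuclei"
    # preprocess
    smoothing: float | str = "auto"
    p_low: float = 0.1
    p_high: float = 99.9
    subvoxel_drift: bool = False
    # segmentation
    min_cell_um3: float = 100.0
    split_cells: bool = False
    polymer_frame_fraction: float = 0.10
    polymer_percentile: float = 99.0
    polymer_min_object_um3: float = 10.0
    polymer_fill_holes: bool = True
    # displacement
    grid_spacing_vox: int = 8
    n_levels: int = 2
    iterations: int = 200
    n_samples: int = 20000
    bin_width_um: float = 5.0
    max_dist_um: float = 150.0
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.relaxed_path or not self.stressed_path:
            raise ValueError("relaxed_path and stressed_path are required")
        if self.split_cells and not self.nuclei_channel:
            raise ValueError("cell splitting requires a nuclei channel")
        if not 0 <= self.p_low < self.p_high <= 100:
            raise ValueError("need 0 <= p_low < p_high <= 100")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "voxel_size_um" in raw and raw["voxel_size_um"] is not None:
            raw["voxel_size_um"] = tuple(raw["voxel_size_um"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _new_run_dir(base: Path) -> Path:
    base.mkdir(parents=True, exist_ok=True)
    i = 1
    while True:
        candidate = base / f"run-{i:03d}"
        try:
            candidate.mkdir()
            return candidate
        except FileExistsError:
            i += 1


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; return the run directory.

    Artifacts: preprocessed masks (TIFF), per-cell morphology CSV,
    displacement field (VTK) + decay profile CSV + maximum displacement,
    remodeling metrics CSV, and ``manifest.json`` listing every output with
    a SHA-256 content hash.
    """
    logging.basicConfig(level=config.log_level)
    run_dir = _new_run_dir(Path(config.out_dir))
    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "version": __version__,
        "stages": [],
        "outputs": {},
    }
    stage = "preprocess"
    try:
        relaxed = read_channels(config.relaxed_path, voxel_size_um=config.voxel_size_um)
        stressed = read_channels(config.stressed_path, voxel_size_um=config.voxel_size_um)
        for chans in (relaxed, stressed):
            for required in (config.fiber_channel, config.cell_channel):
                if required not in chans:
                    raise PipelineError(
                        stage, "missing-channel", f"channel {required!r} not found"
                    )

        def prep(stk: ImageStack) -> ImageStack:
            return stretch_contrast(
                denoise_pls(stk, config.smoothing), config.p_low, config.p_high
            )

        relaxed = {k: prep(v) for k, v in relaxed.items()}
        stressed = {k: prep(v) for k, v in stressed.items()}
        stressed, shift = correct_drift(
            stressed,
            relaxed[config.fiber_channel],
            fiber_channel=config.fiber_channel,
            subvoxel=config.subvoxel_drift,
        )
        log.info("drift shift (z, y, x) vox: %s", shift)
        manifest["drift_shift_vox_zyx"] = [float(s) for s in shift]
        manifest["stages"].append(stage)

        stage = "segment"
        cell_mask = segment_cell(stressed[config.cell_channel], config.min_cell_um3)
        polymer_mask = segment_polymer(
            stressed[config.fiber_channel],
            frame_fraction=config.polymer_frame_fraction,
            percentile=config.polymer_percentile,
            min_object_um3=config.polymer_min_object_um3,
            fill_holes=config.polymer_fill_holes,
        )
        if config.split_cells:
            cells = split_clumped_cells(cell_mask, stressed[config.nuclei_channel])
        else:
            cells = [cell_mask]
        write_mask(cell_mask, run_dir / "cell_mask.ome.tif")
        write_mask(polymer_mask, run_dir / "polymer_mask.ome.tif")
        index = []
        for i, m in enumerate(cells):
            name = f"cell_{i:02d}.ome.tif"
            write_mask(m, run_dir / name)
            index.append({"cell_id": i, "mask": name})
        (run_dir / "cells.json").write_text(json.dumps(index, indent=2))
        manifest["stages"].append(stage)

        stage = "morphology"
        rows = []
        for i, m in enumerate(cells):
            morph = cell_metrics(m, cell_id=i)
            rows.append(
                {
                    "cell_id": i,
                    "volume_um3": morph.volume_um3,
                    "sphericity_pct": morph.sphericity_pct,
                    "inscribed_R_um": morph.inscribed_radius_R_um,
                    "protrusion_count": morph.protrusion_count,
                    "protrusion_lengths_um": ";".join(
                        f"{v:.3f}" for v in morph.protrusion_lengths_um
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(run_dir / "morphology.csv", index=False)
        manifest["stages"].append(stage)

        stage = "displacement"
        field_ = register_ffd(
            stressed[config.fiber_channel],
            relaxed[config.fiber_channel],
            grid_spacing_vox=config.grid_spacing_vox,
            n_levels=config.n_levels,
            iterations=config.iterations,
            seed=config.seed,
            n_samples=config.n_samples,
        )
        write_field_vtk(field_, run_dir / "displacement.vtk")
        profile = decay_profile(
            field_, cell_mask, bin_width_um=config.bin_width_um,
            max_dist_um=config.max_dist_um,
        )
        write_decay_profile_csv(profile, run_dir / "decay_profile.csv")
        pd.DataFrame(
            {
                "max_displacement_um": [max_displacement(field_)],
                "p99_displacement_um": [max_displacement(field_, 99)],
            }
        ).to_csv(run_dir / "max_displacement.csv", index=False)
        manifest["stages"].append(stage)

        stage = "remodeling"
        vol = densified_volume(polymer_mask, cell_mask)
        distances, extent = remodeling_range(polymer_mask, cell_mask)
        pd.DataFrame(
            {
                "densified_volume_um3": [vol],
                "extent_max_um": [extent],
                "range_median_um": [float(np.median(distances)) if len(distances) else np.nan],
            }
        ).to_csv(run_dir / "remodeling.csv", index=False)
        pd.DataFrame({"cell_surface_to_densified_um": distances}).to_csv(
            run_dir / "remodeling_range_distribution.csv", index=False
        )
        manifest["stages"].append(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, "stage-failure", str(exc)) from exc

    for p in sorted(run_dir.iterdir()):
        if p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir
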