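"""Synthetic 3D scenes and rheology traces with exact ground truth.

The generator emulates the statistical structure of confocal z-stacks of a
contractile cell embedded in a fluorescently labeled fibrous hydrogel:

* a **fiber channel** — random sub-resolution line segments blurred by a
  small Gaussian PSF over a diffuse background; around the cell a
  *densification shell* where the fiber concentration is so high that the
  PSF merges fibers into a quasi-continuous bright mat;
* a **cell channel** — a spherical body with slender capsule protrusions;
* a **nuclei channel** — a smaller ball inside the body;
* a smooth, cell-centered radial **displacement field** that warps the
  relaxed matrix into the stressed state, with magnitude decaying
  exponentially with distance from the cell surface;
* optional stage drift (integer circular shift) and confocal noise
  (Poisson then additive Gaussian), applied last.

Everything stochastic is drawn from a single seeded generator, so identical
parameters and seed give bit-identical scenes.  The ground truth (masks,
field, protrusion geometry, densified volume) is recorded before noise and
drift, which makes every downstream stage testable without real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter, map_coordinates

from .core import BinaryMask, DisplacementField, ImageStack
from .rheology import CreepTrace, ModulusTrace

__all__ = [
    "SceneParams",
    "SceneTruth",
    "RheoTruth",
    "generate_scene",
    "generate_cell_mask",
    "generate_creep_trace",
    "generate_modulus_trace",
    "generate_relaxation_series",
    "warp_stack",
]


@dataclass
class SceneParams:
    """Parameters of a synthetic cell-in-gel scene.

    Defaults reflect the imaging conditions the analyses assume: isotropic
    0.57 µm voxels, a ~10 µm-radius mesenchymal cell body with a handful of
    slender protrusions, displacement amplitudes of order 1 µm decaying over
    ~20 µm, and a densified mat extending several µm from the cell surface.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_um: tuple[float, float, float] = (0.57, 0.57, 0.57)
    cell_center_vox: tuple[float, float, float] | None = None  # (z, y, x); default grid center
    cell_radius_um: float = 10.0
    n_protrusions: int = 3
    protrusion_length_um: float = 18.0
    protrusion_radius_um: float = 1.5
    n_fibers: int = 400
    fiber_intensity: float = 120.0
    background_intensity: float = 10.0
    densification_shell_um: tuple[float, float] = (0.0, 8.0)
    densification_factor: float = 2.0
    displacement_amplitude_um: float = 1.5
    displacement_decay_um: float = 20.0
    noise: tuple[float, float] = (1.0, 2.0)  # (poisson_scale, gaussian_sd)
    drift_shift_vox: tuple[int, int, int] = (0, 0, 0)  # (z, y, x)
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape axes must each be >= 8 voxels")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.cell_center_vox is None:
            self.cell_center_vox = tuple((n - 1) / 2.0 for n in self.grid_shape)
        for name in ("cell_radius_um", "protrusion_length_um", "protrusion_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_protrusions < 0:
            raise ValueError("n_protrusions must be >= 0")
        inner, outer = self.densification_shell_um
        if not (0 <= inner < outer):
            raise ValueError("densification shell requires 0 <= inner < outer")
        if self.densification_factor < 1:
            raise ValueError("densification_factor must be >= 1")
        if self.displacement_amplitude_um < 0 or self.displacement_decay_um <= 0:
            raise ValueError("displacement amplitude >= 0 and decay > 0 required")
        self.drift_shift_vox = tuple(int(s) for s in self.drift_shift_vox)


@dataclass
class SceneTruth:
    """Exact pre-noise ground truth of a generated scene."""

    cell_mask: BinaryMask
    nuclei_mask: BinaryMask
    densified_mask: BinaryMask
    field_true: DisplacementField
    protrusion_count: int
    protrusion_lengths_um: list[float]
    densified_volume_um3: float
    applied_shift_vox: tuple[int, int, int]


@dataclass
class RheoTruth:
    """Ground truth of a generated rheology trace."""

    plastic_fraction_true: float
    reversible_stiffening_Pa: float = 0.0
    irreversible_stiffening_Pa: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.plastic_fraction_true <= 1.0:
            raise ValueError("plastic_fraction_true must lie in [0, 1]")


# ---------------------------------------------------------------------------
# geometry helpers


def _physical_coords(shape, voxel_size):
    """Per-axis physical coordinates (µm) of voxel centers, broadcastable."""
    return [
        np.arange(n, dtype=float)[
            (slice(None),) + (None,) * (2 - ax)
        ] * voxel_size[ax]
        for ax, n in enumerate(shape)
    ]


def _capsule_mask(shape, voxel_size, a_um, b_um, radius_um):
    """Boolean mask of a capsule (cylinder with spherical caps) from a to b."""
    zz, yy, xx = _physical_coords(shape, voxel_size)
    a = np.asarray(a_um, dtype=float)
    b = np.asarray(b_um, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    # distance from each voxel center to the segment [a, b]
    t = ((zz - a[0]) * ab[0] + (yy - a[1]) * ab[1] + (xx - a[2]) * ab[2]) / denom
    t = np.clip(t, 0.0, 1.0)
    d2 = (
        (zz - a[0] - t * ab[0]) ** 2
        + (yy - a[1] - t * ab[1]) ** 2
        + (xx - a[2] - t * ab[2]) ** 2
    )
    return d2 <= radius_um**2


def _protrusion_directions(n: int, rng: np.random.Generator, min_angle_deg=40.0):
    """n random unit vectors with pairwise separation >= min_angle_deg."""
    cos_max = np.cos(np.deg2rad(min_angle_deg))
    dirs: list[np.ndarray] = []
    for _ in range(5000):
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        if all(float(v @ d) < cos_max for d in dirs):
            dirs.append(v)
            if len(dirs) == n:
                return dirs
    raise RuntimeError(f"could not place {n} protrusions with {min_angle_deg} deg separation")


def generate_cell_mask(params: SceneParams) -> tuple[BinaryMask, BinaryMask, list[float]]:
    """Cell body + protrusion and nuclei masks, without rendering images.

    Returns ``(cell_mask, nuclei_mask, protrusion_lengths_um)``; the
    stochastic protrusion directions are drawn from ``params.seed`` so the
    mask is reproducible on its own.  Raises if a protrusion (including its
    radius) would leave the grid, naming the offending protrusion.
    """
    rng = np.random.default_rng(params.seed)
    cell, nuc, lengths = _build_cell(params, rng)
    return cell, nuc, lengths


def _build_cell(params: SceneParams, rng: np.random.Generator):
    shape, vs = params.grid_shape, params.voxel_size_um
    center = np.asarray(params.cell_center_vox, dtype=float) * np.asarray(vs)
    zz, yy, xx = _physical_coords(shape, vs)
    r2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    cell = r2 <= params.cell_radius_um**2
    extent_um = np.asarray(shape) * np.asarray(vs)

    lengths: list[float] = []
    if params.n_protrusions > 0:
        dirs = _protrusion_directions(params.n_protrusions, rng)
        for i, d in enumerate(dirs):
            base = center + (params.cell_radius_um - params.protrusion_radius_um) * d
            tip = center + (params.cell_radius_um + params.protrusion_length_um) * d
            lo = tip - params.protrusion_radius_um
            hi = tip + params.protrusion_radius_um
            if np.any(lo < 0) or np.any(hi > extent_um - np.asarray(vs)):
                raise ValueError(
                    f"protrusion {i} (direction {np.round(d, 3).tolist()}) extends "
                    f"outside the grid; enlarge grid_shape or shorten protrusions"
                )
            cell |= _capsule_mask(shape, vs, base, tip, params.protrusion_radius_um)
            lengths.append(float(params.protrusion_length_um))

    nucleus = r2 <= (0.45 * params.cell_radius_um) ** 2
    cm = BinaryMask(cell, voxel_size_um=vs, label="cell")
    nm = BinaryMask(nucleus, voxel_size_um=vs, label="nucleus")
    return cm, nm, lengths


def _rasterize_fibers(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Random line segments of uniform intensity, blurred by a 1-voxel PSF."""
    shape, vs = params.grid_shape, np.asarray(params.voxel_size_um)
    extent_um = np.asarray(shape) * vs
    img = np.zeros(shape, dtype=float)
    step = 0.5 * float(vs.min())
    for _ in range(params.n_fibers):
        start = rng.uniform(0, extent_um, size=3)
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        length = rng.uniform(15.0, 45.0)
        n_samples = max(2, int(length / step))
        pts = start + np.outer(np.linspace(0, length, n_samples), d)
        idx = np.round(pts / vs).astype(int)
        keep = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
        idx = idx[keep]
        img[idx[:, 0], idx[:, 1], idx[:, 2]] = params.fiber_intensity
    # sub-resolution fibers: a ~1 voxel PSF sets their apparent width
    return gaussian_filter(img, sigma=1.0)


def _radial_field(params: SceneParams, cell_mask: np.ndarray) -> np.ndarray:
    """Inward radial field, |u| = A·exp(−d/λ) outside the cell (d = distance
    to the cell surface), linearly tapered to zero at the cell center so the
    discrete gradient stays bounded.  Components ordered (x, y, z), µm."""
    shape, vs = params.grid_shape, params.voxel_size_um
    center = np.asarray(params.cell_center_vox, dtype=float) * np.asarray(vs)
    zz, yy, xx = _physical_coords(shape, vs)
    dz, dy, dx = zz - center[0], yy - center[1], xx - center[2]
    r = np.sqrt(dz**2 + dy**2 + dx**2)
    d_out = distance_transform_edt(~cell_mask, sampling=vs)
    mag = params.displacement_amplitude_um * np.exp(-d_out / params.displacement_decay_um)
    inside = cell_mask & (d_out == 0)
    taper = np.clip(r / params.cell_radius_um, 0.0, 1.0)
    mag = np.where(inside, params.displacement_amplitude_um * taper, mag)
    with np.errstate(invalid="ignore", divide="ignore"):
        ez, ey, ex = dz / r, dy / r, dx / r
    for e in (ez, ey, ex):
        e[~np.isfinite(e)] = 0.0
    # inward: matter moves toward the cell between relaxed and stressed state
    return np.stack([-mag * ex, -mag * ey, -mag * ez], axis=-1)


def warp_stack(stack: ImageStack, field: DisplacementField) -> ImageStack:
    """Warp a stack by a displacement field (trilinear, reflect boundaries).

    The output at voxel x samples the input at x − u(x): material displaced
    by u between the relaxed and stressed states renders the stressed image.
    """
    vs = stack.voxel_size_um
    nz, ny, nx = stack.shape
    zi, yi, xi = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    u = field.vectors  # (..., (x, y, z)) µm
    coords = np.stack(
        [
            zi - u[..., 2] / vs[0],
            yi - u[..., 1] / vs[1],
            xi - u[..., 0] / vs[2],
        ]
    )
    warped = map_coordinates(stack.data.astype(float), coords, order=1, mode="reflect")
    return stack.with_data(warped)


def _apply_noise(data: np.ndarray, noise, rng: np.random.Generator) -> np.ndarray:
    poisson_scale, gaussian_sd = noise
    out = data.astype(float)
    if poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * poisson_scale) / poisson_scale
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, size=out.shape)
    return out


def generate_scene(
    params: SceneParams,
) -> tuple[dict[str, ImageStack], dict[str, ImageStack], SceneTruth]:
    """Generate a relaxed/stressed pair of multi-channel stacks plus truth.

    Returns ``(relaxed, stressed, truth)`` where the stacks are mappings
    ``{"fiber": ..., "cell": ..., "nuclei": ...}``.  The stressed fiber
    channel is the relaxed one warped by the true displacement field, then
    circularly shifted by ``drift_shift_vox`` and noised; the truth records
    the pre-noise, pre-drift masks and field.
    """
    rng = np.random.default_rng(params.seed)
    vs = params.voxel_size_um

    cell_mask, nuclei_mask, lengths = _build_cell(params, rng)
    fiber = _rasterize_fibers(params, rng)
    fiber[cell_mask.data] = 0.0  # the cell body excludes matrix fibers

    # densified mat: fiber concentration high enough that the PSF merges
    # fibers into a bright quasi-continuum (floor at 70% of the nominal fiber
    # intensity) while the individual-fiber texture stays visible on top
    d_out = distance_transform_edt(~cell_mask.data, sampling=vs)
    inner, outer = params.densification_shell_um
    shell = (~cell_mask.data) & (d_out >= inner) & (d_out <= outer)
    fiber_dens = fiber.copy()
    fiber_dens[shell] = params.densification_factor * (
        0.7 * params.fiber_intensity + 0.6 * fiber[shell]
    )
    relaxed_fiber = fiber_dens + params.background_intensity

    cell_img = gaussian_filter(cell_mask.data * 100.0, sigma=0.8)
    nuc_img = gaussian_filter(nuclei_mask.data * 100.0, sigma=0.8)

    field_vec = _radial_field(params, cell_mask.data)
    field_true = DisplacementField(field_vec, voxel_size_um=vs)

    relaxed = {
        "fiber": ImageStack(relaxed_fiber, voxel_size_um=vs, channel="fiber"),
        "cell": ImageStack(cell_img + params.background_intensity, voxel_size_um=vs, channel="cell"),
        "nuclei": ImageStack(nuc_img + params.background_intensity, voxel_size_um=vs, channel="nuclei"),
    }

    stressed = {name: warp_stack(stk, field_true) for name, stk in relaxed.items()}
    shift = params.drift_shift_vox
    if any(shift):
        for name, stk in stressed.items():
            stressed[name] = stk.with_data(np.roll(stk.data, shift, axis=(0, 1, 2)))

    if any(n > 0 for n in params.noise):
        relaxed = {
            name: stk.with_data(_apply_noise(stk.data, params.noise, rng))
            for name, stk in relaxed.items()
        }
        stressed = {
            name: stk.with_data(_apply_noise(stk.data, params.noise, rng))
            for name, stk in stressed.items()
        }

    densified_mask = BinaryMask(shell, voxel_size_um=vs, label="polymer")
    truth = SceneTruth(
        cell_mask=cell_mask,
        nuclei_mask=nuclei_mask,
        densified_mask=densified_mask,
        field_true=field_true,
        protrusion_count=params.n_protrusions,
        protrusion_lengths_um=lengths,
        densified_volume_um3=densified_mask.volume_um3,
        applied_shift_vox=shift,
    )
    return relaxed, stressed, truth


# ---------------------------------------------------------------------------
# rheology trace generators


def generate_creep_trace(
    stress_Pa: float = 20.0,
    creep_duration_s: float = 3600.0,
    recovery_duration_s: float = 3600.0,
    plastic_fraction: float = 0.75,
    relax_time_s: float = 120.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt_s: float = 2.0,
    modulus_Pa: float = 47.0,
) -> tuple[CreepTrace, RheoTruth]:
    """Synthetic creep–recovery strain trace with known plastic fraction.

    During creep the strain rises saturating-exponentially toward
    ``stress_Pa / modulus_Pa``; during recovery it decays with time constant
    ``relax_time_s`` toward ``plastic_fraction`` × the strain actually
    reached at the end of creep.  Defaults mirror a constant stress in the
    5–80 Pa range applied for up to an hour and a gel that retains ~75 % of
    its deformation.
    """
    if creep_duration_s <= 0 or recovery_duration_s <= 0:
        raise ValueError("durations must be positive")
    if not 0.0 <= plastic_fraction <= 1.0:
        raise ValueError("plastic_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    eps_target = stress_Pa / modulus_Pa

    t_creep = np.arange(0.0, creep_duration_s, dt_s)
    eps_creep = eps_target * (1.0 - np.exp(-t_creep / relax_time_s))
    eps_end = eps_creep[-1]
    eps_res = plastic_fraction * eps_end

    t_rec = np.arange(creep_duration_s, creep_duration_s + recovery_duration_s, dt_s)
    eps_rec = eps_res + (eps_end - eps_res) * np.exp(-(t_rec - t_creep[-1]) / relax_time_s)

    strain = np.concatenate([eps_creep, eps_rec])
    if noise_sd > 0:
        strain = strain + rng.normal(0.0, noise_sd, size=strain.shape)
    phase = np.array(["creep"] * len(t_creep) + ["recovery"] * len(t_rec), dtype=object)
    trace = CreepTrace(
        time_s=np.concatenate([t_creep, t_rec]),
        strain=strain,
        phase=phase,
        applied_stress_Pa=stress_Pa,
    )
    return trace, RheoTruth(plastic_fraction_true=plastic_fraction)


def generate_modulus_trace(
    G_baseline_Pa: float = 45.0,
    stiffening_ratio: float = 3.0,
    cytod_time_h: float = 24.0,
    irreversible_fraction: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_h: float | None = None,
    dt_h: float = 0.05,
    rise_tau_h: float | None = None,
    fall_tau_h: float = 0.25,
) -> tuple[ModulusTrace, RheoTruth]:
    """Synthetic live-cell G′(t) trace: stiffening plateau, then cytoD drop.

    G′ rises from the cell-free baseline toward baseline × ``stiffening_ratio``
    (plateauing well before ``cytod_time_h``), then relaxes to
    baseline + ``irreversible_fraction`` × (plateau − baseline).  Defaults
    mirror a 45 Pa gel stiffening ~3× over 24 h with half the stiffening
    surviving cytoD.
    """
    if stiffening_ratio < 1.0:
        raise ValueError("stiffening_ratio must be >= 1")
    if not 0.0 <= irreversible_fraction <= 1.0:
        raise ValueError("irreversible_fraction must lie in [0, 1]")
    if duration_h is None:
        duration_h = cytod_time_h + 4.0
    if not 0.0 < cytod_time_h < duration_h:
        raise ValueError(
            f"cytod_time_h={cytod_time_h} outside the trace span (0, {duration_h})"
        )
    if rise_tau_h is None:
        rise_tau_h = cytod_time_h / 6.0
    rng = np.random.default_rng(seed)

    t = np.arange(0.0, duration_h + dt_h / 2, dt_h)
    plateau = G_baseline_Pa * stiffening_ratio
    post = G_baseline_Pa + irreversible_fraction * (plateau - G_baseline_Pa)
    g = np.where(
        t < cytod_time_h,
        G_baseline_Pa + (plateau - G_baseline_Pa) * (1 - np.exp(-t / rise_tau_h)),
        post + (plateau - post) * np.exp(-(t - cytod_time_h) / fall_tau_h),
    )
    if noise_sd > 0:
        g = np.clip(g + rng.normal(0.0, noise_sd, size=g.shape), 1e-6, None)
    trace = ModulusTrace(
        time_h=t, G_prime_Pa=g, cytod_time_h=cytod_time_h, G_baseline_Pa=G_baseline_Pa
    )
    truth = RheoTruth(
        plastic_fraction_true=irreversible_fraction,
        reversible_stiffening_Pa=plateau - post,
        irreversible_stiffening_Pa=post - G_baseline_Pa,
    )
    return trace, truth


def generate_relaxation_series(
    v_initial_um3: float = 20000.0,
    retained_fraction: float = 0.75,
    relax_time_h: float = 1.0,
    duration_h: float = 6.0,
    dt_h: float = 1.0 / 3.0,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, RheoTruth]:
    """Densified-volume time series after abolishing cell contraction.

    V(t) = V₀·(p + (1−p)·exp(−t/τ)) with p the retained (plastic) volume
    fraction, sampled every 20 min by default, with multiplicative Gaussian
    noise.  Returns ``(time_h, volume_um3, truth)``.
    """
    if not 0.0 <= retained_fraction <= 1.0:
        raise ValueError("retained_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + dt_h / 2, dt_h)
    v = v_initial_um3 * (
        retained_fraction + (1 - retained_fraction) * np.exp(-t / relax_time_h)
    )
    if noise_frac > 0:
        v = np.clip(v * (1 + rng.normal(0.0, noise_frac, size=v.shape)), 0, None)
    return t, v, RheoTruth(plastic_fraction_true=retained_fraction)
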