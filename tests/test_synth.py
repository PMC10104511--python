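"""Synthetic scene and trace generators: determinism, identity cases, and
self-consistency of the recorded ground truth."""

import numpy as np
import pytest

from fibremech.synth import (
    RheoTruth,
    SceneParams,
    generate_creep_trace,
    generate_modulus_trace,
    generate_relaxation_series,
    generate_scene,
    warp_stack,
)

SMALL = dict(
    grid_shape=(48, 48, 48),
    cell_radius_um=5.0,
    n_protrusions=2,
    protrusion_length_um=6.0,
    n_fibers=80,
)


def test_identity_scene_has_identical_fiber_channels():
    params = SceneParams(
        grid_shape=(48, 48, 48), cell_radius_um=5.0, n_protrusions=0,
        n_fibers=80, displacement_amplitude_um=0.0, noise=(0.0, 0.0),
        drift_shift_vox=(0, 0, 0), seed=3,
    )
    relaxed, stressed, _ = generate_scene(params)
    np.testing.assert_array_equal(relaxed["fiber"].data, stressed["fiber"].data)


def test_same_seed_gives_bit_identical_scenes():
    params = SceneParams(**SMALL, seed=7)
    r1, s1, t1 = generate_scene(params)
    r2, s2, t2 = generate_scene(SceneParams(**SMALL, seed=7))
    for ch in r1:
        np.testing.assert_array_equal(r1[ch].data, r2[ch].data)
        np.testing.assert_array_equal(s1[ch].data, s2[ch].data)
    np.testing.assert_array_equal(t1.field_true.vectors, t2.field_true.vectors)
    np.testing.assert_array_equal(t1.cell_mask.data, t2.cell_mask.data)


def test_field_peaks_at_cell_surface_and_warp_is_self_consistent():
    params = SceneParams(
        **SMALL, displacement_amplitude_um=2.0, displacement_decay_um=20.0,
        noise=(0.0, 0.0), seed=5,
    )
    relaxed, stressed, truth = generate_scene(params)
    mag = truth.field_true.magnitude()
    assert mag.max() == pytest.approx(2.0, abs=0.05)
    # the maximum sits at the cell surface (distance 0 from the mask)
    rewarped = warp_stack(relaxed["fiber"], truth.field_true)
    np.testing.assert_allclose(rewarped.data, stressed["fiber"].data)


def test_field_true_gradient_is_bounded():
    params = SceneParams(**SMALL, displacement_amplitude_um=2.0, seed=5)
    _, _, truth = generate_scene(params)
    for ax in range(3):
        step = np.abs(np.diff(truth.field_true.vectors, axis=ax))
        assert step.max() < 1.0  # µm per voxel: smooth by construction


def test_densified_volume_truth_is_exact_voxel_count():
    params = SceneParams(**SMALL, seed=2)
    _, _, truth = generate_scene(params)
    count = int(truth.densified_mask.data.sum())
    assert truth.densified_volume_um3 == pytest.approx(
        count * np.prod(params.voxel_size_um), rel=0, abs=1e-9
    )


def test_drift_is_a_circular_shift_of_the_stressed_stack():
    base = SceneParams(**SMALL, displacement_amplitude_um=0.0, noise=(0.0, 0.0), seed=9)
    shifted = SceneParams(
        **SMALL, displacement_amplitude_um=0.0, noise=(0.0, 0.0), seed=9,
        drift_shift_vox=(2, -3, 1),
    )
    _, s0, _ = generate_scene(base)
    _, s1, truth = generate_scene(shifted)
    assert truth.applied_shift_vox == (2, -3, 1)
    np.testing.assert_array_equal(
        np.roll(s0["fiber"].data, (2, -3, 1), axis=(0, 1, 2)), s1["fiber"].data
    )


def test_protrusion_escaping_grid_raises_naming_it():
    params = dict(SMALL, protrusion_length_um=60.0)
    with pytest.raises(ValueError, match="protrusion"):
        generate_scene(SceneParams(**params, seed=1))


@pytest.mark.parametrize("bad", [
    dict(densification_shell_um=(5.0, 3.0)),
    dict(densification_factor=0.5),
    dict(cell_radius_um=-1.0),
    dict(displacement_decay_um=0.0),
])
def test_invalid_scene_params_rejected(bad):
    with pytest.raises(ValueError):
        SceneParams(**dict(SMALL, **bad))


# ---------------------------------------------------------------------------
# rheology trace generators


def test_creep_trace_fully_reversible_ends_at_zero():
    trace, truth = generate_creep_trace(
        plastic_fraction=0.0, recovery_duration_s=7200.0, relax_time_s=100.0,
        noise_sd=0.0,
    )
    assert truth.plastic_fraction_true == 0.0
    assert abs(trace.strain[-1]) < 1e-6


def test_creep_trace_fully_plastic_recovery_is_flat():
    trace, _ = generate_creep_trace(plastic_fraction=1.0, noise_sd=0.0)
    rec = trace.strain[trace.recovery]
    np.testing.assert_allclose(rec, rec[0])


def test_creep_trace_residual_ratio_matches_construction():
    trace, _ = generate_creep_trace(
        plastic_fraction=0.75, noise_sd=0.0, recovery_duration_s=7200.0,
        relax_time_s=60.0,
    )
    eps_end = trace.strain[trace.creep][-1]
    assert trace.strain[-1] / eps_end == pytest.approx(0.75, abs=1e-6)


def test_modulus_trace_flat_when_no_stiffening():
    trace, _ = generate_modulus_trace(stiffening_ratio=1.0, noise_sd=0.0)
    np.testing.assert_allclose(trace.G_prime_Pa, trace.G_prime_Pa[0])


def test_modulus_trace_plateau_and_post_levels():
    trace, truth = generate_modulus_trace(
        G_baseline_Pa=45.0, stiffening_ratio=3.0, irreversible_fraction=0.5,
        noise_sd=0.0, rise_tau_h=1.0,
    )
    pre = trace.G_prime_Pa[(trace.time_h > 22.0) & (trace.time_h < 24.0)]
    post = trace.G_prime_Pa[trace.time_h > 27.0]
    assert pre.max() == pytest.approx(135.0, rel=1e-3)
    assert post[-1] == pytest.approx(90.0, rel=1e-3)
    assert truth.reversible_stiffening_Pa == pytest.approx(45.0)
    assert truth.irreversible_stiffening_Pa == pytest.approx(45.0)


def test_modulus_trace_seeded_noise_is_deterministic():
    t1, _ = generate_modulus_trace(noise_sd=2.0, seed=11)
    t2, _ = generate_modulus_trace(noise_sd=2.0, seed=11)
    np.testing.assert_array_equal(t1.G_prime_Pa, t2.G_prime_Pa)


def test_modulus_trace_cytod_outside_span_rejected():
    with pytest.raises(ValueError, match="outside"):
        generate_modulus_trace(cytod_time_h=30.0, duration_h=24.0)


def test_relaxation_series_truth_and_bounds():
    t, v, truth = generate_relaxation_series(retained_fraction=0.4, seed=1)
    assert truth.plastic_fraction_true == 0.4
    assert v[0] > v[-1] > 0
    with pytest.raises(ValueError):
        generate_relaxation_series(retained_fraction=1.5)


def test_rheo_truth_validates_range():
    with pytest.raises(ValueError):
        RheoTruth(plastic_fraction_true=1.2)
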