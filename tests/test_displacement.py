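"""FFD registration, displacement maxima, and decay profiling."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from fibremech.core import BinaryMask, DisplacementField, ImageStack
from fibremech.displacement import (
    RegistrationError,
    decay_profile,
    max_displacement,
    register_ffd,
)
from fibremech.synth import SceneParams, generate_scene

from conftest import make_ball_mask

LIGHT = dict(iterations=120, n_samples=8000)  # small-volume test settings


def brute_force_profile(field, cell_mask, bin_width=5.0, max_dist=150.0):
    """Naive per-voxel loop over distances and bins (the oracle)."""
    dist = ndi.distance_transform_edt(~cell_mask.data, sampling=cell_mask.voxel_size_um)
    mags = field.magnitude()
    edges = list(np.arange(0.0, max_dist + 1e-9, bin_width))
    if edges[-1] < max_dist - 1e-9:
        edges.append(max_dist)
    nbins = len(edges) - 1
    per_bin = [[] for _ in range(nbins)]
    for idx in np.ndindex(field.shape):
        if cell_mask.data[idx] or not field.valid_mask[idx]:
            continue
        d = dist[idx]
        if d >= max_dist:
            continue
        per_bin[min(int(d // bin_width), nbins - 1)].append(mags[idx])
    means = np.array([np.mean(b) if b else np.nan for b in per_bin])
    sds = np.array([np.std(b) if b else np.nan for b in per_bin])
    counts = np.array([len(b) for b in per_bin])
    return np.array(edges), means, sds, counts


class TestDecayProfile:
    def test_uniform_field_means_one_sd_zero(self, ball64):
        vec = np.zeros(ball64.shape + (3,))
        vec[..., 0] = 1.0
        field = DisplacementField(vec, voxel_size_um=ball64.voxel_size_um)
        prof = decay_profile(field, ball64)
        filled = prof.n_voxels > 0
        np.testing.assert_allclose(prof.mean_mag_um[filled], 1.0)
        np.testing.assert_allclose(prof.sd_um[filled], 0.0, atol=1e-12)

    def test_matches_brute_force_loop_exactly(self, ball64):
        rng = np.random.default_rng(6)
        vec = rng.normal(0, 0.5, ball64.shape + (3,))
        field = DisplacementField(vec, voxel_size_um=ball64.voxel_size_um)
        prof = decay_profile(field, ball64)
        edges, means, sds, counts = brute_force_profile(field, ball64)
        np.testing.assert_array_equal(prof.bin_edges_um, edges)
        np.testing.assert_array_equal(prof.n_voxels, counts)
        np.testing.assert_allclose(prof.mean_mag_um, means, atol=1e-12)
        np.testing.assert_allclose(prof.sd_um, sds, atol=1e-9)

    def test_count_conservation(self, ball64):
        vec = np.ones(ball64.shape + (3,))
        field = DisplacementField(vec, voxel_size_um=ball64.voxel_size_um)
        prof = decay_profile(field, ball64)
        dist = ndi.distance_transform_edt(~ball64.data, sampling=ball64.voxel_size_um)
        expected = int((~ball64.data & (dist < 150.0)).sum())
        assert int(prof.n_voxels.sum()) == expected

    def test_no_bin_starts_at_or_beyond_the_cap(self, ball64):
        vec = np.ones(ball64.shape + (3,))
        field = DisplacementField(vec, voxel_size_um=ball64.voxel_size_um)
        prof = decay_profile(field, ball64, max_dist_um=150.0)
        assert prof.bin_edges_um[:-1].max() < 150.0

    def test_empty_cell_mask_rejected(self, ball64):
        field = DisplacementField(np.zeros(ball64.shape + (3,)),
                                  voxel_size_um=ball64.voxel_size_um)
        with pytest.raises(ValueError, match="empty cell mask"):
            decay_profile(field, ball64.with_data(np.zeros(ball64.shape, bool)))


class TestMaxDisplacement:
    def test_constant_magnitude_field(self):
        vec = np.zeros((8, 8, 8, 3))
        vec[..., 1] = 3.0
        field = DisplacementField(vec, voxel_size_um=(1.0, 1.0, 1.0))
        assert max_displacement(field) == pytest.approx(3.0)

    def test_median_of_three_magnitudes(self):
        vec = np.zeros((1, 1, 3, 3))
        vec[0, 0, :, 0] = [1.0, 2.0, 3.0]
        field = DisplacementField(vec, voxel_size_um=(1.0, 1.0, 1.0))
        assert max_displacement(field, percentile=50) == pytest.approx(2.0)

    def test_empty_valid_mask_rejected(self):
        field = DisplacementField(
            np.zeros((4, 4, 4, 3)), voxel_size_um=(1.0, 1.0, 1.0),
            valid_mask=np.zeros((4, 4, 4), bool),
        )
        with pytest.raises(ValueError):
            max_displacement(field)


class TestRegisterFFD:
    @pytest.fixture(scope="class")
    def scene48(self):
        params = SceneParams(
            grid_shape=(48, 48, 48), cell_radius_um=5.0, n_protrusions=0,
            n_fibers=120, displacement_amplitude_um=2 * 0.57,
            displacement_decay_um=20.0, noise=(0.0, 0.0), seed=11,
        )
        return generate_scene(params)

    def test_identity_registration_is_exactly_zero(self, scene48):
        relaxed, _, _ = scene48
        field = register_ffd(relaxed["fiber"], relaxed["fiber"], seed=1, **LIGHT)
        assert field.magnitude()[field.valid_mask].max() <= 0.05

    def test_known_radial_field_recovered(self, scene48):
        relaxed, stressed, truth = scene48
        field = register_ffd(stressed["fiber"], relaxed["fiber"], seed=1, **LIGHT)
        err = field.vectors - truth.field_true.vectors
        rmse_vox = np.sqrt((err[field.valid_mask] ** 2).sum(-1).mean()) / 0.57
        assert rmse_vox < 0.5

    def test_uniform_translation_recovered(self):
        from scipy.ndimage import gaussian_filter, shift as nd_shift

        rng = np.random.default_rng(13)
        base = gaussian_filter(rng.random((48, 48, 48)), 1.2)
        relaxed = ImageStack(base, (1.0, 1.0, 1.0), "fiber")
        # the matrix moved +1.5 voxels along x between relaxed and stressed
        stressed = relaxed.with_data(
            nd_shift(base, (0, 0, 1.5), order=1, mode="reflect")
        )
        field = register_ffd(stressed, relaxed, seed=2, **LIGHT)
        mean_vec = field.vectors[field.valid_mask].mean(axis=0)
        np.testing.assert_allclose(mean_vec, [1.5, 0.0, 0.0], atol=0.2)

    def test_content_free_images_rejected(self):
        flat = ImageStack(np.full((32, 32, 32), 4.0), (1.0, 1.0, 1.0))
        with pytest.raises(RegistrationError, match="correlation"):
            register_ffd(flat, flat)

    def test_same_seed_is_bit_identical(self, scene48):
        relaxed, stressed, _ = scene48
        f1 = register_ffd(stressed["fiber"], relaxed["fiber"], seed=3,
                          iterations=30, n_samples=4000)
        f2 = register_ffd(stressed["fiber"], relaxed["fiber"], seed=3,
                          iterations=30, n_samples=4000)
        np.testing.assert_array_equal(f1.vectors, f2.vectors)
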