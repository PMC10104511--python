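"""Inscribed sphere, protrusion census, principal-axis length, sphericity."""

import numpy as np
import pytest

from fibremech.core import BinaryMask
from fibremech.morphology import (
    cell_metrics,
    detect_protrusions,
    inscribed_sphere,
    protrusion_length,
)

from conftest import make_ball_mask, make_capsule


class TestInscribedSphere:
    def test_digital_ball_center_and_radius(self, ball64):
        center, R = inscribed_sphere(ball64)
        assert center == (32, 32, 32)
        assert R == pytest.approx(10.0, abs=0.5)

    def test_single_voxel_pins_the_degenerate_convention(self):
        data = np.zeros((9, 9, 9), dtype=bool)
        data[4, 4, 4] = True
        mask = BinaryMask(data, (1.0, 1.0, 1.0))
        center, R = inscribed_sphere(mask)
        assert center == (4, 4, 4)
        assert R == pytest.approx(1.0)  # distance to the nearest background voxel

    def test_ellipsoid_inscribed_radius_is_smallest_semi_axis(self):
        zz, yy, xx = np.meshgrid(*[np.arange(n) for n in (64, 48, 48)], indexing="ij")
        ell = ((zz - 32) / 20.0) ** 2 + ((yy - 24) / 10.0) ** 2 + ((xx - 24) / 10.0) ** 2 <= 1
        _, R = inscribed_sphere(BinaryMask(ell, (1.0, 1.0, 1.0)))
        assert R == pytest.approx(10.0, abs=0.5)

    def test_radius_bounded_by_half_caliper_width(self, ball64):
        _, R = inscribed_sphere(ball64)
        extent = np.ptp(np.argwhere(ball64.data), axis=0).min() + 1
        assert R <= extent / 2 + 0.5

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            inscribed_sphere(BinaryMask(np.zeros((8, 8, 8), bool), (1.0, 1.0, 1.0)))


class TestDetectProtrusions:
    def test_bare_ball_has_none(self, ball64):
        center, R = inscribed_sphere(ball64)
        assert detect_protrusions(ball64, center, R) == []

    def test_three_orthogonal_capsules_detected(self):
        mask = make_ball_mask(8.0, (96, 96, 96), (48, 48, 48))
        c = np.array([48.0, 48.0, 48.0])
        for d in ([1, 0, 0], [0, 1, 0], [0, 0, 1]):
            mask = make_capsule(mask, c + 8.0 * np.asarray(d, float) - 2.0 * np.asarray(d, float),
                                d, 40.0, 2.0)
        center, R = inscribed_sphere(mask)
        prot = detect_protrusions(mask, center, R)
        assert len(prot) == 3

    def test_capsule_short_of_2R_is_not_a_protrusion(self):
        mask = make_ball_mask(8.0, (64, 64, 64), (32, 32, 32))
        # reaches only 1.5R from the center
        mask = make_capsule(mask, [32.0, 32.0, 38.0], [0, 0, 1], 4.0, 2.0)
        center, R = inscribed_sphere(mask)
        assert detect_protrusions(mask, center, R) == []

    @pytest.mark.parametrize("transform", [
        lambda m: np.rot90(m, axes=(0, 1)),
        lambda m: np.rot90(m, axes=(1, 2)),
        lambda m: m[::-1],
        lambda m: m[:, :, ::-1],
    ])
    def test_count_invariant_under_grid_symmetries(self, transform):
        mask = make_ball_mask(8.0, (96, 96, 96), (48, 48, 48))
        c = np.array([48.0, 48.0, 48.0])
        for d in ([1, 0, 0], [0, 1, 1], [0, 0, -1]):
            dn = np.asarray(d, float) / np.linalg.norm(d)
            mask = make_capsule(mask, c + 6.0 * dn, dn, 40.0, 2.0)
        sym = mask.with_data(np.ascontiguousarray(transform(mask.data)))
        for m in (mask, sym):
            center, R = inscribed_sphere(m)
            assert len(detect_protrusions(m, center, R)) == 3


class TestProtrusionLength:
    def _cylinder(self, length, radius, axis=2, shape=(64, 64, 64)):
        mask = BinaryMask(np.zeros(shape, bool), (1.0, 1.0, 1.0))
        start = np.array([32.0, 32.0, 32.0])
        start[axis] -= length / 2
        d = np.zeros(3)
        d[axis] = 1.0
        return make_capsule(mask, start, d, length, radius).with_data(
            make_capsule(mask, start, d, length, radius).data
        )

    def test_axis_aligned_cylinder_matches_equivalent_ellipsoid_value(self):
        # uniform solid cylinder of length L: coordinate variance along the
        # axis is L²/12, so the equivalent-ellipsoid convention 2·sqrt(5λ)
        # gives L·sqrt(5/3) ≈ 1.291·L (from the covariance integral); a
        # discrete cylinder of n voxel planes has axial variance (n²−1)/12
        data = np.zeros((64, 64, 64), bool)
        zz, yy, xx = np.meshgrid(*[np.arange(64)] * 3, indexing="ij")
        data[(np.abs(zz - 32) <= 15) & ((yy - 32) ** 2 + (xx - 32) ** 2 <= 4.0)] = True
        cyl = BinaryMask(data, (1.0, 1.0, 1.0))
        n = 31
        expected_discrete = 2.0 * np.sqrt(5.0 * (n**2 - 1) / 12.0)
        assert protrusion_length(cyl) == pytest.approx(expected_discrete, rel=0.02)
        assert protrusion_length(cyl) == pytest.approx(30.0 * np.sqrt(5.0 / 3.0), rel=0.05)

    def test_rotation_by_90_degrees_preserves_length(self):
        a = self._cylinder(30.0, 2.0, axis=2)
        b = self._cylinder(30.0, 2.0, axis=1)
        assert protrusion_length(a) == pytest.approx(protrusion_length(b), rel=1e-6)

    def test_lengths_are_ordered_with_cylinder_lengths(self):
        long = self._cylinder(30.0, 2.0)
        short = self._cylinder(15.0, 2.0)
        assert protrusion_length(long) > protrusion_length(short)

    def test_single_voxel_returns_one_voxel_extent(self):
        data = np.zeros((8, 8, 8), bool)
        data[3, 3, 3] = True
        assert protrusion_length(BinaryMask(data, (1.0, 1.0, 1.0))) == pytest.approx(1.0)


class TestCellMetrics:
    def test_ball_sphericity_is_100_within_digitisation(self, ball64):
        m = cell_metrics(ball64)
        assert m.sphericity_pct == pytest.approx(100.0, abs=2.0)
        assert m.protrusion_count == 0

    def test_protrusions_lower_sphericity_towards_hull_oracle(self):
        from skimage.morphology import convex_hull_image

        mask = make_ball_mask(8.0, (64, 64, 64), (32, 32, 32))
        c = np.array([32.0, 32.0, 32.0])
        for d in ([1, 0, 0], [0, 1, 0], [0, 0, 1]):
            mask = make_capsule(mask, c + 6.0 * np.asarray(d, float), d, 22.0, 1.5)
        bare = cell_metrics(make_ball_mask(8.0, (64, 64, 64), (32, 32, 32)))
        spiky = cell_metrics(mask)
        assert spiky.sphericity_pct < bare.sphericity_pct
        oracle = 100.0 * mask.data.sum() / convex_hull_image(
            mask.data, offset_coordinates=False
        ).sum()
        assert spiky.sphericity_pct == pytest.approx(oracle, rel=1e-9)

    def test_ball_volume_at_confocal_voxel_size(self):
        # 20 µm diameter ball sampled at 0.57 µm voxels
        vs = (0.57, 0.57, 0.57)
        shape = (48, 48, 48)
        zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        r2 = sum(((g - 23.5) * v) ** 2 for g, v in zip((zz, yy, xx), vs))
        mask = BinaryMask(r2 <= 10.0**2, vs)
        m = cell_metrics(mask)
        assert m.volume_um3 == pytest.approx(4.0 / 3.0 * np.pi * 1000.0, rel=0.05)

    def test_protrusion_count_matches_length_list(self):
        mask = make_ball_mask(8.0, (96, 96, 96), (48, 48, 48))
        c = np.array([48.0, 48.0, 48.0])
        for d in ([1, 0, 0], [0, 1, 0]):
            mask = make_capsule(mask, c + 6.0 * np.asarray(d, float), d, 40.0, 2.0)
        m = cell_metrics(mask)
        assert m.protrusion_count == 2 == len(m.protrusion_lengths_um)
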