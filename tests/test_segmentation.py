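"""Cell/nuclei/polymer segmentation and watershed cell splitting."""

import numpy as np
import pytest

from fibremech.core import ImageStack
from fibremech.segmentation import (
    frame_band,
    segment_cell,
    segment_polymer,
    split_clumped_cells,
)

from conftest import make_ball_mask


def _brute_force_percentile(sample: np.ndarray, q: float) -> float:
    """Quantile by explicit linear interpolation between order statistics."""
    s = np.sort(sample.ravel())
    pos = (len(s) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(s[lo] * (1 - frac) + s[hi] * frac)


@pytest.fixture
def bimodal_ball():
    """Background N(10, 1) with a ball at intensity 100, 1 µm voxels."""
    rng = np.random.default_rng(4)
    ball = make_ball_mask(10.0, (64, 64, 64), (32, 32, 32))
    data = rng.normal(10, 1, ball.shape)
    data[ball.data] = 100.0
    return ImageStack(data, (1.0, 1.0, 1.0), "cell"), ball


class TestSegmentCell:
    def test_ball_volume_recovered_within_5pct(self, bimodal_ball):
        stack, ball = bimodal_ball
        mask = segment_cell(stack, min_object_um3=50.0)
        analytic = 4.0 / 3.0 * np.pi * 10.0**3
        assert mask.volume_um3 == pytest.approx(analytic, rel=0.05)

    def test_affine_intensity_rescaling_leaves_mask_unchanged(self, bimodal_ball):
        stack, _ = bimodal_ball
        m1 = segment_cell(stack)
        m2 = segment_cell(stack.with_data(2.0 * stack.data + 5.0))
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_min_object_above_everything_raises(self, bimodal_ball):
        stack, _ = bimodal_ball
        with pytest.raises(ValueError, match="no cell found"):
            segment_cell(stack, min_object_um3=1e7)

    def test_speck_removed_leaving_one_component(self, bimodal_ball):
        stack, _ = bimodal_ball
        data = stack.data.copy()
        data[2, 2, 2:5] = 100.0  # 3-voxel speck
        mask = segment_cell(stack.with_data(data), min_object_um3=10.0)
        from scipy import ndimage as ndi

        _, n = ndi.label(mask.data, structure=np.ones((3, 3, 3), bool))
        assert n == 1


class TestSegmentPolymer:
    def test_uniform_stack_yields_empty_mask(self):
        stack = ImageStack(np.full((32, 32, 32), 5.0), (1.0, 1.0, 1.0))
        mask = segment_polymer(stack, min_object_um3=0.0)
        assert not mask.data.any()

    def test_flat_frame_threshold_selects_blob_exactly(self):
        data = np.full((32, 40, 40), 10.0)
        blob = np.zeros_like(data, dtype=bool)
        blob[12:20, 16:24, 16:24] = True
        data[blob] = 100.0
        stack = ImageStack(data, (1.0, 1.0, 1.0))
        mask = segment_polymer(stack, min_object_um3=0.0, fill_holes=False)
        np.testing.assert_array_equal(mask.data, blob)

    def test_threshold_matches_brute_force_frame_percentile(self):
        rng = np.random.default_rng(3)
        data = np.full((32, 40, 40), 10.0)
        band = frame_band(data.shape, 0.10)
        data[band] = rng.normal(10, 1, int(band.sum()))
        blob = np.zeros_like(data, dtype=bool)
        blob[10:20, 18:26, 18:26] = True
        data[blob] = 100.0
        stack = ImageStack(data, (1.0, 1.0, 1.0))
        thr = _brute_force_percentile(data[band], 99.0)
        assert np.percentile(data[band], 99.0) == pytest.approx(thr, abs=1e-12)
        assert thr > 10.0  # interior background sits below the frame quantile
        mask = segment_polymer(stack, min_object_um3=10.0, fill_holes=False)
        np.testing.assert_array_equal(mask.data, blob)

    def test_lowering_percentile_never_shrinks_mask(self):
        rng = np.random.default_rng(5)
        data = rng.normal(10, 2, (24, 32, 32))
        data[8:16, 12:20, 12:20] += 50.0
        stack = ImageStack(data, (1.0, 1.0, 1.0))
        prev = None
        for pct in (99.0, 90.0, 75.0, 50.0):
            m = segment_polymer(stack, percentile=pct, min_object_um3=0.0, fill_holes=False)
            if prev is not None:
                assert np.all(prev.data <= m.data)
            prev = m

    def test_bad_frame_fraction_rejected(self):
        stack = ImageStack(np.zeros((8, 8, 8)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            segment_polymer(stack, frame_fraction=0.6)


class TestSplitClumpedCells:
    def test_fused_balls_split_into_disjoint_seeded_masks(self, fused_balls):
        cell_mask, nuclei, c1, c2 = fused_balls
        parts = split_clumped_cells(cell_mask, nuclei)
        assert len(parts) == 2
        overlap = parts[0].data & parts[1].data
        assert not overlap.any()
        seeds = [c1, c2]
        containment = [
            [p.data[c] for c in seeds].count(True) for p in parts
        ]
        assert containment == [1, 1]

    def test_split_preserves_the_union_voxel_count(self, fused_balls):
        cell_mask, nuclei, _, _ = fused_balls
        parts = split_clumped_cells(cell_mask, nuclei)
        assert sum(int(p.data.sum()) for p in parts) == int(cell_mask.data.sum())

    def test_single_nucleus_returns_input_unchanged(self):
        ball = make_ball_mask(8.0, (32, 32, 32), (16, 16, 16))
        nuc = np.zeros(ball.shape)
        nuc[14:19, 14:19, 14:19] = 100.0
        nuc += np.random.default_rng(1).normal(0, 0.5, ball.shape)
        parts = split_clumped_cells(ball, ImageStack(nuc, (1.0, 1.0, 1.0)))
        assert len(parts) == 1
        np.testing.assert_array_equal(parts[0].data, ball.data)

    def test_no_nuclei_raises(self):
        ball = make_ball_mask(8.0, (32, 32, 32), (16, 16, 16))
        # only two isolated bright voxels: everything above the Otsu
        # threshold is below the minimum nucleus volume
        nuc = np.zeros(ball.shape)
        nuc[4, 4, 4] = 100.0
        nuc[20, 25, 9] = 100.0
        with pytest.raises(ValueError, match="no nuclei"):
            split_clumped_cells(ball, ImageStack(nuc, (1.0, 1.0, 1.0)))
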