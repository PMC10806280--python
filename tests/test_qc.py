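"""Segmentation error-checking rules and OK/Small/Empty classification."""

import numpy as np
import pytest

from conftest import random_mask
from marrowseg.qc import (
    QcStatus,
    RegionStats,
    check_com_outlier,
    classify_output,
    component_count,
    compute_region_stats,
    join_discontinuous_voi,
    remove_single_voxel_components,
    run_qc,
)
from marrowseg.volumes import LabelMask, RegionLabel


def oracle_components(data):
    """Independent 26-connectivity component labelling via BFS."""
    data = np.asarray(data, dtype=bool)
    seen = np.zeros_like(data)
    comps = []
    for start in map(tuple, np.argwhere(data)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            z, y, x = v
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        n = (z + dz, y + dy, x + dx)
                        if all(0 <= n[a] < data.shape[a] for a in range(3)):
                            if data[n] and not seen[n]:
                                seen[n] = True
                                stack.append(n)
        comps.append(comp)
    return comps


def oracle_fill(data):
    """Independent hole filling: 6-connected flood fill from the border."""
    data = np.asarray(data, dtype=bool)
    padded = np.pad(data, 1)
    outside = np.zeros_like(padded)
    stack = [(0, 0, 0)]
    outside[0, 0, 0] = True
    while stack:
        z, y, x = stack.pop()
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            n = (z + dz, y + dy, x + dx)
            if all(0 <= n[a] < padded.shape[a] for a in range(3)):
                if not padded[n] and not outside[n]:
                    outside[n] = True
                    stack.append(n)
    return ~outside[1:-1, 1:-1, 1:-1]


def _stats(mean_vol=100.0, sd_vol=10.0, mean_com=(5.0, 5.0, 5.0), sd_com=(1.0, 1.0, 1.0)):
    return RegionStats(
        region=RegionLabel.SPINE,
        mean_volume=mean_vol,
        sd_volume=sd_vol,
        mean_com=mean_com,
        sd_com=sd_com,
    )


class TestSingleVoxelRemoval:
    def test_isolated_voxel_removed_bar_kept(self):
        data = np.zeros((5, 5, 5))
        data[0, 0, 0] = 1  # isolated voxel
        data[2, 2, 1:4] = 1  # 3-voxel bar
        out = remove_single_voxel_components(LabelMask(data))
        assert out.voxel_count == 3
        assert out.data[2, 2, 1:4].all()

    def test_empty_and_solid_block_untouched(self):
        assert remove_single_voxel_components(LabelMask(np.zeros((3, 3, 3)))).voxel_count == 0
        block = np.zeros((4, 4, 4))
        block[1:3, 1:3, 1:3] = 1
        out = remove_single_voxel_components(LabelMask(block))
        assert np.array_equal(out.data, block)

    def test_diagonal_pair_counts_as_one_component(self):
        data = np.zeros((3, 3, 3))
        data[0, 0, 0] = 1
        data[1, 1, 1] = 1  # 26-connected to the first voxel
        out = remove_single_voxel_components(LabelMask(data))
        assert out.voxel_count == 2

    def test_idempotent_subset_and_oracle_agreement(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            m = random_mask(r, (5, 5, 5), p=0.2)
            out = remove_single_voxel_components(m)
            expected = np.zeros(m.shape, dtype=bool)
            for comp in oracle_components(m.data):
                if len(comp) >= 2:
                    for v in comp:
                        expected[v] = True
            assert np.array_equal(out.data.astype(bool), expected)
            again = remove_single_voxel_components(out)
            assert np.array_equal(again.data, out.data)
            assert not np.any(out.data > m.data)  # output is a subset


class TestJoinDiscontinuous:
    def test_hollow_shell_filled_solid(self):
        shell = np.zeros((6, 6, 6))
        shell[1:5, 1:5, 1:5] = 1
        shell[2:4, 2:4, 2:4] = 0  # internal cavity
        out = join_discontinuous_voi(LabelMask(shell))
        assert out.data[2:4, 2:4, 2:4].all()
        assert out.voxel_count == 4**3

    def test_already_solid_idempotent(self):
        solid = np.zeros((5, 5, 5))
        solid[1:4, 1:4, 1:4] = 1
        out = join_discontinuous_voi(LabelMask(solid))
        assert np.array_equal(out.data, solid)

    def test_two_separated_blocks_retained(self):
        data = np.zeros((8, 4, 4))
        data[1:3, 1:3, 1:3] = 1
        data[5:7, 1:3, 1:3] = 1
        out = join_discontinuous_voi(LabelMask(data))
        assert np.array_equal(out.data, data)
        assert component_count(out) == 2

    def test_superset_and_oracle_agreement(self):
        for seed in range(100):
            r = np.random.default_rng(seed + 1000)
            m = random_mask(r, (6, 6, 6), p=0.4)
            out = join_discontinuous_voi(m)
            assert not np.any(out.data < m.data)  # output is a superset
            assert np.array_equal(out.data.astype(bool), oracle_fill(m.data))
            assert np.array_equal(join_discontinuous_voi(out).data, out.data)


class TestComOutlier:
    def _mask_at(self, com):
        data = np.zeros((12, 12, 12))
        data[com] = 1
        return LabelMask(data)

    def test_com_at_mean_not_outlier(self):
        assert not check_com_outlier(self._mask_at((5, 5, 5)), _stats())

    def test_four_sd_on_one_axis_is_outlier(self):
        assert check_com_outlier(self._mask_at((9, 5, 5)), _stats())

    def test_exactly_three_sd_is_not_outlier(self):
        # strict '>' means a displacement of exactly 3 SD does not trigger
        assert not check_com_outlier(self._mask_at((8, 5, 5)), _stats())

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            check_com_outlier(LabelMask(np.zeros((4, 4, 4))), _stats())


class TestClassification:
    def _mask_with_volume(self, n):
        data = np.zeros((12, 12, 12))
        data.ravel()[:n] = 1
        return LabelMask(data)

    def test_volume_at_mean_is_ok(self):
        res = classify_output(self._mask_with_volume(100), _stats())
        assert res.status is QcStatus.OK

    def test_three_sd_below_mean_is_small(self):
        res = classify_output(self._mask_with_volume(70), _stats())
        assert res.status is QcStatus.SMALL
        assert res.volume == 70

    def test_exactly_at_threshold_is_ok(self):
        # threshold is mean - 2.5 SD = 75; 'Small' requires volume strictly below
        res = classify_output(self._mask_with_volume(75), _stats())
        assert res.status is QcStatus.OK

    def test_empty_mask(self):
        res = classify_output(LabelMask(np.zeros((4, 4, 4))), _stats())
        assert res.status is QcStatus.EMPTY
        assert res.volume == 0 and res.com_outlier is None

    def test_statuses_partition_random_masks(self):
        stats = _stats(mean_vol=20.0, sd_vol=4.0)
        for seed in range(50):
            r = np.random.default_rng(seed)
            m = random_mask(r, (6, 6, 6), p=r.uniform(0, 0.3))
            res = classify_output(m, stats)
            expected = (
                QcStatus.EMPTY
                if m.voxel_count == 0
                else (QcStatus.SMALL if m.voxel_count < 10.0 else QcStatus.OK)
            )
            assert res.status is expected


class TestRegionStats:
    def _mask_with_volume(self, n, shape=(12, 12, 12)):
        data = np.zeros(shape)
        data.ravel()[:n] = 1
        return LabelMask(data)

    def test_hand_arithmetic(self):
        stats = compute_region_stats(
            [self._mask_with_volume(100), self._mask_with_volume(102)], RegionLabel.SPINE
        )
        assert stats.mean_volume == pytest.approx(101.0)
        assert stats.sd_volume == pytest.approx(np.sqrt(2.0))

    def test_identical_masks_zero_sd(self):
        m = self._mask_with_volume(50)
        stats = compute_region_stats([m, m, m], RegionLabel.TOTAL_HIP)
        assert stats.sd_volume == 0.0
        assert all(s == pytest.approx(0.0, abs=1e-12) for s in stats.sd_com)

    def test_order_invariance(self, rng):
        masks = [random_mask(rng, (6, 6, 6), p=0.5) for _ in range(4)]
        a = compute_region_stats(masks, RegionLabel.SPINE)
        b = compute_region_stats(masks[::-1], RegionLabel.SPINE)
        assert a.mean_volume == b.mean_volume and a.sd_volume == b.sd_volume
        assert a.mean_com == pytest.approx(b.mean_com, abs=1e-12)
        assert a.sd_com == pytest.approx(b.sd_com, abs=1e-12)

    def test_fewer_than_two_masks_rejected(self):
        with pytest.raises(ValueError):
            compute_region_stats([self._mask_with_volume(5)], RegionLabel.SPINE)


def test_run_qc_cleans_then_classifies():
    data = np.zeros((8, 8, 8))
    data[2:6, 2:6, 2:6] = 1
    data[3:5, 3:5, 3:5] = 0  # cavity, filled by QC
    data[0, 0, 0] = 1  # stray voxel, removed by QC
    cleaned, result = run_qc(LabelMask(data), _stats(mean_vol=64.0, sd_vol=5.0))
    assert cleaned.voxel_count == 64
    assert result.status is QcStatus.OK
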