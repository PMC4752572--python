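"""Histogram threshold, clustering, and contralateral artery selection."""

from collections import deque

import numpy as np
import pytest

from autoidif import artery_segmentation as seg
from autoidif import phantom as ph
from autoidif.core_io import Volume3D


def flood_fill_count(binary):
    """Independent 26-connectivity component counter (BFS)."""
    visited = np.zeros_like(binary, dtype=bool)
    shape = binary.shape
    count = 0
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
               if (a, b, c) != (0, 0, 0)]
    for start in zip(*np.nonzero(binary)):
        if visited[start]:
            continue
        count += 1
        q = deque([start])
        visited[start] = True
        while q:
            i, j, k = q.popleft()
            for a, b, c in offsets:
                ni, nj, nk = i + a, j + b, k + c
                if (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]
                        and binary[ni, nj, nk] and not visited[ni, nj, nk]):
                    visited[ni, nj, nk] = True
                    q.append((ni, nj, nk))
    return count


class TestHistogramThreshold:
    def test_bimodal_volume_threshold_in_gap(self, rng):
        # ~10^4 background voxels near 0.01, 50 bright voxels near 0.9, max 1.0
        n = 10_000
        vals = np.abs(rng.normal(0.01, 0.003, size=n))
        bright = rng.normal(0.9, 0.02, size=50)
        data = np.concatenate([vals, bright, [1.0]])
        vol = Volume3D(data.reshape(-1, 1, 1), (1, 1, 1))
        thr = seg.histogram_threshold(vol)

        # independent oracle: scan all 100 smoothed bins for the first
        # interior local minimum
        counts, edges = np.histogram(vol.values, bins=100, range=(0, vol.values.max()))
        smoothed = np.convolve(counts.astype(float), np.ones(3) / 3, mode="same")
        expected = None
        for b in range(1, 99):
            if smoothed[b] <= smoothed[b - 1] and smoothed[b] <= smoothed[b + 1]:
                expected = edges[b]
                break
        assert thr == pytest.approx(expected)
        assert vals.max() < thr < bright.min()  # inside the empty gap
        assert (vol.values > thr).sum() == 51  # the bright voxels only

    def test_first_minimum_rule_on_constructed_counts(self):
        # raw counts [900, 120, 6, 0, 0, 4, 30]: first local minimum at bin 3
        counts = [900, 120, 6, 0, 0, 4, 30]
        vals = []
        bin_width = 0.01
        for b, c in enumerate(counts):
            vals.extend([(b + 0.5) * bin_width] * c)
        vals.append(1.0)  # sets the histogram range to [0, 1], bin width 0.01
        vol = Volume3D(np.asarray(vals).reshape(-1, 1, 1), (1, 1, 1))
        thr = seg.histogram_threshold(vol, smooth_width=1)
        assert thr == pytest.approx(3 * bin_width)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            seg.histogram_threshold(Volume3D(np.full((5, 5, 5), 2.0), (1, 1, 1)))

    def test_foreground_fraction_strictly_interior(self, segmented_subject):
        enhanced = segmented_subject["enhanced"]
        thr = segmented_subject["mask"].threshold
        frac = (enhanced.values > thr).mean()
        assert 0.0 < frac < 1.0


class TestConnectedClusters:
    def test_two_separated_blobs(self):
        vals = np.zeros((10, 10, 10))
        vals[1:3, 1:3, 1:3] = 1          # 8 voxels ... make 10 and 7
        vals[1, 3, 1] = vals[1, 3, 2] = 1  # -> 10 voxels
        vals[7:9, 7:9, 7] = 1            # 4 voxels
        vals[7, 7, 8] = vals[7, 8, 8] = vals[8, 7, 8] = 1  # -> 7 voxels
        clusters = seg.connected_clusters(Volume3D(vals, (1, 1, 1)))
        assert [c.size for c in clusters] == [10, 7]

    def test_single_voxel(self):
        vals = np.zeros((4, 4, 4))
        vals[2, 2, 2] = 1
        clusters = seg.connected_clusters(Volume3D(vals, (1, 1, 1)))
        assert len(clusters) == 1 and clusters[0].size == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            seg.connected_clusters(Volume3D(np.zeros((4, 4, 4)), (1, 1, 1)))

    def test_component_count_matches_flood_fill_oracle(self, rng):
        binary = rng.random((12, 12, 12)) > 0.7
        if not binary.any():
            binary[0, 0, 0] = True
        clusters = seg.connected_clusters(Volume3D(binary.astype(float), (1, 1, 1)))
        assert len(clusters) == flood_fill_count(binary)

    def test_cog_in_world_coordinates(self):
        vals = np.zeros((5, 5, 5))
        vals[1, 2, 3] = 1
        vol = Volume3D(vals, (0.5, 0.5, 0.7), (-1.0, -1.0, -1.4))
        (cluster,) = seg.connected_clusters(vol)
        np.testing.assert_allclose(cluster.cog, [-0.5, 0.0, 0.7])


class TestSelection:
    def _clusters(self, sizes):
        out = []
        for n, x in zip(sizes, np.linspace(-20, 20, len(sizes))):
            idx = np.array([[i, 0, 0] for i in range(n)])
            out.append(seg.VoxelCluster(idx, np.array([x, 0.0, 0.0])))
        return out

    def test_two_largest_kept(self):
        clusters = self._clusters([120, 115, 9, 3])
        a, b = seg.select_major_arteries(clusters)
        assert (a.size, b.size) == (120, 115)

    def test_exactly_two_identity(self):
        clusters = self._clusters([5, 4])
        assert seg.select_major_arteries(clusters) == (clusters[0], clusters[1])

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="two clusters"):
            seg.select_major_arteries(self._clusters([5]))

    def test_contralateral_geometry(self):
        # candidate COGs at x = -20 and +20 mm; PET COG pulled to +5 mm
        grid = Volume3D(np.zeros((41, 5, 5)), (1, 1, 1), (-20.0, -2.0, -2.0))
        a = seg.VoxelCluster(np.array([[0, 2, 2]]), np.array([-20.0, 0.0, 0.0]))
        b = seg.VoxelCluster(np.array([[40, 2, 2]]), np.array([20.0, 0.0, 0.0]))
        pet = Volume3D(np.zeros((41, 5, 5)), (1, 1, 1), (-20.0, -2.0, -2.0))
        pet.values[25, 2, 2] = 1.0  # intensity COG at x = +5
        mask = seg.select_contralateral((a, b), pet, grid)
        assert mask.provenance["selected_candidate"] == 0
        assert mask.mask.values[0, 2, 2] == 1.0

    def test_tie_break_to_larger_cluster(self, caplog):
        grid = Volume3D(np.zeros((41, 5, 5)), (1, 1, 1), (-20.0, -2.0, -2.0))
        a = seg.VoxelCluster(np.array([[0, 2, 2]]), np.array([-10.0, 0.0, 0.0]))
        b = seg.VoxelCluster(np.array([[40, 2, 2], [39, 2, 2]]),
                             np.array([10.0, 0.0, 0.0]))
        pet = Volume3D(np.zeros((41, 5, 5)), (1, 1, 1), (-20.0, -2.0, -2.0))
        pet.values[20, 2, 2] = 1.0  # PET COG exactly between the candidates
        mask = seg.select_contralateral((a, b), pet, grid)
        assert mask.provenance["selected_candidate"] == 1  # the larger one

    def test_scale_invariance_of_pet_cog(self):
        grid = Volume3D(np.zeros((41, 5, 5)), (1, 1, 1), (-20.0, -2.0, -2.0))
        a = seg.VoxelCluster(np.array([[0, 2, 2]]), np.array([-20.0, 0.0, 0.0]))
        b = seg.VoxelCluster(np.array([[40, 2, 2]]), np.array([20.0, 0.0, 0.0]))
        pet = Volume3D(np.zeros((41, 5, 5)), (1, 1, 1), (-20.0, -2.0, -2.0))
        pet.values[25, 2, 2] = 1.0
        m1 = seg.select_contralateral((a, b), pet, grid)
        m2 = seg.select_contralateral((a, b), pet.with_values(pet.values * 1e4), grid)
        assert m1.provenance["selected_candidate"] == m2.provenance["selected_candidate"]

    def test_catheter_side_avoided_across_noise_seeds(self, default_config):
        # the catheter's residual activity must pull the PET COG so that the
        # contralateral (catheter-free) artery is picked, robust to noise
        cfg = default_config
        for seed in range(10):
            mra, series, _, truth = ph.generate_subject(cfg, 100 + seed)
            grid = mra
            clusters = [
                seg.VoxelCluster(np.argwhere(m),
                                 np.asarray(grid.origin)
                                 + np.argwhere(m).mean(axis=0) * np.asarray(grid.spacing))
                for m in truth.mra_masks
            ]
            mask = seg.select_contralateral((clusters[0], clusters[1]),
                                            series.max_over_time(), grid)
            assert mask.provenance["selected_candidate"] == truth.selected_artery


class TestSegmentPipeline:
    def test_mask_covers_contralateral_tube(self, segmented_subject):
        truth = segmented_subject["truth"]
        mask = segmented_subject["mask"]
        tube = truth.mra_masks[truth.selected_artery]
        covered = (mask.mask.values > 0)[tube].mean()
        background = ~(truth.mra_masks[0] | truth.mra_masks[1])
        false_pos = (mask.mask.values > 0)[background].mean()
        assert covered > 0.90
        assert false_pos < 0.01

    def test_zero_volume_propagates_threshold_error(self, default_subject):
        zeros = Volume3D(np.zeros((8, 8, 8)), (1, 1, 1))
        with pytest.raises(ValueError):
            seg.segment_arteries(zeros, default_subject["series"].max_over_time())

    def test_determinism(self, segmented_subject):
        mask1 = segmented_subject["mask"]
        mask2 = seg.segment_arteries(segmented_subject["enhanced"],
                                     segmented_subject["pet_ref"])
        np.testing.assert_array_equal(mask1.mask.values, mask2.mask.values)
        assert mask1.threshold == mask2.threshold
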