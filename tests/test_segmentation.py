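import numpy as np
import pytest

from fddft import (
    BoundingBox,
    ImageGrid,
    SimilarityMask,
    aware_feature_map,
    count_edges,
    edge_threshold,
    filter_components,
    reconstruct_3d,
    select_candidates,
    split_image,
)
from fddft.segmentation import SegmentationResult


def _brute_force_edges(mask, connectivity):
    steps = [(0, 1), (1, 0)] + ([(1, 1), (1, -1)] if connectivity == 8 else [])
    pixels = set(zip(*np.nonzero(mask)))
    return sum((i + di, j + dj) in pixels for (i, j) in pixels for di, dj in steps)


def _brute_force_labels(mask, connectivity):
    """Flood-fill labeling, independent of scipy."""
    steps = [(0, 1), (0, -1), (1, 0), (-1, 0)]
    if connectivity == 8:
        steps += [(1, 1), (1, -1), (-1, 1), (-1, -1)]
    labels = np.zeros(mask.shape, int)
    nxt = 0
    for i, j in zip(*np.nonzero(mask)):
        if labels[i, j]:
            continue
        nxt += 1
        stack = [(i, j)]
        labels[i, j] = nxt
        while stack:
            a, b = stack.pop()
            for da, db in steps:
                x, y = a + da, b + db
                if 0 <= x < mask.shape[0] and 0 <= y < mask.shape[1]:
                    if mask[x, y] and not labels[x, y]:
                        labels[x, y] = nxt
                        stack.append((x, y))
    return labels, nxt


class TestEdgeCounting:
    def test_three_by_three_squares(self):
        block = np.ones((3, 3), bool)
        assert count_edges(block, 4) == 12
        assert count_edges(block, 8) == 20

    def test_single_pixel_has_no_edges(self):
        m = np.zeros((4, 4), bool)
        m[2, 2] = True
        assert count_edges(m, 8) == 0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_brute_force_pair_count(self, connectivity, rng):
        for _ in range(15):
            mask = rng.random((12, 12)) > 0.5
            assert count_edges(mask, connectivity) == _brute_force_edges(mask, connectivity)


class TestAwareFeatureMap:
    def test_two_separated_squares(self):
        L = np.zeros((12, 12))
        L[1:4, 1:4] = 1.0
        L[7:10, 7:10] = 1.0
        fmap = aware_feature_map(L, threshold=0.5, connectivity=4)
        assert len(fmap.components) == 2
        assert all(c.edge_count == 12 for c in fmap.components)
        assert all(c.voxel_count == 9 for c in fmap.components)

    def test_all_below_threshold_gives_empty_map(self):
        fmap = aware_feature_map(np.zeros((6, 6)), threshold=0.5)
        assert fmap.components == ()

    def test_single_pixel_component(self):
        L = np.zeros((5, 5))
        L[2, 3] = 2.0
        fmap = aware_feature_map(L, threshold=1.0)
        (c,) = fmap.components
        assert c.edge_count == 0 and c.voxel_count == 1
        assert c.bbox == BoundingBox(2, 2, 3, 3)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_labeling_matches_flood_fill(self, connectivity, rng):
        for _ in range(10):
            L = (rng.random((32, 32)) > 0.6).astype(float)
            fmap = aware_feature_map(L, threshold=0.5, connectivity=connectivity)
            ref_labels, n_ref = _brute_force_labels(L > 0, connectivity)
            assert len(fmap.components) == n_ref
            # identical partition (label ids may differ)
            for c in fmap.components:
                ids = np.unique(ref_labels[c.mask])
                assert len(ids) == 1 and ids[0] > 0

    def test_mean_energy_and_threshold_recorded(self):
        L = np.array([[0.0, 2.0], [4.0, 0.0]])
        fmap = aware_feature_map(L, threshold=1.5, connectivity=4)
        energies = sorted(c.mean_energy for c in fmap.components)
        assert energies == [2.0, 4.0]
        assert fmap.threshold == 1.5


class TestCandidateSelection:
    def _fmap(self, rng):
        L = (rng.random((20, 20)) > 0.7).astype(float)
        return aware_feature_map(L, 0.5, 8)

    def test_single_pixel_overlap_selects(self):
        L = np.zeros((8, 8))
        L[2:5, 2:5] = 1.0
        fmap = aware_feature_map(L, 0.5, 8)
        sim = np.zeros((8, 8), bool)
        sim[4, 4] = True
        out = select_candidates(fmap, SimilarityMask(sim, 1, "pedf"))
        assert len(out) == 1

    def test_disjoint_component_rejected(self):
        L = np.zeros((8, 8))
        L[2:5, 2:5] = 1.0
        sim = np.zeros((8, 8), bool)
        sim[7, 7] = True
        fmap = aware_feature_map(L, 0.5, 8)
        assert select_candidates(fmap, SimilarityMask(sim, 1, "pedf")) == []

    def test_matches_brute_force_intersection(self, rng):
        for _ in range(10):
            fmap = self._fmap(rng)
            sim = rng.random((20, 20)) > 0.8
            out = select_candidates(fmap, SimilarityMask(sim, 1, "hdf"))
            expected = [c for c in fmap.components if (c.mask & sim).any()]
            assert [c.label for c in out] == [c.label for c in expected]


class TestFilters:
    def test_printed_threshold_values(self):
        assert edge_threshold(10_000, "strict") == pytest.approx(3 * np.pi * 100 / 2)
        assert edge_threshold(10_000, "relaxed") == pytest.approx(np.pi * 100)

    def test_strict_floor_is_exclusive(self, rng):
        img = np.zeros((120, 120))
        img[:100, :100] = 1.0  # l0 = 10000, strict floor ~471.24
        fmap = aware_feature_map(img, 0.5, 8)
        (comp,) = fmap.components
        import dataclasses

        brain = BoundingBox(0, 119, 0, 119)
        at_floor = dataclasses.replace(comp, edge_count=471, bbox=BoundingBox(0, 10, 0, 10))
        above = dataclasses.replace(comp, edge_count=472, bbox=BoundingBox(0, 10, 0, 10))
        assert filter_components([at_floor], img, "strict", brain) == []
        assert filter_components([above], img, "strict", brain) == [above]

    def test_full_span_bbox_rejected(self):
        img = np.zeros((40, 40))
        img[2:38, 2:38] = 1.0
        fmap = aware_feature_map(img, 0.5, 8)
        (comp,) = fmap.components
        brain = BoundingBox(2, 37, 2, 37)
        assert filter_components([comp], img, "strict", brain) == []

    def test_strict_subset_of_relaxed(self, rng):
        import dataclasses

        img = np.ones((64, 64))
        brain = BoundingBox(0, 63, 0, 63)
        base = aware_feature_map(np.pad(np.ones((4, 4)), 2), 0.5, 8).components[0]
        cands = [
            dataclasses.replace(
                base, label=i, edge_count=int(e), bbox=BoundingBox(0, 9, 0, 9)
            )
            for i, e in enumerate(rng.integers(1, 800, size=40))
        ]
        strict = filter_components(cands, img, "strict", brain)
        relaxed = filter_components(cands, img, "relaxed", brain)
        assert {c.label for c in strict} <= {c.label for c in relaxed}

    def test_pixel_count_mode(self):
        import dataclasses

        img = np.ones((64, 64))  # l0 = 4096, strict floor = 3*pi*64/2 ~ 301.6
        brain = BoundingBox(0, 63, 0, 63)
        base = aware_feature_map(np.pad(np.ones((4, 4)), 2), 0.5, 8).components[0]
        comp = dataclasses.replace(base, edge_count=0, voxel_count=400, bbox=BoundingBox(0, 9, 0, 9))
        assert filter_components([comp], img, "strict", brain, count_mode="pixels") == [comp]
        assert filter_components([comp], img, "strict", brain, count_mode="edges") == []


class TestSplitAndReconstruct:
    def test_empty_selection_keeps_foreground_normal(self):
        img = np.zeros((8, 8))
        img[2:6, 2:6] = 0.5
        res = split_image(img, [])
        assert res.tumor_mask.sum() == 0
        assert res.normal_mask.sum() == 16

    def test_masks_partition_foreground(self, rng):
        img = (rng.random((20, 20)) > 0.4).astype(float) * 0.7
        fmap = aware_feature_map(img, 0.5, 8)
        chosen = list(fmap.components)[::2]
        res = split_image(img, chosen)
        fg = img > 0
        assert not (res.tumor_mask & res.normal_mask).any()
        np.testing.assert_array_equal(res.tumor_mask | res.normal_mask, fg)

    def _slice_results(self, vols):
        return [
            SegmentationResult(tumor_mask=v, normal_mask=np.zeros_like(v)) for v in vols
        ]

    def test_single_blob_survives(self):
        masks = [np.zeros((6, 6), bool) for _ in range(3)]
        for m in masks:
            m[2:4, 2:4] = True
        energy = [np.ones((6, 6)) for _ in range(3)]
        out, stats = reconstruct_3d(self._slice_results(masks), energy)
        assert out.sum() == 12
        assert len(stats) == 1 and stats[0]["kept"]

    def test_equal_energy_tie_broken_by_voxel_count(self):
        big = np.zeros((10, 10), bool)
        big[0:5, 0:5] = True  # 25 voxels/slice
        small = np.zeros((10, 10), bool)
        small[8:9, 8:9] = True
        masks = [big | small] * 4  # 100 vs 4 voxels, same energy
        energy = [np.ones((10, 10))] * 4
        out, stats = reconstruct_3d(self._slice_results(masks), energy)
        assert out.sum() == 100

    def test_matches_brute_force_ranking(self, rng):
        from scipy import ndimage

        for _ in range(8):
            vol = rng.random((12, 12, 5)) > 0.7
            energy = rng.random((12, 12, 5))
            res = self._slice_results([vol[:, :, k] for k in range(5)])
            out, stats = reconstruct_3d(res, [energy[:, :, k] for k in range(5)])
            labels, n = ndimage.label(vol, structure=np.ones((3, 3, 3), bool))
            if n == 0:
                assert out.sum() == 0
                continue
            scored = [
                (energy[labels == i].mean(), (labels == i).sum(), -i)
                for i in range(1, n + 1)
            ]
            best = int(-max(scored)[2])
            np.testing.assert_array_equal(out, labels == best)

    def test_empty_volume_is_valid(self):
        masks = [np.zeros((5, 5), bool)] * 3
        out, stats = reconstruct_3d(self._slice_results(masks), [np.zeros((5, 5))] * 3)
        assert out.sum() == 0 and stats == []
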