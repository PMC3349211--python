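"""Spurious filtering, object labelling, 1 cm² density map and ROI building."""

import numpy as np
import pytest

from mcica.classifier import DetectionMap
from mcica.errors import GeometryError
from mcica.roi_builder import (MicrocalcObject, build_rois, density_map,
                               filter_spurious, label_objects,
                               neighbourhood_side_px)


def _det(mask):
    return DetectionMap(mask=np.asarray(mask, dtype=bool))


def _flood_fill_components(mask):
    """Independent 8-connected component labelling via BFS flood fill."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c] or seen[r, c]:
                continue
            stack, pixels = [(r, c)], []
            seen[r, c] = True
            while stack:
                pr, pc = stack.pop()
                pixels.append((pr, pc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = pr + dr, pc + dc
                        if 0 <= nr < mask.shape[0] and 0 <= nc < mask.shape[1] \
                                and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
            comps.append(pixels)
    return comps


def _objects_at(centroids):
    return [MicrocalcObject(i, 1, (float(r), float(c)), (r, c, r, c))
            for i, (r, c) in enumerate(centroids)]


def _brute_density(centroids, shape, side):
    half = side // 2
    counts = np.zeros(shape, dtype=int)
    binned = [(int(round(r)), int(round(c))) for r, c in centroids]
    for pr in range(shape[0]):
        for pc in range(shape[1]):
            counts[pr, pc] = sum(
                1 for br, bc in binned
                if abs(br - pr) <= half and abs(bc - pc) <= half)
    return counts


class TestFilterSpurious:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 5] = True
        out = filter_spurious(_det(mask), min_object_px=2)
        assert not out.mask.any()

    def test_min_one_max_inf_is_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.random((20, 20)) < 0.2
        out = filter_spurious(_det(mask), min_object_px=1,
                              max_object_px=np.inf)
        assert np.array_equal(out.mask, mask)

    def test_blobs_survive_singletons_removed(self):
        mask = np.zeros((20, 20), bool)
        mask[2, 2:5] = True          # 3-px blob
        mask[10, 10:13] = True       # 3-px blob
        for r, c in [(0, 19), (19, 0), (6, 15), (15, 6)]:
            mask[r, c] = True        # singletons
        out = filter_spurious(_det(mask), min_object_px=2)
        comps = _flood_fill_components(out.mask)
        assert len(comps) == 2
        assert out.mask.sum() == 6

    def test_oversized_artifact_removed(self):
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True  # 400 px artifact
        out = filter_spurious(_det(mask), min_object_px=2, max_object_px=100)
        assert not out.mask.any()


class TestLabelObjects:
    def test_empty_map(self):
        assert label_objects(_det(np.zeros((8, 8), bool))) == []

    def test_square_block_geometry(self):
        mask = np.zeros((20, 20), bool)
        mask[10:12, 10:12] = True
        objs = label_objects(_det(mask))
        assert len(objs) == 1
        assert objs[0].pixel_count == 4
        assert objs[0].centroid == (10.5, 10.5)
        assert objs[0].bounding_box == (10, 10, 11, 11)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((48, 48)) < 0.1
        objs = label_objects(_det(mask))
        comps = _flood_fill_components(mask)
        assert len(objs) == len(comps)
        assert sorted(o.pixel_count for o in objs) \
            == sorted(len(p) for p in comps)


class TestDensityMap:
    def test_window_side_forced_odd(self):
        assert neighbourhood_side_px(1000.0) == 11   # 10 px → 11
        assert neighbourhood_side_px(43.5) == 231    # round(229.9) = 230 → 231

    def test_no_objects_gives_zero_map(self):
        dm = density_map([], (32, 32), 1000.0)
        assert not dm.counts.any()
        assert dm.neighbourhood_px == 11

    def test_four_centroids_within_half_window(self):
        centroids = [(10, 10), (12, 14), (14, 10), (8, 8)]
        dm = density_map(_objects_at(centroids), (32, 32), 1000.0)
        assert dm.counts[11, 11] == 4  # all within Chebyshev 5 of (11, 11)

    def test_single_object_support_is_clipped_window(self):
        dm = density_map(_objects_at([(3, 3)]), (32, 32), 1000.0)
        assert dm.counts.max() == 1
        expected = np.zeros((32, 32), int)
        expected[max(0, 3 - 5):3 + 6, max(0, 3 - 5):3 + 6] = 1
        assert np.array_equal(dm.counts, expected)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(GeometryError):
            density_map([], (8, 8), 1000.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(20, 64), rng.integers(20, 64))
        n_obj = rng.integers(0, 15)
        centroids = [(rng.uniform(0, shape[0] - 1), rng.uniform(0, shape[1] - 1))
                     for _ in range(n_obj)]
        px_um = rng.choice([800.0, 1000.0, 1500.0])
        side = neighbourhood_side_px(px_um)
        if side > min(shape):
            return
        dm = density_map(_objects_at(centroids), shape, px_um)
        assert np.array_equal(dm.counts, _brute_density(centroids, shape, side))

    def test_adding_object_never_decreases_counts(self):
        rng = np.random.default_rng(1)
        centroids = [(rng.uniform(0, 31), rng.uniform(0, 31)) for _ in range(6)]
        before = density_map(_objects_at(centroids), (32, 32), 1000.0).counts
        after = density_map(_objects_at(centroids + [(16, 16)]),
                            (32, 32), 1000.0).counts
        assert np.all(after >= before)

    def test_disc_neighbourhood_counts_match_definition(self):
        centroids = [(16, 16), (16, 20), (25, 5)]
        dm = density_map(_objects_at(centroids), (32, 32), 1000.0,
                         shape="disc")
        radius = np.sqrt(1e8 / np.pi) / 1000.0
        expected = sum(1 for r, c in centroids
                       if (r - 16) ** 2 + (c - 18) ** 2 <= radius ** 2)
        assert dm.counts[16, 18] == expected


class TestBuildRois:
    def test_all_below_threshold_gives_no_rois(self):
        dm = density_map(_objects_at([(5, 5), (25, 25)]), (32, 32), 1000.0)
        assert build_rois(dm, _objects_at([(5, 5), (25, 25)]), threshold=3) == []

    def test_tight_cluster_gives_one_roi_with_members(self):
        centroids = [(15, 15), (16, 18), (18, 15), (14, 17)]
        objs = _objects_at(centroids)
        dm = density_map(objs, (32, 32), 1000.0)
        rois = build_rois(dm, objs, threshold=3)
        assert len(rois) == 1
        assert sorted(rois[0].member_objects) == [0, 1, 2, 3]
        assert rois[0].peak_density >= 3

    def test_distant_clusters_give_disjoint_rois(self):
        # two 4-object clusters > 2 cm apart (20 px/cm here)
        a = [(10, 8), (10, 10), (12, 8), (12, 10)]
        b = [(50, 52), (50, 54), (52, 52), (52, 54)]
        objs = _objects_at(a + b)
        dm = density_map(objs, (64, 64), 1000.0)
        rois = build_rois(dm, objs, threshold=3)
        assert len(rois) == 2
        assert not np.any(rois[0].mask & rois[1].mask)
        member_sets = sorted(tuple(sorted(r.member_objects)) for r in rois)
        assert member_sets == [(0, 1, 2, 3), (4, 5, 6, 7)]

    def test_roi_invariants_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        centroids = [(rng.uniform(0, 63), rng.uniform(0, 63))
                     for _ in range(20)]
        objs = _objects_at(centroids)
        dm = density_map(objs, (64, 64), 1000.0)
        rois = build_rois(dm, objs, threshold=3)
        union = np.zeros((64, 64), int)
        for roi in rois:
            union += roi.mask
            assert roi.peak_density >= 3
            for m in roi.member_objects:
                br, bc = objs[m].binned_centroid
                assert roi.mask[br, bc]
        assert union.max() <= 1  # pairwise disjoint
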