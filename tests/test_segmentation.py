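"""Thresholding, region growing (vs. independent BFS) and preset averaging."""
from collections import deque

import numpy as np
import pytest

import osteoprint as op
from osteoprint.errors import LabelCollisionError, ParameterError
from osteoprint.segmentation import LocalRegion


def bfs_flood_fill(values, seeds, low, high, connectivity):
    """Independent breadth-first flood-fill oracle."""
    shape = values.shape
    if connectivity == 6:
        offsets = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        ]
    else:
        offsets = [
            (di, dj, dk)
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            for dk in (-1, 0, 1)
            if (di, dj, dk) != (0, 0, 0)
        ]
    in_range = (values >= low) & (values <= high)
    out = np.zeros(shape, dtype=np.uint8)
    q = deque(s for s in seeds if in_range[s])
    for s in q:
        out[s] = 1
    while q:
        i, j, k = q.popleft()
        for di, dj, dk in offsets:
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                if in_range[ni, nj, nk] and not out[ni, nj, nk]:
                    out[ni, nj, nk] = 1
                    q.append((ni, nj, nk))
    return out


def _vol(values, spacing=(1.0, 1.0, 1.0)):
    return op.HUVolume(np.asarray(values, dtype=float), spacing)


class TestThresholdMask:
    def test_containment_and_exclusion(self):
        vol = _vol(np.full((3, 3, 3), 300.0))
        assert op.threshold_mask(vol, 200, 400).count() == 27
        assert op.threshold_mask(vol, 400, 500).count() == 0

    def test_matches_elementwise_loop(self, rng):
        arr = rng.uniform(-500, 2000, (6, 6, 6))
        mask = op.threshold_mask(_vol(arr), 100.0, 900.0)
        expected = np.zeros(arr.shape, dtype=np.uint8)
        for idx in np.ndindex(arr.shape):
            expected[idx] = 1 if 100.0 <= arr[idx] <= 900.0 else 0
        assert np.array_equal(mask.values, expected)

    def test_inverted_interval_rejected(self):
        with pytest.raises(ParameterError):
            op.threshold_mask(_vol(np.zeros((2, 2, 2))), 10.0, 0.0)


class TestRegionGrow:
    def test_uniform_volume_fills_grid(self):
        vol = _vol(np.full((4, 4, 4), 100.0))
        mask = op.region_grow(vol, [(0, 0, 0)], 50, 150)
        assert mask.count() == 64

    def test_grows_only_the_seeded_blob(self):
        arr = np.zeros((9, 4, 4))
        arr[0:3] = 500.0  # blob A
        arr[6:9] = 500.0  # blob B, separated by out-of-range band
        vol = _vol(arr)
        mask = op.region_grow(vol, [(1, 1, 1)], 400, 600)
        expected = bfs_flood_fill(arr, [(1, 1, 1)], 400, 600, 26)
        assert np.array_equal(mask.values, expected)
        assert mask.values[7, 1, 1] == 0

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bfs_on_random_volumes(self, rng, connectivity):
        for _ in range(20):
            arr = rng.choice([0.0, 500.0], size=(10, 10, 10))
            seeds = [tuple(rng.integers(0, 10, 3)) for _ in range(3)]
            seeds = [s for s in seeds if arr[s] == 500.0]
            if not seeds:
                continue
            mask = op.region_grow(_vol(arr), seeds, 400, 600, connectivity)
            expected = bfs_flood_fill(arr, seeds, 400, 600, connectivity)
            assert np.array_equal(mask.values, expected)

    def test_out_of_range_seed_warned_and_rejected(self):
        arr = np.zeros((4, 4, 4))
        arr[0, 0, 0] = 500.0
        with pytest.warns(UserWarning, match="rejected"):
            mask = op.region_grow(_vol(arr), [(1, 1, 1), (0, 0, 0)], 400, 600)
        assert mask.count() == 1

    def test_no_accepted_seed_returns_empty_with_warning(self):
        vol = _vol(np.zeros((4, 4, 4)))
        with pytest.warns(UserWarning, match="empty"):
            mask = op.region_grow(vol, [(0, 0, 0)], 400, 600)
        assert mask.count() == 0

    def test_subset_of_threshold_mask_and_monotone(self, rng):
        arr = rng.uniform(0, 1000, (8, 8, 8))
        vol = _vol(arr)
        seeds = [(4, 4, 4)]
        if not (300 <= arr[4, 4, 4] <= 700):
            arr[4, 4, 4] = 500.0
            vol = _vol(arr)
        narrow = op.region_grow(vol, seeds, 300, 700)
        wide = op.region_grow(vol, seeds, 200, 800)
        thr = op.threshold_mask(vol, 300, 700)
        assert np.all(narrow.values <= thr.values)
        assert np.all(narrow.values <= wide.values)


class TestSegmentLocal:
    def test_single_full_grid_region_equals_region_grow(self, rng):
        arr = rng.choice([0.0, 500.0], size=(6, 6, 6))
        arr[3, 3, 3] = 500.0
        vol = _vol(arr)
        region = LocalRegion(((0, 0, 0), (6, 6, 6)), 400, 600, [(3, 3, 3)])
        lv = op.segment_local(vol, [region], ["bone"])
        direct = op.region_grow(vol, [(3, 3, 3)], 400, 600)
        assert np.array_equal((lv.values == 1).astype(np.uint8), direct.values)
        assert lv.legend == {1: "bone"}

    def test_disjoint_rois_union_independently(self):
        arr = np.full((8, 4, 4), 500.0)
        vol = _vol(arr)
        r1 = LocalRegion(((0, 0, 0), (3, 4, 4)), 400, 600, [(1, 1, 1)])
        r2 = LocalRegion(((5, 0, 0), (8, 4, 4)), 400, 600, [(6, 1, 1)])
        lv = op.segment_local(vol, [r1, r2], ["a", "b"])
        assert np.all(lv.values[0:3] == 1)
        assert np.all(lv.values[5:8] == 2)
        assert np.all(lv.values[3:5] == 0)

    def test_empty_seed_region_contributes_nothing(self):
        vol = _vol(np.full((4, 4, 4), 500.0))
        region = LocalRegion(((0, 0, 0), (4, 4, 4)), 400, 600, [])
        with pytest.warns(UserWarning, match="no seeds"):
            lv = op.segment_local(vol, [region], ["bone"])
        assert np.all(lv.values == 0)

    def test_duplicate_names_rejected(self):
        vol = _vol(np.zeros((4, 4, 4)))
        r = LocalRegion(((0, 0, 0), (4, 4, 4)), -10, 10, [(0, 0, 0)])
        with pytest.raises(LabelCollisionError):
            op.segment_local(vol, [r, r], ["bone", "bone"])

    def test_overlap_resolved_by_list_order(self):
        vol = _vol(np.full((4, 4, 4), 500.0))
        r1 = LocalRegion(((0, 0, 0), (4, 4, 4)), 400, 600, [(0, 0, 0)])
        r2 = LocalRegion(((0, 0, 0), (4, 4, 4)), 400, 600, [(3, 3, 3)])
        lv = op.segment_local(vol, [r1, r2], ["first", "second"])
        assert np.all(lv.values == 1)  # earlier region wins everywhere


class TestSeparateImplant:
    def test_phantom_implant_recovered_and_disjoint(self, clean_phantom):
        vol, truth = clean_phantom
        bone, implant = op.separate_implant(vol, (150.0, 2500.0), 3000.0, margin=1.0)
        t = truth.masks["implant"].astype_bool()
        b = implant.astype_bool()
        dice = 2 * (b & t).sum() / (b.sum() + t.sum())
        assert dice >= 0.99
        assert not np.any(bone.astype_bool() & implant.astype_bool())

    def test_absent_metal_gives_empty_implant(self):
        vol = _vol(np.full((4, 4, 4), 300.0))
        bone, implant = op.separate_implant(vol, (150.0, 2500.0), 3000.0, margin=1.0)
        assert implant.count() == 0
        assert bone.count() == 64  # bone unchanged by subtraction

    def test_zero_margin_subtracts_raw_implant(self):
        arr = np.full((6, 6, 6), 300.0)
        arr[2:4, 2:4, 2:4] = 8000.0
        vol = _vol(arr)
        bone, implant = op.separate_implant(vol, (150.0, 2500.0), 3000.0, margin=0.0)
        assert implant.count() == 8
        assert bone.count() == 216 - 8

    def test_metal_low_within_bone_interval_rejected(self):
        with pytest.raises(ParameterError):
            op.separate_implant(_vol(np.zeros((3, 3, 3))), (150.0, 2500.0), 2000.0)


class TestAverageThresholds:
    def test_single_case(self):
        preset = op.average_thresholds([{"bone": (148.0, 1800.0)}])
        e = preset.entries["bone"]
        assert (e.low, e.high, e.sd_low, e.n_cases) == (148.0, 1800.0, 0.0, 1)

    def test_two_case_mean_and_sd(self):
        preset = op.average_thresholds(
            [{"bone": (100.0, 1000.0)}, {"bone": (120.0, 1100.0)}]
        )
        e = preset.entries["bone"]
        assert e.low == pytest.approx(110.0)
        assert e.sd_low == pytest.approx(14.1421356, rel=1e-6)
        assert e.n_cases == 2

    def test_matches_direct_recomputation(self, rng):
        cases = [
            {"bone": (rng.uniform(100, 200), rng.uniform(1500, 2000))}
            for _ in range(10)
        ]
        preset = op.average_thresholds(cases)
        lows = np.array([c["bone"][0] for c in cases])
        highs = np.array([c["bone"][1] for c in cases])
        assert preset.entries["bone"].low == pytest.approx(lows.mean())
        assert preset.entries["bone"].high == pytest.approx(highs.mean())
        assert preset.entries["bone"].sd_low == pytest.approx(lows.std(ddof=1))

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            op.average_thresholds([])

    def test_yaml_round_trip(self, tmp_path):
        preset = op.average_thresholds(
            [{"bone": (100.0, 1000.0), "implant": (3000.0, 32767.0)}]
        )
        path = preset.to_yaml(tmp_path / "preset.yaml")
        back = op.ThresholdPreset.from_yaml(path)
        assert back.entries["bone"].low == 100.0
        assert back.entries["implant"].high == 32767.0
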