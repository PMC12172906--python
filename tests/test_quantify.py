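"""Unit and oracle tests for subtraction, Z-scoring and activity labeling.

The classification oracle here is an independent brute-force interpreter of
the labeling rules (pure-python flood fills and per-voxel rule evaluation);
it shares no code with the implementation.
"""

from collections import deque
from itertools import product

import numpy as np
import pytest

from lesionsub.core import AffineTransform, BinaryMask, ConfigurationError, DataError, ImageVolume
from lesionsub.quantify import (
    ActivityLabelMap,
    LABEL_CODES,
    ZScoreMap,
    check_fov_coverage,
    classify_activity,
    compute_tlvc,
    condition_lesion_mask,
    pair_lesion_components,
    remove_in_slice_singletons,
    subtract,
    to_zscores,
)
from lesionsub.registration import GridSpec

AFF = np.diag([1.0, 1.0, 3.0, 1.0])


def vol(data):
    return ImageVolume(np.asarray(data, float), AFF.copy(), "SUBTRACTION")


def mask(data):
    return BinaryMask(np.asarray(data, dtype=np.uint8), AFF.copy())


# --------------------------------------------------------------------------
# independent brute-force oracle


def _flood3d(m, start, seen):
    comp = set()
    q = deque([start])
    seen.add(start)
    while q:
        v = q.popleft()
        comp.add(v)
        for d in product((-1, 0, 1), repeat=3):
            if d == (0, 0, 0):
                continue
            n = tuple(a + b for a, b in zip(v, d))
            if all(0 <= n[i] < m.shape[i] for i in range(3)) and m[n] and n not in seen:
                seen.add(n)
                q.append(n)
    return comp


def _components(m):
    comps, seen = [], set()
    for idx in np.ndindex(m.shape):
        if m[idx] and idx not in seen:
            comps.append(_flood3d(m, idx, seen))
    return comps


def _erode_2d_cross(m):
    out = np.zeros_like(m)
    for i, j, k in np.ndindex(m.shape):
        if not m[i, j, k]:
            continue
        ok = True
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if not (0 <= ni < m.shape[0] and 0 <= nj < m.shape[1]) or not m[ni, nj, k]:
                ok = False
                break
        out[i, j, k] = ok
    return out


def oracle_classify(z, m1, m2, thr):
    """Independent rule interpreter for the three-situation labeling."""
    comps1 = _components(m1)
    comps2 = _components(m2)
    overlaps = [
        (i, j)
        for i, c1 in enumerate(comps1)
        for j, c2 in enumerate(comps2)
        if c1 & c2
    ]
    linked1 = {i for i, _ in overlaps}
    linked2 = {j for _, j in overlaps}
    # transitive closure of the overlap relation
    groups = []
    todo = list(overlaps)
    while todo:
        gi, gj = {todo[0][0]}, {todo[0][1]}
        todo.pop(0)
        changed = True
        while changed:
            changed = False
            for i, j in list(todo):
                if i in gi or j in gj:
                    gi.add(i)
                    gj.add(j)
                    todo.remove((i, j))
                    changed = True
        groups.append((gi, gj))
    e1 = _erode_2d_cross(m1)
    e2 = _erode_2d_cross(m2)
    labels = np.zeros(z.shape, dtype=np.uint8)
    for j, c2 in enumerate(comps2):
        if j not in linked2:
            for v in c2:
                if z[v] > thr:
                    labels[v] = LABEL_CODES["new"]
    for i, c1 in enumerate(comps1):
        if i not in linked1:
            for v in c1:
                if z[v] < -thr:
                    labels[v] = LABEL_CODES["disappearing"]
    for gi, gj in groups:
        region = set()
        for i in gi:
            region |= comps1[i]
        for j in gj:
            region |= comps2[j]
        for v in region:
            if z[v] > thr and not e1[v]:
                labels[v] = LABEL_CODES["enlarging"]
            elif z[v] < -thr and not e2[v]:
                labels[v] = LABEL_CODES["shrinking"]
    return labels


def run_impl(z, m1, m2, thr=1.5):
    zmap = ZScoreMap(np.asarray(z, float), AFF.copy(), 0.0, 1.0)
    corr = pair_lesion_components(mask(m1), mask(m2))
    return classify_activity(zmap, corr, mask(m1), mask(m2), thr).labels


# --------------------------------------------------------------------------


class TestSubtract:
    def test_identical_images_zero(self):
        a = vol(np.random.default_rng(0).random((4, 4, 2)))
        out = subtract(a, a)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_regional_offset_and_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = vol(rng.random((5, 5, 2)))
        bdata = a.data.copy()
        bdata[1:3, 1:3, :] += 0.2
        b = vol(bdata)
        d = subtract(b, a)
        assert d.data[1, 1, 0] == pytest.approx(0.2)
        assert d.data[4, 4, 1] == pytest.approx(0.0)
        np.testing.assert_allclose(subtract(a, b).data, -d.data)

    def test_geometry_mismatch_rejected(self):
        a = vol(np.zeros((4, 4, 2)))
        b = ImageVolume(np.zeros((4, 4, 2)), np.eye(4), "PD")
        with pytest.raises(DataError):
            subtract(a, b)


class TestZScores:
    def test_standard_reference_is_identity(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((6, 6, 3))
        ref = np.ones((6, 6, 3), dtype=np.uint8)
        data -= data.mean()
        data /= data.std(ddof=1)
        z = to_zscores(vol(data), mask(ref), mask(np.zeros_like(ref)))
        np.testing.assert_allclose(z.data, data, atol=1e-10)

    def test_two_point_reference_sample_sd(self):
        # reference {-1, +1}: mean 0, sample SD sqrt(2); value 2 -> Z = sqrt(2)
        data = np.zeros((2, 1, 1))
        data[0, 0, 0], data[1, 0, 0] = -1.0, 1.0
        full = np.ones((2, 1, 1), dtype=np.uint8)
        z = to_zscores(vol(data), mask(full), mask(np.zeros_like(full)))
        assert z.reference_sd == pytest.approx(np.sqrt(2))
        probe = np.full((2, 1, 1), 2.0)
        z2 = ZScoreMap((probe - z.reference_mean) / z.reference_sd, AFF, 0, 1)
        assert z2.data[0, 0, 0] == pytest.approx(np.sqrt(2))

    def test_reference_mean_zero_sd_one_by_construction(self):
        rng = np.random.default_rng(3)
        data = rng.normal(5, 3, (8, 8, 4))
        ref = (rng.random((8, 8, 4)) < 0.6).astype(np.uint8)
        les = np.zeros_like(ref)
        les[2:4, 2:4, 1] = 1
        z = to_zscores(vol(data), mask(ref), mask(les))
        sel = ref.astype(bool) & ~les.astype(bool)
        assert z.data[sel].mean() == pytest.approx(0.0, abs=1e-10)
        assert z.data[sel].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_constant_reference_rejected(self):
        data = np.zeros((4, 4, 2))
        full = np.ones((4, 4, 2), dtype=np.uint8)
        with pytest.raises(DataError):
            to_zscores(vol(data), mask(full), mask(np.zeros_like(full)))


class TestConditioning:
    def grid(self):
        return GridSpec((10, 10, 4), AFF.copy())

    def test_identity_no_singletons_is_identity(self):
        m = np.zeros((10, 10, 4), dtype=np.uint8)
        m[3:6, 3:6, 1:3] = 1
        out, emptied = condition_lesion_mask(
            mask(m), AffineTransform.identity(), self.grid()
        )
        np.testing.assert_array_equal(out.data, m)
        assert not emptied

    def test_half_voxel_shift_keeps_half_weight_boundary(self):
        m = np.zeros((10, 10, 4), dtype=np.uint8)
        m[4, 3:7, 1] = 1  # one-voxel-thick line
        t = AffineTransform.from_rigid(translation_mm=(-0.5, 0, 0))
        out, _ = condition_lesion_mask(mask(m), t, self.grid())
        # content moves to x-0.5: rows 3 and 4 carry fraction 0.5 >= 0.25
        assert out.data[3, 4, 1] == 1 and out.data[4, 4, 1] == 1
        assert out.data[5, 4, 1] == 0

    def test_isolated_in_slice_voxel_removed(self):
        m = np.zeros((10, 10, 4), dtype=np.uint8)
        m[3:6, 3:6, 1] = 1
        m[8, 8, 2] = 1  # singleton in its slice
        out, _ = condition_lesion_mask(
            mask(m), AffineTransform.identity(), self.grid()
        )
        assert out.data[8, 8, 2] == 0
        assert out.data[3:6, 3:6, 1].sum() == 9

    def test_emptied_mask_flagged_not_raised(self):
        m = np.zeros((10, 10, 4), dtype=np.uint8)
        m[5, 5, 1] = 1  # a single voxel: removed by the singleton rule
        out, emptied = condition_lesion_mask(
            mask(m), AffineTransform.identity(), self.grid()
        )
        assert out.count() == 0 and emptied

    def test_bad_threshold_rejected(self):
        m = np.zeros((10, 10, 4), dtype=np.uint8)
        with pytest.raises(ConfigurationError):
            condition_lesion_mask(
                mask(m), AffineTransform.identity(), self.grid(), threshold=0.0
            )


def test_singleton_removal_uses_2d_8_connectivity():
    m = np.zeros((6, 6, 2), dtype=bool)
    m[2, 2, 0] = True
    m[3, 3, 0] = True  # diagonal neighbour in-slice: 8-connected pair survives
    m[5, 5, 1] = True  # true singleton in its own slice
    out = remove_in_slice_singletons(m)
    assert out[2, 2, 0] and out[3, 3, 0]
    assert not out[5, 5, 1]


class TestCorrespondence:
    def test_lone_visit2_blob_is_situation_1(self):
        m1 = np.zeros((8, 8, 3), dtype=np.uint8)
        m2 = np.zeros_like(m1)
        m2[2:4, 2:4, 1] = 1
        entries = pair_lesion_components(mask(m1), mask(m2))
        assert [e.situation for e in entries] == [1]
        assert entries[0].region.sum() == 4

    def test_overlapping_blobs_merge_to_situation_3(self):
        m1 = np.zeros((8, 8, 3), dtype=np.uint8)
        m2 = np.zeros_like(m1)
        m1[2:5, 2:5, 1] = 1
        m2[4:7, 4:7, 1] = 1  # shares voxel (4,4,1)
        entries = pair_lesion_components(mask(m1), mask(m2))
        assert [e.situation for e in entries] == [3]
        np.testing.assert_array_equal(
            entries[0].region, m1.astype(bool) | m2.astype(bool)
        )

    def test_chain_merges_transitively(self):
        # A1 <-> B2 <-> C1: one combined group
        m1 = np.zeros((12, 6, 3), dtype=np.uint8)
        m2 = np.zeros_like(m1)
        m1[1:4, 2:4, 1] = 1    # A1
        m1[7:10, 2:4, 1] = 1   # C1
        m2[3:8, 2:4, 1] = 1    # B2 overlaps both
        entries = pair_lesion_components(mask(m1), mask(m2))
        assert [e.situation for e in entries] == [3]
        assert entries[0].v1_labels and entries[0].v2_labels
        expected = m1.astype(bool) | m2.astype(bool)
        np.testing.assert_array_equal(entries[0].region, expected)

    def test_empty_masks_empty_table(self):
        z = np.zeros((4, 4, 2), dtype=np.uint8)
        assert pair_lesion_components(mask(z), mask(z)) == []


class TestClassification:
    def test_all_subthreshold_all_none(self):
        m1 = np.zeros((6, 6, 2), dtype=np.uint8)
        m2 = np.zeros_like(m1)
        m2[1:4, 1:4, 0] = 1
        labels = run_impl(np.full((6, 6, 2), 1.0), m1, m2)
        assert (labels == 0).all()

    def test_threshold_is_strict(self):
        m1 = np.zeros((6, 6, 2), dtype=np.uint8)
        m2 = np.zeros_like(m1)
        m2[1:4, 1:4, 0] = 1
        z = np.zeros((6, 6, 2))
        z[1, 1, 0] = 1.5   # exactly at threshold -> none
        z[2, 2, 0] = 1.5000001
        labels = run_impl(z, m1, m2)
        assert labels[1, 1, 0] == 0
        assert labels[2, 2, 0] == LABEL_CODES["new"]

    def test_erosion_restriction_blocks_interior_enlarging(self):
        m1 = np.zeros((7, 7, 1), dtype=np.uint8)
        m2 = np.zeros_like(m1)
        m1[1:6, 1:6, 0] = 1
        m2[1:6, 1:6, 0] = 1
        z = np.zeros((7, 7, 1))
        z[3, 3, 0] = 2.0  # deep interior of visit-1 mask
        z[1, 3, 0] = 2.0  # boundary: not in eroded mask
        labels = run_impl(z, m1, m2)
        assert labels[3, 3, 0] == 0
        assert labels[1, 3, 0] == LABEL_CODES["enlarging"]

    def test_bad_threshold_rejected(self):
        zmap = ZScoreMap(np.zeros((4, 4, 2)), AFF.copy(), 0.0, 1.0)
        with pytest.raises(ConfigurationError):
            classify_activity(zmap, [], mask(np.zeros((4, 4, 2), dtype=np.uint8)),
                              mask(np.zeros((4, 4, 2), dtype=np.uint8)), 0.0)

    def test_matches_bruteforce_oracle_on_randomized_instances(self):
        rng = np.random.default_rng(12345)
        shape = (8, 8, 3)
        for trial in range(300):
            m1 = (rng.random(shape) < 0.25).astype(np.uint8)
            m2 = (rng.random(shape) < 0.25).astype(np.uint8)
            z = rng.normal(0, 2.0, shape)
            # force exact boundary values to pin down strictness
            z.flat[rng.integers(0, z.size, 6)] = 1.5
            z.flat[rng.integers(0, z.size, 6)] = -1.5
            got = run_impl(z, m1, m2)
            want = oracle_classify(z, m1.astype(bool), m2.astype(bool), 1.5)
            np.testing.assert_array_equal(got, want)


class TestTLVC:
    def label_map(self, counts):
        data = np.zeros((20, 20, 2), dtype=np.uint8)
        flat = data.ravel()
        pos = 0
        for cat, n in counts.items():
            flat[pos:pos + n] = LABEL_CODES[cat]
            pos += n
        return ActivityLabelMap(flat.reshape(data.shape), AFF.copy())

    def test_all_none_zero(self):
        res = compute_tlvc(self.label_map({}))
        assert res.tlvc == 0.0

    def test_hundred_new_voxels(self):
        res = compute_tlvc(self.label_map({"new": 100}))
        assert res.tlvc == pytest.approx(0.3)

    def test_mixed_counts_match_hand_calculation(self):
        counts = {"new": 50, "enlarging": 30, "shrinking": 20, "disappearing": 40}
        res = compute_tlvc(self.label_map(counts))
        voxml = 3.0 / 1000.0
        # independent count-and-multiply oracle
        assert res.vol_new == pytest.approx(50 * voxml)
        assert res.positive_activity == pytest.approx(80 * voxml)
        assert res.negative_activity == pytest.approx(60 * voxml)
        assert res.tlvc == pytest.approx((80 - 60) * voxml)


class TestThresholdMonotonicity:
    def test_raising_threshold_never_increases_categories(self):
        rng = np.random.default_rng(7)
        shape = (8, 8, 3)
        m1 = (rng.random(shape) < 0.3).astype(np.uint8)
        m2 = (rng.random(shape) < 0.3).astype(np.uint8)
        z = rng.normal(0, 2, shape)
        prev = None
        for thr in (1.0, 1.5, 2.0, 3.0):
            labels = run_impl(z, m1, m2, thr)
            counts = np.bincount(labels.ravel(), minlength=5)
            if prev is not None:
                assert all(counts[1:] <= prev[1:])
            prev = counts


class TestFovCoverage:
    def masks(self):
        m1 = np.zeros((6, 6, 4), dtype=np.uint8)
        m2 = np.zeros_like(m1)
        m1[2:4, 2:4, 1] = 1
        m2[2:4, 2:4, 3] = 1
        return m1, m2

    def test_full_coverage_clear(self):
        m1, m2 = self.masks()
        full = np.ones_like(m1)
        assert not check_fov_coverage(mask(m1), mask(m2), mask(full), mask(full))

    def test_missing_slice_with_lesion_raises_flag(self):
        m1, m2 = self.masks()
        fov1 = np.ones_like(m1)
        fov1[:, :, 3] = 0  # visit-1 misses the slice holding visit-2's lesion
        assert check_fov_coverage(mask(m1), mask(m2), mask(fov1), mask(np.ones_like(m1)))

    def test_agrees_with_exhaustive_loop(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            m1 = (rng.random((5, 5, 3)) < 0.2).astype(np.uint8)
            m2 = (rng.random((5, 5, 3)) < 0.2).astype(np.uint8)
            f1 = (rng.random((5, 5, 3)) < 0.9).astype(np.uint8)
            f2 = (rng.random((5, 5, 3)) < 0.9).astype(np.uint8)
            expected = False
            for idx in np.ndindex((5, 5, 3)):
                if (m1[idx] and not f2[idx]) or (m2[idx] and not f1[idx]):
                    expected = True
            assert check_fov_coverage(mask(m1), mask(m2), mask(f1), mask(f2)) == expected


def test_category_conservation_within_masks():
    rng = np.random.default_rng(21)
    shape = (8, 8, 3)
    m1 = (rng.random(shape) < 0.3).astype(np.uint8)
    m2 = (rng.random(shape) < 0.3).astype(np.uint8)
    z = rng.normal(0, 2, shape)
    labels = run_impl(z, m1, m2)
    region_union = np.zeros(shape, dtype=bool)
    for e in pair_lesion_components(mask(m1), mask(m2)):
        region_union |= e.region
    n_labeled = (labels > 0).sum()
    n_none_in_masks = (region_union & (labels == 0)).sum()
    assert n_labeled + n_none_in_masks == region_union.sum()
    assert not ((labels > 0) & ~region_union).any()
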