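"""Thresholding, cluster-extent filtering and ROI peak extraction tests."""

from collections import deque

import numpy as np
import pytest
from scipy import stats

from dynabody.glm import StatMap
from dynabody.localize import (
    CANONICAL_SEEDS,
    LITERATURE_PEAKS,
    METHOD_MEAN_PEAKS,
    RoiSeed,
    ThresholdSpec,
    apply_threshold,
    cluster_filter,
    compare_to_reference,
    find_roi_peak,
    permutation_max_t,
    roi_report,
    seeds_from_table,
    subject_tally,
    t_threshold_value,
    voxel_threshold,
)
from dynabody.synthetic import bold_affine


def _stat_map(values, df=230, voxel=3.0):
    values = np.asarray(values, dtype=float)
    return StatMap(values=values, affine=bold_affine(values.shape, voxel), df=df)


def flood_fill_sizes(binary, connectivity=6):
    """Brute-force BFS component labeling oracle."""
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (i, j, k)
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    sizes = []
    for start in np.argwhere(binary):
        start = tuple(start)
        if seen[start]:
            continue
        queue, size = deque([start]), 0
        seen[start] = True
        while queue:
            cur = queue.popleft()
            size += 1
            for off in offsets:
                nxt = tuple(np.add(cur, off))
                if any(c < 0 or c >= s for c, s in zip(nxt, binary.shape)):
                    continue
                if binary[nxt] and not seen[nxt]:
                    seen[nxt] = True
                    queue.append(nxt)
        sizes.append(size)
    return sorted(sizes)


class TestVoxelThreshold:
    def test_bonferroni_per_voxel_alpha(self):
        spec = ThresholdSpec("fwe_05")
        thr = t_threshold_value(spec, df=230, n_voxels=1000)
        assert thr == pytest.approx(float(stats.t.isf(0.05 / 1000, 230)))

    def test_uncorrected_null_survival_rate(self, rng):
        values = stats.t.rvs(df=230, size=(30, 30, 30),
                             random_state=np.random.default_rng(1))
        sm = _stat_map(values)
        binary, thr = voxel_threshold(sm, ThresholdSpec("unc_05"))
        assert binary.mean() == pytest.approx(0.05, abs=0.01)

    def test_scaling_the_map_grows_the_surviving_set(self, rng):
        values = rng.normal(size=(10, 10, 10))
        a, thr = voxel_threshold(_stat_map(values), ThresholdSpec("unc_05"))
        b, _ = voxel_threshold(_stat_map(values * 2), ThresholdSpec("unc_05"))
        assert (a <= b).all()

    def test_empty_mask_rejected(self, rng):
        sm = _stat_map(rng.normal(size=(5, 5, 5)))
        with pytest.raises(ValueError, match="empty mask"):
            voxel_threshold(sm, ThresholdSpec("unc_05"),
                            mask=np.zeros((5, 5, 5), bool))


class TestClusterFilter:
    def test_extent_threshold_semantics(self):
        binary = np.zeros((10, 10, 10), dtype=bool)
        binary[0, 0, :9] = True  # size 9
        binary[5, 5:9, 5:8] = True  # size 12
        labels, sizes = cluster_filter(binary, extent_min=10)
        assert sorted(sizes.values()) == [12]
        assert (labels > 0).sum() == 12

    def test_zero_extent_is_identity(self, rng):
        binary = rng.random((8, 8, 8)) < 0.2
        labels, _ = cluster_filter(binary, extent_min=0)
        assert np.array_equal(labels > 0, binary)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_component_sizes_match_flood_fill_oracle(self, rng, connectivity):
        binary = rng.random((10, 10, 10)) < 0.25
        labels, sizes = cluster_filter(binary, extent_min=1,
                                       connectivity=connectivity)
        assert sorted(sizes.values()) == flood_fill_sizes(binary, connectivity)

    def test_bad_connectivity_rejected(self):
        with pytest.raises(ValueError):
            cluster_filter(np.zeros((2, 2, 2), bool), connectivity=10)


class TestRoiPeaks:
    def _planted_map(self, seed_xyz, peak_t=12.0, shape=(46, 54, 38)):
        sm = _stat_map(np.zeros(shape))
        center = np.round(sm.mm_to_voxel(seed_xyz)[0]).astype(int)
        sl = tuple(slice(c - 1, c + 2) for c in center)
        values = sm.values
        values[sl] = peak_t * 0.8
        values[tuple(center)] = peak_t
        return _stat_map(values), center

    def test_planted_peak_recovered_at_canonical_seed(self):
        sm, center = self._planted_map((45.0, -46.0, -17.0))
        seed = RoiSeed("rFBA", (45.0, -46.0, -17.0))
        peak = find_roi_peak(sm, seed, ThresholdSpec("unc_001"))
        assert peak.present
        peak_vox = np.round(sm.mm_to_voxel(peak.peak_xyz)[0]).astype(int)
        assert np.abs(peak_vox - center).max() <= 1

    def test_empty_sphere_is_absent_not_error(self):
        sm = _stat_map(np.zeros((20, 20, 20)))
        peak = find_roi_peak(sm, RoiSeed("mid", (0.0, 0.0, 0.0)),
                             ThresholdSpec("unc_001"))
        assert not peak.present and peak.n_voxels == 0

    def test_peak_is_argmax_of_survivors(self):
        sm = _stat_map(np.zeros((20, 20, 20)))
        a = np.round(sm.mm_to_voxel((0.0, 0.0, 0.0))[0]).astype(int)
        sm.values[tuple(a)] = 5.0
        sm.values[a[0] + 1, a[1], a[2]] = 7.0
        spec = ThresholdSpec("unc_001", cluster_extent_min=0)
        peak = find_roi_peak(sm, RoiSeed("mid", (0.0, 0.0, 0.0)), spec)
        assert peak.peak_t == 7.0

    def test_sphere_outside_grid_rejected(self):
        sm = _stat_map(np.zeros((6, 6, 6)))
        with pytest.raises(ValueError, match="outside the image grid"):
            find_roi_peak(sm, RoiSeed("far", (200.0, 0.0, 0.0)),
                          ThresholdSpec("unc_001"))

    def test_nested_thresholds_on_random_maps(self, rng):
        for _ in range(5):
            sm = _stat_map(rng.normal(size=(15, 15, 15)) * 3)
            maps = {
                level: apply_threshold(sm, ThresholdSpec(level))[0]
                for level in ("fwe_05", "unc_001", "unc_05")
            }
            assert (maps["fwe_05"] <= maps["unc_001"]).all()
            assert (maps["unc_001"] <= maps["unc_05"]).all()


class TestGroupTables:
    def _report_with_presence(self, present, peak_t=10.0):
        shape = (24, 24, 24)
        values = np.zeros(shape)
        if present:
            sm0 = _stat_map(values)
            center = np.round(sm0.mm_to_voxel((0.0, 0.0, 0.0))[0]).astype(int)
            sl = tuple(slice(c - 1, c + 2) for c in center)
            values[sl] = peak_t
        sm = _stat_map(values)
        seeds = [RoiSeed("mid", (0.0, 0.0, 0.0))]
        return roi_report(sm, seeds)

    def test_single_subject_counts(self):
        tally = subject_tally([self._report_with_presence(True)])
        assert (tally["n_present"] == 1).all()
        assert (tally["n_subjects"] == 1).all()

    def test_partial_cohort_detection_count(self):
        reports = [self._report_with_presence(i < 8) for i in range(10)]
        tally = subject_tally(reports).set_index("level")
        assert tally.loc["unc_001", "n_present"] == 8
        assert tally.loc["unc_001", "fraction_present"] == pytest.approx(0.8)

    def test_counts_monotone_across_thresholds(self, rng):
        reports = []
        for s in range(6):
            sm = _stat_map(rng.normal(size=(20, 20, 20))
                           + (3.0 if s % 2 else 0.0))
            reports.append(roi_report(sm, [RoiSeed("mid", (0.0, 0.0, 0.0))]))
        tally = subject_tally(reports).set_index("level")
        assert (tally.loc["unc_05", "n_present"]
                >= tally.loc["unc_001", "n_present"]
                >= tally.loc["fwe_05", "n_present"])


class TestReferenceComparison:
    def test_identical_tables_give_zero_distance(self):
        d = compare_to_reference(METHOD_MEAN_PEAKS, METHOD_MEAN_PEAKS)
        assert np.allclose(d["distance_mm"], 0.0)

    def test_fusiform_body_area_distance_to_literature(self):
        d = compare_to_reference(METHOD_MEAN_PEAKS, LITERATURE_PEAKS)
        assert d.set_index("name").loc["rFBA", "distance_mm"] == pytest.approx(5.0)

    def test_symmetry(self):
        a = compare_to_reference(METHOD_MEAN_PEAKS, LITERATURE_PEAKS)
        b = compare_to_reference(LITERATURE_PEAKS, METHOD_MEAN_PEAKS)
        assert np.allclose(np.sort(a["distance_mm"]), np.sort(b["distance_mm"]))

    def test_missing_roi_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            compare_to_reference(METHOD_MEAN_PEAKS.iloc[:3], LITERATURE_PEAKS)


class TestPermutationMaxT:
    def test_threshold_is_quantile_of_sign_flip_null(self, rng):
        imgs = rng.normal(size=(8, 200))
        thr_a = permutation_max_t(imgs, alpha=0.05, n_permutations=200, seed=0)
        thr_b = permutation_max_t(imgs, alpha=0.05, n_permutations=200, seed=0)
        assert thr_a == thr_b  # deterministic under seed
        thr_strict = permutation_max_t(imgs, alpha=0.01, n_permutations=200, seed=0)
        assert thr_strict >= thr_a

    def test_strong_effect_exceeds_threshold(self, rng):
        imgs = rng.normal(size=(10, 100))
        imgs[:, 0] += 5.0
        thr = permutation_max_t(imgs, alpha=0.05, n_permutations=300, seed=1)
        group_t = imgs[:, 0].mean() / (imgs[:, 0].std(ddof=1) / np.sqrt(10))
        assert group_t > thr

    def test_canonical_seed_table_is_well_formed(self):
        seeds = seeds_from_table(CANONICAL_SEEDS)
        assert len(seeds) == 7
        assert {s.name for s in seeds} == {
            "rFBA", "rEBA", "rpSTS", "rPCG", "lEBA", "lpSTS", "rIFG"
        }
        assert all(s.radius_mm == 10.0 for s in seeds)
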