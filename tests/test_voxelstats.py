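"""Group inference, cluster machinery and cohort-table statistics."""

import numpy as np
import pytest
from scipy import stats

import falffkit as fk
from falffkit.preprocess import BrainMask
from falffkit.voxelstats import (ClusterNull, contingency_chi2,
                                 corrected_significance, label_clusters,
                                 monte_carlo_cluster_null, one_sample_ttest,
                                 overlap_stats, summary_stat_anova,
                                 voxelwise_anova, voxelwise_ttest)

AFFINE3 = np.diag([3.0, 3.0, 3.0, 1.0])


def flood_fill_label(binary, connectivity):
    """Independent BFS connected-components oracle."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(binary, bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp, queue = [], [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.append(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if all(0 <= wi < si for wi, si in zip(w, binary.shape)) \
                        and binary[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(sorted(comp))
    return sorted((len(c) for c in comps), reverse=True)


def _mask(shape=(8, 8, 8)):
    return BrainMask(np.ones(shape, bool), AFFINE3)


def _maps_from(rng, shape, n):
    return [rng.standard_normal(shape) for _ in range(n)]


class TestVoxelwiseAnova:
    def test_agrees_with_scipy_f_oneway(self):
        """Independent-implementation oracle at 100 random voxels to 1e-8."""
        rng = np.random.default_rng(0)
        mask = _mask((5, 5, 4))
        groups = {g: _maps_from(rng, (5, 5, 4), n) for g, n in
                  [("a", 5), ("b", 7), ("c", 4)]}
        sm = voxelwise_anova(groups, mask)
        for (i, j, k) in map(tuple, rng.integers(0, (5, 5, 4), size=(100, 3))):
            samples = [np.array([m[i, j, k] for m in groups[g]]) for g in groups]
            F, p = stats.f_oneway(*samples)
            assert sm.stat[i, j, k] == pytest.approx(F, abs=1e-8)
            assert sm.p[i, j, k] == pytest.approx(p, abs=1e-8)

    def test_constant_voxel_gives_f0_p1(self):
        mask = _mask((2, 2, 2))
        groups = {"a": [np.ones((2, 2, 2))] * 3, "b": [np.ones((2, 2, 2))] * 3}
        sm = voxelwise_anova(groups, mask)
        assert np.all(sm.stat == 0) and np.all(sm.p == 1)

    def test_null_p_values_uniform(self):
        """Identically drawn groups: in-mask p-values pass a KS test vs uniform."""
        rng = np.random.default_rng(42)
        mask = _mask((8, 8, 8))
        groups = {g: _maps_from(rng, (8, 8, 8), 8) for g in "abc"}
        sm = voxelwise_anova(groups, mask)
        assert stats.kstest(sm.p[mask.data], "uniform").pvalue > 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            voxelwise_anova({"a": [np.ones((2, 2, 2))], "b": [np.ones((2, 2, 2))] * 2},
                            _mask((2, 2, 2)))


class TestVoxelwiseTtest:
    def test_identical_groups_t0_p1(self):
        maps = [np.full((3, 3, 3), 2.0)] * 3
        sm = voxelwise_ttest(maps, [m.copy() for m in maps], _mask((3, 3, 3)))
        assert np.all(sm.stat == 0) and np.all(sm.p == 1)
        assert sm.qc["zero_variance_voxels"] == 27

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = _maps_from(rng, (4, 4, 4), 6)
        b = _maps_from(rng, (4, 4, 4), 5)
        ab = voxelwise_ttest(a, b, _mask((4, 4, 4)))
        ba = voxelwise_ttest(b, a, _mask((4, 4, 4)))
        assert np.allclose(ab.stat, -ba.stat)
        assert np.allclose(ab.p, ba.p)

    def test_agrees_with_scipy_pooled_ttest(self):
        rng = np.random.default_rng(2)
        a = _maps_from(rng, (3, 3, 3), 11)
        b = _maps_from(rng, (3, 3, 3), 13)
        sm = voxelwise_ttest(a, b, _mask((3, 3, 3)))
        i, j, k = 1, 2, 0
        t, p = stats.ttest_ind([m[i, j, k] for m in a], [m[i, j, k] for m in b],
                               equal_var=True)
        assert sm.stat[i, j, k] == pytest.approx(t, abs=1e-10)
        assert sm.p[i, j, k] == pytest.approx(p, abs=1e-10)

    def test_injected_effect_detected(self):
        """Cohen's d=2 shift in a 30-voxel region, n=11 vs 13: median p < 0.05
        in at least 90% of repetitions."""
        region = np.zeros((6, 6, 6), bool)
        region[1:6, 1:3, 1:4] = True
        assert region.sum() == 30
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            a = [rng.standard_normal((6, 6, 6)) + 2.0 * region for _ in range(11)]
            b = _maps_from(rng, (6, 6, 6), 13)
            sm = voxelwise_ttest(a, b, _mask((6, 6, 6)))
            hits += np.median(sm.p[region]) < 0.05
        assert hits / 20 >= 0.9


class TestClusterLabeling:
    def test_two_blobs_sizes_and_threshold(self):
        binary = np.zeros((10, 10, 10), bool)
        binary[1:3, 1:3, 1] = True
        binary[3, 1, 1] = True  # face-connected blob of 5
        binary[6:9, 6:9, 6] = True
        binary[6:8, 6:8, 7] = True  # face-connected blob of 13
        table = label_clusters(binary, 6, affine=AFFINE3)
        assert sorted(table.size_voxels, reverse=True) == [13, 5]
        assert flood_fill_label(binary, 6) == [13, 5]
        assert (table.size_mm3 == table.size_voxels * 27.0).all()
        surviving = table[table.size_voxels > 6]
        assert len(surviving) == 1 and surviving.iloc[0].size_voxels == 13

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_agrees_with_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(connectivity)
        for _ in range(25):
            binary = rng.random((9, 9, 9)) < 0.25
            table = label_clusters(binary, connectivity)
            assert sorted(table.size_voxels, reverse=True) == \
                flood_fill_label(binary, connectivity)

    def test_diagonal_pair_split_by_connectivity(self):
        binary = np.zeros((4, 4, 4), bool)
        binary[1, 1, 1] = binary[2, 2, 2] = True
        assert len(label_clusters(binary, 6)) == 2
        assert len(label_clusters(binary, 26)) == 1

    def test_unknown_connectivity_rejected(self):
        with pytest.raises(ValueError):
            label_clusters(np.ones((3, 3, 3), bool), 10)

    def test_peak_world_coordinates_roundtrip(self):
        stat = np.zeros((5, 5, 5))
        stat[2, 3, 1] = 7.5
        binary = stat != 0
        table = label_clusters(binary, 26, stat=stat, affine=AFFINE3)
        world = np.array(table.iloc[0].peak_world_xyz_mm)
        ijk = np.linalg.solve(AFFINE3, np.append(world, 1.0))[:3]
        assert np.allclose(ijk, [2, 3, 1])
        assert table.iloc[0].peak_stat == 7.5


class TestMonteCarloNull:
    def test_kmin_matches_binomial_field_oracle(self):
        """At FWHM 0 the null field is iid: a direct Bernoulli-field simulation
        must give the same k_min within one voxel."""
        mask = _mask((20, 20, 20))
        null = monte_carlo_cluster_null(mask, fwhm_mm=0.0, voxel_p_threshold=0.05,
                                        n_iterations=2000, seed=3)
        rng = np.random.default_rng(99)
        from scipy import ndimage
        struct = ndimage.generate_binary_structure(3, 3)
        maxima = []
        for _ in range(2000):
            field = rng.random((20, 20, 20)) < 0.05
            labels, n = ndimage.label(field, structure=struct)
            maxima.append(np.bincount(labels.ravel())[1:].max() if n else 0)
        oracle = ClusterNull(0.05, 0.0, 2000, np.asarray(maxima))
        assert abs(null.k_min(0.05) - oracle.k_min(0.05)) <= 1

    def test_kmin_monotone_in_alpha(self, cluster_null):
        assert cluster_null.k_min(0.01) >= cluster_null.k_min(0.05) >= cluster_null.k_min(0.2)

    def test_smoothing_inflates_kmin(self):
        mask = _mask((16, 16, 16))
        k0 = monte_carlo_cluster_null(mask, 0.0, 0.05, 200, seed=5).k_min()
        k8 = monte_carlo_cluster_null(mask, 8.0, 0.05, 200, seed=5).k_min()
        assert k8 > k0

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_cluster_null(_mask((4, 4, 4)), 4.0, 0.05, 50, seed=0)


class TestCorrectedSignificance:
    def _null(self, k):
        # fabricated null whose k_min(0.05) is exactly k: order stat k-1, +1
        sizes = np.full(100, k - 1)
        return ClusterNull(0.05, 0.0, 100, sizes, 26, (6, 6, 6))

    def _statmap(self, region, t=6.0):
        stat = np.where(region, t, 0.0)
        p = np.where(region, 1e-6, 1.0)
        return fk.StatMap(stat, p, (10,), _mask((6, 6, 6)), "two_sample_t")

    def test_empty_suprathreshold_empty_table(self):
        table, sig = corrected_significance(self._statmap(np.zeros((6, 6, 6), bool)),
                                            0.05, self._null(3))
        assert len(table) == 0 and not sig.any()

    def test_cluster_exactly_at_kmin_removed(self):
        region = np.zeros((6, 6, 6), bool)
        region[1:5, 1, 1] = True  # 4-voxel cluster
        table, sig = corrected_significance(self._statmap(region), 0.05, self._null(4))
        assert len(table) == 0
        table, sig = corrected_significance(self._statmap(region), 0.05, self._null(3))
        assert len(table) == 1 and sig.sum() == 4

    def test_positive_and_negative_clusters_labeled_separately(self):
        region_pos = np.zeros((6, 6, 6), bool)
        region_pos[1:4, 1:4, 1] = True
        region_neg = np.zeros((6, 6, 6), bool)
        region_neg[4:6, 4:6, 4] = True
        stat = 5.0 * region_pos - 5.0 * region_neg
        p = np.where(region_pos | region_neg, 1e-6, 1.0)
        sm = fk.StatMap(stat, p, (10,), _mask((6, 6, 6)), "two_sample_t")
        table, _ = corrected_significance(sm, 0.05, self._null(2))
        assert set(table.sign) == {"positive", "negative"}

    def test_grid_mismatch_rejected(self):
        null = ClusterNull(0.05, 0.0, 100, np.ones(100), 26, (9, 9, 9))
        with pytest.raises(ValueError, match="grid"):
            corrected_significance(self._statmap(np.zeros((6, 6, 6), bool)), 0.05, null)


class TestOverlap:
    def test_identical_and_disjoint(self):
        a = np.zeros((5, 5, 5), bool)
        a[:2] = True
        r = overlap_stats(a, a)
        assert (r.pct_of_a, r.pct_of_b, r.pct_of_union) == (100.0, 100.0, 100.0)
        b = np.zeros((5, 5, 5), bool)
        b[3:] = True
        r = overlap_stats(a, b)
        assert (r.pct_of_a, r.pct_of_b, r.pct_of_union) == (0.0, 0.0, 0.0)

    def test_inclusion_exclusion_identity(self):
        rng = np.random.default_rng(8)
        a = rng.random((8, 8, 8)) < 0.4
        b = rng.random((8, 8, 8)) < 0.4
        r = overlap_stats(a, b)
        assert r.size_union == r.size_a + r.size_b - r.size_intersection
        assert r.pct_of_union == pytest.approx(100 * r.size_intersection / r.size_union)


class TestSummaryStatistics:
    NS = [11, 10, 8, 11, 13]

    def test_identical_means_give_p1(self):
        F, p = summary_stat_anova([5, 5], [1.0, 1.0], [0.5, 0.7])
        assert (F, p) == (0.0, 1.0)

    def test_cohort_age_row(self):
        """Five-group age summaries reproduce the reported p of about 0.97."""
        F, p = summary_stat_anova(self.NS, [29.5, 32.2, 29.5, 29.1, 32.2],
                                  [12.8, 17.5, 15.7, 13.7, 11.2])
        assert p == pytest.approx(0.97, abs=0.005)

    def test_cohort_education_row(self):
        F, p = summary_stat_anova(self.NS, [12.8, 12.2, 10.6, 11.2, 13.5],
                                  [3.4, 3.6, 3.2, 3.9, 5.0])
        assert p == pytest.approx(0.47, abs=0.005)

    def test_matches_scipy_on_raw_samples(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(i * 0.3, 1, size=n) for i, n in enumerate([6, 9, 7])]
        F, p = summary_stat_anova([len(g) for g in groups],
                                  [g.mean() for g in groups],
                                  [g.std(ddof=1) for g in groups])
        F2, p2 = stats.f_oneway(*groups)
        assert F == pytest.approx(F2, abs=1e-8) and p == pytest.approx(p2, abs=1e-8)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            summary_stat_anova([3, 3], [1, 2], [0.5, -0.1])


class TestContingency:
    def test_gender_table(self):
        """5x2 female/male counts reproduce the reported chi-squared p of 0.17."""
        chi2, df, p = contingency_chi2([[6, 5], [4, 6], [1, 7], [7, 4], [8, 5]])
        assert df == 4
        assert p == pytest.approx(0.17, abs=0.005)

    def test_proportional_rows_give_zero(self):
        chi2, df, p = contingency_chi2([[10, 20], [5, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-10) and p == pytest.approx(1.0)

    def test_perfect_association_hand_value(self):
        chi2, df, p = contingency_chi2([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0) and df == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            contingency_chi2([[0, 0], [3, 4]])


class TestOneSampleT:
    def test_matches_scipy(self):
        rng = np.random.default_rng(12)
        maps = [rng.standard_normal((3, 3, 3)) + 0.4 for _ in range(9)]
        sm = one_sample_ttest(maps, _mask((3, 3, 3)))
        t, p = stats.ttest_1samp([m[0, 1, 2] for m in maps], 0.0)
        assert sm.stat[0, 1, 2] == pytest.approx(t, abs=1e-10)
        assert sm.p[0, 1, 2] == pytest.approx(p, abs=1e-10)
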