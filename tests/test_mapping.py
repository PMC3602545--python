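"""Voxel statistics, cluster thresholding, seed series and correlation maps."""

import numpy as np
import pytest

from oracles import (brute_components, brute_pearson_map,
                     brute_region_overlap, brute_t_map)
from slfcmap.errors import EmptyIntersectionError, SpecificationError
from slfcmap.mapping import (ClusterSet, SeedSeries, StatMap,
                             clusters_to_regions, define_seed_roi,
                             extract_seed_series, factorial_interaction,
                             scale_extent, seed_correlation_map, t_contrast,
                             threshold_clusters)
from slfcmap.synthetic import SUBGROUPS, CohortSpec, generate_cohort

SHAPE = (6, 4, 6)


def random_groups(rng, n_a=4, n_b=4, shape=SHAPE):
    return (list(rng.normal(size=(n_a,) + shape)),
            list(rng.normal(size=(n_b,) + shape)))


class TestTContrast:
    def test_identical_groups_give_zero(self, rng):
        a = list(rng.normal(size=(4,) + SHAPE))
        t = t_contrast(a, list(a)).data
        assert np.allclose(t[np.isfinite(t)], 0.0)

    def test_matches_closed_form_single_voxel(self):
        a = [np.full((1, 1, 1), v) for v in (1.0, 2.0, 3.0)]
        b = [np.full((1, 1, 1), v) for v in (0.0, 0.5, 1.0)]
        # pooled t by hand: means 2.0 / 0.5, s²_a = 1.0, s²_b = 0.25
        sp2 = (2 * 1.0 + 2 * 0.25) / 4
        expected = 1.5 / np.sqrt(sp2 * (2 / 3))
        assert t_contrast(a, b).data[0, 0, 0] == pytest.approx(expected)

    def test_swapping_groups_negates_map(self, rng):
        a, b = random_groups(rng)
        ab = t_contrast(a, b).data
        ba = t_contrast(b, a).data
        assert np.allclose(ab, -ba, equal_nan=True)

    def test_zero_variance_voxels_undefined_and_counted(self):
        a = [np.zeros(SHAPE) for _ in range(3)]
        b = [np.zeros(SHAPE) for _ in range(3)]
        smap = t_contrast(a, b)
        assert np.isnan(smap.data).all()
        assert smap.n_undefined == np.prod(SHAPE)

    def test_group_size_validated(self, rng):
        with pytest.raises(SpecificationError):
            t_contrast([rng.normal(size=SHAPE)], list(rng.normal(size=(3,) + SHAPE)))


class TestFactorialInteraction:
    @staticmethod
    def _cells(rng, ns=(4, 4, 4, 4), mu=(0, 0, 0, 0)):
        keys = [("WAS", 60), ("WAS", 0), ("sham", 60), ("sham", 0)]
        return {k: list(m + rng.normal(size=(n,) + SHAPE))
                for k, n, m in zip(keys, ns, mu)}

    def test_equal_cell_means_zero_at_noise_free_voxels(self):
        # identical cell means (5.0) with unequal n and nonzero variance
        cells = {k: [np.full(SHAPE, 5.0 + i - (n - 1) / 2) for i in range(n)]
                 for k, n in zip([("WAS", 60), ("WAS", 0), ("sham", 60),
                                  ("sham", 0)], (3, 4, 3, 5))}
        t = factorial_interaction(cells).data
        assert np.allclose(t, 0.0)

    def test_df_is_total_n_minus_4(self, rng):
        cells = self._cells(rng, ns=(4, 3, 5, 4))
        assert factorial_interaction(cells).df == 16 - 4

    def test_missing_cell_rejected(self, rng):
        cells = self._cells(rng)
        del cells[("sham", 0)]
        with pytest.raises(SpecificationError):
            factorial_interaction(cells)

    def test_recovers_effect_planted_in_single_cell(self, small_atlas):
        """An OD offset present only in the WAS-60 cell drives the
        interaction map in that region, with positive sign, in ≥90 % of
        replicates at the scaled default thresholds."""
        grid = (20, 10, 20)
        region = small_atlas.region_mask("CeA")
        extent = scale_extent(int(np.prod(grid)))
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            spec = CohortSpec(grid_shape=grid, n_per_subgroup=10,
                              region_effects={"CeA": {("WAS", 60): 0.75}},
                              rng_seed=3000 + rep)
            vols, _ = generate_cohort(spec, small_atlas)
            cells = {sg: [v for v in vols if v.subgroup == sg]
                     for sg in SUBGROUPS}
            smap = factorial_interaction(cells)
            clusters = threshold_clusters(smap, 0.05, extent)
            cov = (clusters.mask(sign=+1) & region).sum()
            hits += cov >= region.sum() / 2
        assert hits >= 0.9 * n_rep


class TestThresholdClusters:
    @staticmethod
    def _tmap(data, df=10):
        return StatMap(np.asarray(data, float), kind="t", df=df)

    def test_extent_boundary_just_below(self):
        # one connected 99-voxel block: rows 0-8 of a plane plus 9 voxels
        data = np.zeros((10, 10, 10))
        plane = np.zeros((10, 10), bool)
        plane.ravel()[:99] = True
        data[:, :, 0][plane] = 10.0
        smap = self._tmap(data)
        assert int((data >= smap.t_critical(0.05)).sum()) == 99
        assert len(threshold_clusters(smap, 0.05, extent=100)) == 0
        assert len(threshold_clusters(smap, 0.05, extent=99)) == 1

    def test_two_disjoint_blocks_reported_with_sizes(self):
        data = np.zeros((12, 12, 12))
        data[0:6, 0:5, 0:5] = 10.0     # 150 voxels
        data[8:12, 6:12, 7:12] = 10.0  # 120 voxels
        clusters = threshold_clusters(self._tmap(data), 0.05, extent=100)
        assert sorted(c.size for c in clusters) == [120, 150]

    def test_adjacent_opposite_signs_never_merged(self):
        data = np.zeros((8, 4, 4))
        data[0:4] = 10.0
        data[4:8] = -10.0
        clusters = threshold_clusters(self._tmap(data), 0.05, extent=10)
        assert sorted(c.sign for c in clusters) == [-1, 1]
        assert all(c.size == 64 for c in clusters)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_bfs_flood_fill_oracle(self, rng, connectivity):
        smap_df = 8
        tcrit = self._tmap(np.zeros(1), df=smap_df).t_critical(0.05)
        for _ in range(30):
            data = rng.normal(scale=2.0, size=(6, 6, 6))
            clusters = threshold_clusters(self._tmap(data, df=smap_df),
                                          0.05, extent=1,
                                          connectivity=connectivity)
            for sign in (+1, -1):
                got = sorted(
                    tuple(sorted(map(tuple, c.voxels)))
                    for c in clusters if c.sign == sign)
                want = sorted(
                    tuple(sorted(comp))
                    for comp in brute_components(sign * data >= tcrit,
                                                 connectivity))
                assert got == want

    def test_peak_is_extreme_voxel(self, rng):
        data = rng.normal(scale=3.0, size=(6, 6, 6))
        for c in threshold_clusters(self._tmap(data), 0.05, extent=1):
            vals = data[tuple(c.voxels.T)]
            assert c.peak_stat == pytest.approx(
                vals[np.argmax(c.sign * vals)])


class TestScaleExtent:
    def test_monotone_in_grid_size(self):
        small = scale_extent(10_000)
        large = scale_extent(10_000_000)
        assert small <= large

    def test_full_scale_grid_keeps_paper_extent(self):
        from slfcmap.mapping import REFERENCE_FULLSCALE_VOXELS
        assert scale_extent(REFERENCE_FULLSCALE_VOXELS) == 100

    def test_smoothed_floor_spans_equivalent_resels(self):
        ext = scale_extent(32_000, smoothing_fwhm_vox=(3.0, 2.3548, 3.0))
        assert ext == int(np.ceil(100 / 9 * 3.0 * 2.3548 * 3.0))


class TestSeedSeries:
    def test_constant_volume_gives_constant(self, rng):
        from slfcmap.volume import BrainVolume
        vols = [BrainVolume(np.full(SHAPE, c)) for c in (1.0, 2.0, 5.0)]
        roi = np.zeros(SHAPE, bool)
        roi[1:3, 1:3, 1:3] = True
        series = extract_seed_series(vols, roi)
        assert np.allclose(series.values, [1.0, 2.0, 5.0])

    def test_single_voxel_roi(self, rng):
        from slfcmap.volume import BrainVolume
        vols = [BrainVolume(rng.normal(size=SHAPE)) for _ in range(3)]
        roi = np.zeros(SHAPE, bool)
        roi[2, 2, 2] = True
        series = extract_seed_series(vols, roi)
        assert np.allclose(series.values, [v.data[2, 2, 2] for v in vols])

    def test_matches_brute_force_mean(self, rng):
        from slfcmap.volume import BrainVolume
        vols = [BrainVolume(rng.normal(size=SHAPE)) for _ in range(4)]
        roi = rng.random(SHAPE) > 0.5
        series = extract_seed_series(vols, roi)
        for val, v in zip(series.values, vols):
            acc = [v.data[idx] for idx in np.ndindex(*SHAPE) if roi[idx]]
            assert val == pytest.approx(np.mean(acc))

    def test_roi_outside_mask_rejected(self, rng):
        from slfcmap.volume import BrainVolume
        vols = [BrainVolume(rng.normal(size=SHAPE)) for _ in range(3)]
        roi = np.ones(SHAPE, bool)
        mask = np.zeros(SHAPE, bool)
        mask[0:3] = True
        with pytest.raises(SpecificationError, match="outside the mask"):
            extract_seed_series(vols, roi, mask=mask)


class TestDefineSeedRoi:
    @staticmethod
    def _clusters(mask3d, sign=+1):
        voxels = np.argwhere(mask3d)
        from slfcmap.mapping import Cluster
        cluster = Cluster(voxels=voxels, sign=sign, size=len(voxels),
                          peak_stat=5.0 * sign,
                          peak_ijk=tuple(voxels[0]))
        return ClusterSet([cluster], voxel_p=0.05, extent=1, df=10,
                          shape=mask3d.shape)

    def test_cluster_superset_returns_region(self):
        region = np.zeros(SHAPE, bool); region[1:3, 1:3, 1:3] = True
        roi = define_seed_roi(region, self._clusters(np.ones(SHAPE, bool)))
        assert np.array_equal(roi, region)

    def test_disjoint_raises(self):
        region = np.zeros(SHAPE, bool); region[0, 0, 0] = True
        blob = np.zeros(SHAPE, bool); blob[3:, 3:, 3:] = True
        with pytest.raises(EmptyIntersectionError):
            define_seed_roi(region, self._clusters(blob))

    def test_negative_clusters_do_not_define_roi(self):
        region = np.ones(SHAPE, bool)
        with pytest.raises(EmptyIntersectionError):
            define_seed_roi(region, self._clusters(region, sign=-1))

    def test_partial_overlap_equals_brute_intersection(self, rng):
        region = rng.random(SHAPE) > 0.4
        blob = rng.random(SHAPE) > 0.4
        if not (region & blob).any():
            pytest.skip("degenerate draw")
        roi = define_seed_roi(region, self._clusters(blob))
        assert np.array_equal(roi, region & blob)


class TestSeedCorrelationMap:
    def test_perfect_linear_coupling_gives_r_one(self):
        from slfcmap.volume import BrainVolume
        seeds = np.array([1.0, 2.0, 3.0, 4.0])
        vols = [BrainVolume(np.full(SHAPE, 1.0) * s) for s in seeds]
        series = SeedSeries(seeds, [f"a{i}" for i in range(4)])
        smap = seed_correlation_map(vols, series)
        assert np.allclose(smap.r_data, 1.0)
        assert np.isinf(smap.data).all() or (smap.data > 50).all()

    def test_matches_pearson_oracle(self, rng):
        from slfcmap.volume import BrainVolume
        x = rng.normal(size=(8,) + SHAPE)
        seeds = rng.normal(size=8)
        smap = seed_correlation_map([BrainVolume(v) for v in x],
                                    SeedSeries(seeds, [str(i) for i in range(8)]))
        r_ref, t_ref = brute_pearson_map(x, seeds)
        assert np.allclose(smap.r_data, r_ref, atol=1e-10)
        assert np.allclose(smap.data, t_ref, atol=1e-8)

    def test_permutation_null_rate_near_nominal(self, rng):
        """Randomly permuted seed values give ≈ the nominal 5 % one-sided
        suprathreshold voxel rate."""
        from slfcmap.volume import BrainVolume
        shape = (10, 8, 10)
        hits = total = 0
        for _ in range(40):
            x = rng.normal(size=(10,) + shape)
            seeds = rng.permutation(rng.normal(size=10))
            smap = seed_correlation_map([BrainVolume(v) for v in x],
                                        SeedSeries(seeds, [str(i) for i in range(10)]))
            hits += int((smap.data >= smap.t_critical(0.05)).sum())
            total += int(np.isfinite(smap.data).sum())
        rate = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 4 * se

    def test_zero_variance_seed_rejected(self, rng):
        from slfcmap.volume import BrainVolume
        vols = [BrainVolume(rng.normal(size=SHAPE)) for _ in range(4)]
        with pytest.raises(SpecificationError, match="zero variance"):
            seed_correlation_map(vols, SeedSeries(np.ones(4), list("abcd")))


class TestClustersToRegions:
    def test_cluster_inside_single_region(self, small_atlas):
        region = small_atlas.region_mask("La")
        voxels = np.argwhere(region)[:50]
        from slfcmap.mapping import Cluster
        cs = ClusterSet([Cluster(voxels, +1, 50, 4.0, tuple(voxels[0]))],
                        0.05, 5, 10, shape=small_atlas.labels.shape)
        table = clusters_to_regions(cs, small_atlas)
        assert list(table.region) == ["La"]
        assert table.overlap_voxels.iloc[0] == 50

    def test_straddling_cluster_counts_match_brute_force(self, small_atlas):
        la = np.argwhere(small_atlas.region_mask("La"))[:60]
        cea = np.argwhere(small_atlas.region_mask("CeA"))[:40]
        voxels = np.vstack([la, cea])
        from slfcmap.mapping import Cluster
        cs = ClusterSet([Cluster(voxels, -1, 100, -4.0, tuple(voxels[0]))],
                        0.05, 5, 10, shape=small_atlas.labels.shape)
        table = clusters_to_regions(cs, small_atlas)
        counts = brute_region_overlap(voxels, small_atlas.labels)
        got = dict(zip(table.region, table.overlap_voxels))
        assert got == {"La": counts[small_atlas.label_of("La")],
                       "CeA": counts[small_atlas.label_of("CeA")]}

    def test_empty_cluster_set_gives_empty_table(self, small_atlas):
        cs = ClusterSet([], 0.05, 5, 10, shape=small_atlas.labels.shape)
        assert clusters_to_regions(cs, small_atlas).empty


def test_null_two_sample_t_matches_brute_force_oracle(rng):
    """Vectorized t map equals per-voxel scipy computation exactly."""
    a, b = random_groups(rng, 5, 4)
    smap = t_contrast(a, b)
    ref = brute_t_map(np.stack(a), np.stack(b))
    assert np.allclose(smap.data, ref, atol=1e-10, equal_nan=True)
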