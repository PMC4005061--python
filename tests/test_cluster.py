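import numpy as np
import pytest
import scipy.stats

from alffpipe import (
    BrainMask,
    ClusterSimParams,
    MaxClusterDistribution,
    ScalarMap,
    VoxelGrid,
    apply_cluster_correction,
    cluster_extent_threshold,
    label_clusters,
    simulate_max_cluster_null,
    smooth_gaussian,
)
from alffpipe.cluster import FWHM_TO_SIGMA, _iter_null_fields
from _oracles import flood_fill_components


class TestSmoothGaussian:
    def test_fwhm_zero_is_identity(self):
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((6, 6, 6))
        out = smooth_gaussian(vol, 0.0, (3.0, 3.0, 3.0))
        assert np.array_equal(out, vol)
        assert out is not vol

    def test_impulse_response_matches_analytic_gaussian(self):
        # ratios of the response to an impulse are exactly exp(-d^2/2 sigma^2)
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        fwhm, voxel = 8.0, 4.0
        out = smooth_gaussian(vol, fwhm, (voxel,) * 3)
        sigma_vox = fwhm * FWHM_TO_SIGMA / voxel
        for d in range(1, 5):
            expected = np.exp(-(d**2) / (2.0 * sigma_vox**2))
            assert out[10 + d, 10, 10] / out[10, 10, 10] == pytest.approx(
                expected, rel=1e-6
            )
            assert out[10, 10 - d, 10] / out[10, 10, 10] == pytest.approx(
                expected, rel=1e-6
            )

    def test_mass_conserved_for_interior_support(self):
        rng = np.random.default_rng(1)
        vol = np.zeros((30, 30, 30))
        vol[13:17, 13:17, 13:17] = rng.random((4, 4, 4))
        out = smooth_gaussian(vol, 6.0, (3.0, 3.0, 3.0), mode="constant")
        assert out.sum() == pytest.approx(vol.sum(), rel=1e-6)

    def test_anisotropic_voxels_scale_per_axis(self):
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        out = smooth_gaussian(vol, 8.0, (2.0, 4.0, 4.0))
        # narrower voxels along x -> wider kernel in voxel units -> flatter
        assert out[11, 10, 10] > out[10, 11, 10]

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(np.zeros((4, 4, 4)), -1.0, (3.0,) * 3)


class TestLabelClusters:
    def test_corner_touching_voxels(self):
        vol = np.zeros((4, 4, 4), dtype=bool)
        vol[0, 0, 0] = vol[1, 1, 1] = True
        assert label_clusters(vol, 6).n_clusters == 2
        assert label_clusters(vol, 18).n_clusters == 2
        assert label_clusters(vol, 26).n_clusters == 1

    def test_edge_touching_voxels(self):
        vol = np.zeros((4, 4, 4), dtype=bool)
        vol[0, 0, 0] = vol[1, 1, 0] = True
        assert label_clusters(vol, 6).n_clusters == 2
        assert label_clusters(vol, 18).n_clusters == 1

    def test_all_false(self):
        cs = label_clusters(np.zeros((5, 5, 5), dtype=bool), 26)
        assert cs.n_clusters == 0
        assert cs.sizes.size == 0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(100 + connectivity)
        for _ in range(25):
            vol = rng.random((8, 8, 8)) < 0.4
            cs = label_clusters(vol, connectivity)
            assert sorted(cs.sizes.tolist()) == flood_fill_components(vol, connectivity)

    def test_peaks_report_world_coordinates_and_tie_break(self):
        grid = VoxelGrid.isotropic((5, 5, 5), 3.0)
        vals = np.zeros(grid.shape)
        vol = np.zeros(grid.shape, dtype=bool)
        vol[1, 1, 1] = vol[1, 1, 2] = True
        vals[1, 1, 1] = vals[1, 1, 2] = -4.0   # tie -> smallest linear index
        cs = label_clusters(vol, 26, grid=grid, values=vals)
        peak_val, xyz = cs.peaks[0]
        assert peak_val == -4.0
        assert np.allclose(xyz, grid.voxel_to_world(np.array([1, 1, 1])))


def tiny_params(**kw):
    grid = VoxelGrid.isotropic(kw.pop("shape", (10, 10, 8)), 3.0)
    mask = kw.pop("mask", BrainMask(grid, np.ones(grid.shape, dtype=bool)))
    kw.setdefault("n_iter", 100)
    kw.setdefault("seed", 5)
    return ClusterSimParams(mask=mask, **kw)


class TestNullSimulation:
    def test_saturation_limit_every_voxel_survives(self):
        # one-tailed threshold far in the left tail: all voxels exceed it
        with np.errstate(all="ignore"):
            p = tiny_params(fwhm_mm=0.0, voxel_p=1 - 1e-12, two_tailed=False)
            dist = simulate_max_cluster_null(p)
        assert np.all(dist.max_sizes == p.mask.n_voxels)

    def test_isolated_voxel_mask_gives_singletons(self):
        # checkerboard mask: no two masked voxels are 6-adjacent
        grid = VoxelGrid.isotropic((10, 10, 8), 3.0)
        idx = np.indices(grid.shape).sum(axis=0)
        mask = BrainMask(grid, idx % 2 == 0)
        p = tiny_params(mask=mask, fwhm_mm=0.0, voxel_p=0.05, connectivity=6,
                        n_iter=200)
        dist = simulate_max_cluster_null(p)
        assert dist.max_sizes.max() == 1      # singletons only
        # P(no survivor among 400 voxels at p=.05) ~ 1e-9: all iterations hit
        assert dist.max_sizes.min() == 1

    @pytest.mark.parametrize("fwhm", [0.0, 8.0])
    def test_survival_fraction_equals_voxel_p(self, fwhm):
        # the post-smoothing variance rescale keeps the per-voxel exceedance
        # at its nominal level for any kernel width
        p = tiny_params(shape=(16, 16, 12), fwhm_mm=fwhm, voxel_p=0.05, seed=9)
        rng = np.random.default_rng(17)
        z = p.z_threshold
        count = total = 0
        n_fields = 100
        it = _iter_null_fields(
            ClusterSimParams(mask=p.mask, fwhm_mm=fwhm, voxel_p=0.05,
                             n_iter=n_fields, seed=23), rng)
        for f in it:
            count += int((np.abs(f[p.mask.data]) > z).sum())
            total += p.mask.n_voxels
        frac = count / total
        # correlated voxels within a field: SE from the number of fields,
        # conservatively using one effective draw per resel
        n_eff = n_fields * max(p.mask.n_voxels / max((fwhm / 3.0) ** 3, 1.0), 1.0)
        se = np.sqrt(0.05 * 0.95 / n_eff)
        assert abs(frac - 0.05) < 3 * se

    def test_larger_fwhm_gives_stochastically_larger_clusters(self):
        p0 = tiny_params(shape=(14, 14, 10), fwhm_mm=0.0, n_iter=300, seed=2)
        p8 = tiny_params(shape=(14, 14, 10), fwhm_mm=8.0, n_iter=300, seed=2)
        d0 = simulate_max_cluster_null(p0)
        d8 = simulate_max_cluster_null(p8)
        stat = scipy.stats.mannwhitneyu(d8.max_sizes, d0.max_sizes,
                                        alternative="greater")
        assert stat.pvalue < 0.01

    def test_reproducible_from_seed(self):
        p = tiny_params(fwhm_mm=6.0)
        a = simulate_max_cluster_null(p)
        b = simulate_max_cluster_null(p)
        assert np.array_equal(a.max_sizes, b.max_sizes)

    def test_small_mask_warns_not_errors(self):
        grid = VoxelGrid.isotropic((4, 4, 4), 3.0)
        mask = BrainMask(grid, np.ones(grid.shape, dtype=bool))
        with pytest.warns(UserWarning, match="kernel"):
            simulate_max_cluster_null(
                ClusterSimParams(mask=mask, fwhm_mm=8.0, n_iter=100, seed=1))


class TestExtentThreshold:
    def test_all_zero_null_makes_any_cluster_significant(self):
        p = tiny_params()
        dist = MaxClusterDistribution(np.zeros(p.n_iter, dtype=int), p)
        s, mm3 = cluster_extent_threshold(dist, 0.05)
        assert s == 1
        assert mm3 == pytest.approx(27.0)

    def test_uniform_multiset_counting_oracle(self):
        p = tiny_params()
        sizes = np.arange(1, 101)
        dist = MaxClusterDistribution(sizes, tiny_params(n_iter=100))
        s, _ = cluster_extent_threshold(dist, 0.05)
        # direct counting oracle: smallest s with #(max >= s)/100 <= 0.05
        oracle = next(k for k in range(1, 102)
                      if (sizes >= k).sum() / 100 <= 0.05)
        assert s == oracle == 96

    def test_alpha_one_never_exceeds_a_single_voxel(self):
        dist = MaxClusterDistribution(np.full(100, 7), tiny_params(n_iter=100))
        s, _ = cluster_extent_threshold(dist, 1.0)
        assert s == 1

    def test_unattainable_alpha_warns(self):
        dist = MaxClusterDistribution(np.full(100, 5), tiny_params(n_iter=100))
        with pytest.warns(UserWarning, match="unattainable"):
            s, _ = cluster_extent_threshold(dist, 0.005)
        assert s == 6

    def test_monotone_nonincreasing_in_alpha(self):
        rng = np.random.default_rng(3)
        dist = MaxClusterDistribution(rng.integers(0, 50, size=500),
                                      tiny_params(n_iter=500))
        alphas = [0.01, 0.05, 0.1, 0.5]
        thresholds = [cluster_extent_threshold(dist, a)[0] for a in alphas]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))

    def test_round_trip_tsv(self, tmp_path):
        p = tiny_params(n_iter=100)
        dist = simulate_max_cluster_null(p)
        path = tmp_path / "null.tsv"
        dist.to_tsv(path)
        import pandas as pd

        back = pd.read_csv(path, sep="\t", comment="#")
        assert np.array_equal(back["max_size"].to_numpy(), dist.max_sizes)


class TestApplyCorrection:
    def make_tmap(self, shape=(12, 12, 10)):
        grid = VoxelGrid.isotropic(shape, 3.0)
        mask = BrainMask(grid, np.ones(shape, dtype=bool))
        return grid, mask

    def test_all_zero_tmap_empty(self):
        grid, mask = self.make_tmap()
        cs = apply_cluster_correction(
            ScalarMap(grid, np.zeros(grid.shape), "tstat"), df=30,
            voxel_p=0.05, extent_voxels=10, mask=mask)
        assert cs.n_clusters == 0

    @pytest.mark.parametrize("extent,expected", [(20, 1), (31, 0)])
    def test_extent_filter_on_a_30_voxel_blob(self, extent, expected):
        grid, mask = self.make_tmap()
        t = np.zeros(grid.shape)
        t[3:8, 4:7, 5:7] = 5.0          # 5*3*2 = 30 voxels
        cs = apply_cluster_correction(ScalarMap(grid, t, "tstat"), df=30,
                                      voxel_p=0.05, extent_voxels=extent,
                                      mask=mask)
        assert cs.n_clusters == expected
        if expected:
            assert cs.sizes[0] == 30
            assert cs.directions == ["pos"]
            assert cs.peaks[0][0] == 5.0

    def test_opposite_tails_reported_separately(self):
        grid, mask = self.make_tmap()
        t = np.zeros(grid.shape)
        t[2:5, 2:5, 2:5] = 6.0
        t[5:8, 2:5, 2:5] = -6.0          # adjacent block, opposite sign
        cs = apply_cluster_correction(ScalarMap(grid, t, "tstat"), df=20,
                                      voxel_p=0.05, extent_voxels=5, mask=mask)
        assert cs.n_clusters == 2
        assert sorted(cs.directions) == ["neg", "pos"]
        assert np.all(cs.sizes == 27)

    def test_subthreshold_t_is_invisible(self):
        grid, mask = self.make_tmap()
        t = np.full(grid.shape, 1.0)     # |t|=1 < t_crit for p=.05
        cs = apply_cluster_correction(ScalarMap(grid, t, "tstat"), df=30,
                                      voxel_p=0.05, extent_voxels=1, mask=mask)
        assert cs.n_clusters == 0
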