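import numpy as np
import pytest
from scipy import ndimage, stats

from lctau.core_io import BrainVolume
from lctau.exceptions import DegenerateClusterError, SingularDesignError
from lctau.synthetic import CohortSimSpec, gen_cohort, make_blob
from lctau.voxelwise import (
    compare_directions,
    extract_clusters,
    fit_interaction,
    fit_voxelwise,
    mc_cluster_threshold,
    residualize_against,
)

from oracles import ols_full

AFF = np.diag([2.0, 2.0, 2.0, 1.0])


def _vols(arr):
    """(n_subjects, x, y, z) array -> list of BrainVolumes."""
    return [BrainVolume(a, AFF) for a in arr]


def _mask(shape):
    return BrainVolume(np.ones(shape), AFF)


class TestFitVoxelwise:
    def test_perfect_fit(self, rng):
        shape = (3, 3, 3)
        pred = rng.standard_normal(10)
        outs = np.tile(pred[:, None, None, None], (1, *shape))
        res = fit_voxelwise(_vols(outs), pred, mask=_mask(shape))
        np.testing.assert_allclose(res.beta_map.data, 1.0, atol=1e-10)
        # clamped CDF path: z finite and huge
        assert np.all(np.isfinite(res.z_map.data))
        assert res.z_map.data.min() > 6

    def test_single_voxel_matches_explicit_ols(self, rng):
        n = 40
        pred = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        y = 0.7 * pred + cov @ [0.3, -0.2] + rng.standard_normal(n)
        outs = y[:, None, None, None] * np.ones((1, 1, 1, 1))
        res = fit_voxelwise(_vols(outs), pred, cov, _mask((1, 1, 1)))
        X = np.column_stack([np.ones(n), pred, cov])
        beta, se, t, df = ols_full(y, X)
        assert res.beta_map.data[0, 0, 0] == pytest.approx(beta[1],
                                                           abs=1e-10)
        assert res.t_map.data[0, 0, 0] == pytest.approx(t[1], abs=1e-10)
        assert res.df == df

    def test_null_calibration(self, rng):
        shape = (8, 8, 8)  # 512 independent voxels
        n = 60
        pred = rng.standard_normal(n)
        outs = rng.standard_normal((n, *shape))
        res = fit_voxelwise(_vols(outs), pred, mask=_mask(shape))
        frac = np.mean(res.z_map.data > 1.64)
        p0 = stats.norm.sf(1.64)
        tol = 3 * np.sqrt(p0 * (1 - p0) / np.prod(shape))
        assert abs(frac - p0) <= tol

    def test_rank_deficient_design(self, rng):
        n = 20
        pred = rng.standard_normal(n)
        cov = np.column_stack([pred * 2.0])  # collinear with predictor
        outs = rng.standard_normal((n, 2, 2, 2))
        with pytest.raises(SingularDesignError):
            fit_voxelwise(_vols(outs), pred, cov, _mask((2, 2, 2)))

    def test_complete_cases_dropped(self, rng):
        n = 30
        pred = rng.standard_normal(n)
        pred[3] = np.nan
        outs = rng.standard_normal((n, 2, 2, 2))
        res = fit_voxelwise(_vols(outs), pred, mask=_mask((2, 2, 2)))
        assert res.n_used == n - 1
        assert res.df == n - 1 - 2

    def test_z_invariant_under_affine_outcome_rescale(self, rng):
        shape = (3, 3, 3)
        n = 25
        pred = rng.standard_normal(n)
        outs = rng.standard_normal((n, *shape)) + 0.4 * pred[
            :, None, None, None]
        r1 = fit_voxelwise(_vols(outs), pred, mask=_mask(shape))
        r2 = fit_voxelwise(_vols(outs * 3.0 + 5.0), pred, mask=_mask(shape))
        np.testing.assert_allclose(r1.z_map.data, r2.z_map.data, atol=1e-10)

    def test_partial_r_identity(self, rng):
        shape = (4, 4, 4)
        n = 30
        pred = rng.standard_normal(n)
        outs = rng.standard_normal((n, *shape)) + 0.3 * pred[
            :, None, None, None]
        res = fit_voxelwise(_vols(outs), pred, mask=_mask(shape))
        r = res.partial_r()
        t = res.t_map.data[res.mask.require_mask()]
        np.testing.assert_allclose(r * r, t * t / (t * t + res.df),
                                   atol=1e-12)


class TestResidualize:
    def test_orthogonal_nuisance_means_removed_only(self, rng):
        shape = (2, 2, 2)
        n = 20
        nuis = np.concatenate([np.ones(10), -np.ones(10)])  # zero-mean
        outs = rng.standard_normal((n, *shape))
        # make outcome orthogonal to nuisance by construction
        outs = outs - (outs * nuis[:, None, None, None]).mean(0) * \
            nuis[:, None, None, None] / (nuis ** 2).mean()
        res = residualize_against(_vols(outs), nuis)
        stacked = np.stack([v.data for v in res])
        np.testing.assert_allclose(stacked, outs - outs.mean(0), atol=1e-8)

    def test_residuals_orthogonal(self, rng):
        shape = (3, 3, 3)
        n = 25
        nuis = rng.standard_normal(n)
        outs = 2.0 * nuis[:, None, None, None] + rng.standard_normal(
            (n, *shape)) * 0.1
        res = residualize_against(_vols(outs), nuis)
        stacked = np.stack([v.data for v in res]).reshape(n, -1)
        inner = np.abs(stacked.T @ nuis)
        assert inner.max() < 1e-8
        # residual variance approx var(noise)
        assert np.median(stacked.var(axis=0, ddof=2)) == pytest.approx(
            0.01, rel=0.35)


class TestInteraction:
    def test_centering_invariance_of_product_term(self, rng):
        shape = (2, 2, 2)
        n = 50
        x = rng.standard_normal(n)
        m = rng.standard_normal(n)
        outs = rng.standard_normal((n, *shape)) + 0.5 * (x * m)[
            :, None, None, None]
        r1 = fit_interaction(_vols(outs), x, m, mask=_mask(shape))
        r2 = fit_interaction(_vols(outs), x, m + 100.0, mask=_mask(shape))
        np.testing.assert_allclose(r1.beta_map.data, r2.beta_map.data,
                                   atol=1e-8)
        np.testing.assert_allclose(r1.z_map.data, r2.z_map.data, atol=1e-7)

    def test_null_interaction_calibrated(self, rng):
        shape = (8, 8, 8)
        n = 80
        x = rng.standard_normal(n)
        m = rng.standard_normal(n)
        outs = rng.standard_normal((n, *shape)) + 0.5 * x[
            :, None, None, None] + 0.3 * m[:, None, None, None]
        res = fit_interaction(_vols(outs), x, m, mask=_mask(shape))
        frac = np.mean(res.z_map.data > 1.64)
        p0 = stats.norm.sf(1.64)
        tol = 3 * np.sqrt(p0 * (1 - p0) / np.prod(shape))
        assert abs(frac - p0) <= tol


class TestMcClusterThreshold:
    def test_matches_bruteforce_from_distribution(self):
        mask = _mask((10, 10, 10))
        ext, sizes = mc_cluster_threshold(
            mask, smoothing_fwhm_mm=0.0, voxel_z_threshold=1.64,
            alpha=0.05, n_iter=300, seed=0, return_distribution=True)
        order = np.sort(sizes)
        k = int(np.ceil(0.95 * 300))
        assert ext == order[k - 1] + 1

    def test_unsmoothed_suprathreshold_fraction(self, rng):
        # one unsmoothed standardized draw: ~5% of voxels above 1.64
        mask = _mask((20, 20, 20))
        _, sizes = mc_cluster_threshold(
            mask, 0.0, 1.64, 0.05, n_iter=100, seed=1,
            return_distribution=True)
        noise = rng.standard_normal((20, 20, 20))
        z = (noise - noise.mean()) / noise.std()
        frac = np.mean(z > 1.64)
        p0 = stats.norm.sf(1.64)
        assert abs(frac - p0) <= 3 * np.sqrt(p0 * (1 - p0) / 8000)

    def test_warns_when_fwhm_below_voxel(self):
        with pytest.warns(UserWarning, match="smoothing skipped"):
            mc_cluster_threshold(_mask((6, 6, 6)), smoothing_fwhm_mm=1.0,
                                 n_iter=100, seed=0)

    def test_monotone_in_z_threshold_and_fwhm(self):
        mask = _mask((10, 10, 10))
        exts_z = [mc_cluster_threshold(mask, 0.0, z, 0.05, 200, seed=3)
                  for z in (1.0, 1.64, 2.3)]
        assert exts_z == sorted(exts_z, reverse=True)
        exts_f = [mc_cluster_threshold(mask, f, 1.64, 0.05, 200, seed=3)
                  for f in (0.0, 4.0, 8.0)]
        assert exts_f == sorted(exts_f)

    def test_deterministic_given_seed(self):
        mask = _mask((8, 8, 8))
        a = mc_cluster_threshold(mask, 4.0, 1.64, 0.05, 150, seed=9)
        b = mc_cluster_threshold(mask, 4.0, 1.64, 0.05, 150, seed=9)
        assert a == b

    def test_rejects_tiny_n_iter(self):
        with pytest.raises(ValueError):
            mc_cluster_threshold(_mask((4, 4, 4)), n_iter=50)


class TestExtractClusters:
    def test_all_zero_map(self):
        shape = (5, 5, 5)
        cs = extract_clusters(BrainVolume(np.zeros(shape), AFF),
                              _mask(shape), 1.64, 5)
        assert cs.n_clusters == 0

    def test_extent_filter_semantics(self):
        shape = (10, 10, 10)
        z = np.zeros(shape)
        blob30 = make_blob(shape, (3, 3, 3), radius=2)[:30]
        blob3 = [(8, 8, 8), (8, 8, 9), (8, 9, 8)]
        for p in blob30:
            z[p] = 3.0
        for p in blob3:
            z[p] = 3.0
        cs = extract_clusters(BrainVolume(z, AFF), _mask(shape), 1.64, 10)
        assert cs.sizes == [30]
        assert np.all(cs.label_map.data[z < 1.64] == 0)

    def test_labels_sorted_by_descending_size(self):
        shape = (12, 12, 4)
        z = np.zeros(shape)
        z[0:2, 0:3, 0] = 3.0   # size 6
        z[8:10, 8:10, 0] = 3.0  # size 4
        cs = extract_clusters(BrainVolume(z, AFF), _mask(shape), 1.64, 2)
        assert cs.sizes == [6, 4]
        assert np.all(cs.label_map.data[0:2, 0:3, 0] == 1)

    def test_recovers_planted_cluster(self):
        spec = CohortSimSpec(n_subjects=120, grid_shape=(12, 12, 12),
                             beta_lc_tau=0.5, noise_sd_tau=0.2, seed=11)
        cohort, _, fu, mask, truth = gen_cohort(spec)
        res = fit_voxelwise(fu, cohort["intensity_r_bl"].to_numpy(),
                            cohort[["age", "sex"]], mask)
        ext = mc_cluster_threshold(mask, 0.0, 1.64, 0.05, 300, seed=5)
        cs = extract_clusters(res.z_map, mask, 1.64, ext)
        assert cs.n_clusters >= 1
        planted = np.zeros(mask.shape, bool)
        for p in truth["mtl_cluster_voxels"]:
            planted[tuple(p)] = True
        found = cs.cluster_mask(1)
        dice = 2 * (planted & found).sum() / (planted.sum() + found.sum())
        assert dice >= 0.5


class TestCompareDirections:
    def _cluster_set(self, shape, voxels):
        lab = np.zeros(shape, int)
        for p in voxels:
            lab[p] = 1
        from lctau.voxelwise import ClusterSet
        return ClusterSet(BrainVolume(lab, AFF), [len(voxels)], 1.64,
                          1, 0.05)

    def test_identical_directions(self, rng):
        shape = (6, 6, 6)
        n = 30
        pred = rng.standard_normal(n)
        outs = rng.standard_normal((n, *shape)) + 0.5 * pred[
            :, None, None, None]
        res = fit_voxelwise(_vols(outs), pred, mask=_mask(shape))
        voxels = [(i, j, 0) for i in range(4) for j in range(4)]
        cs = self._cluster_set(shape, voxels)
        comp = compare_directions(res, res, cs)[0]
        assert comp.t_stat == 0.0
        assert comp.mean_difference == 0.0
        assert comp.pearson_r == pytest.approx(1.0)
        assert comp.df == len(voxels) - 1

    def test_forward_effect_only_positive_difference(self):
        spec = CohortSimSpec(n_subjects=150, grid_shape=(10, 10, 10),
                             beta_lc_tau=0.6, noise_sd_tau=0.2, seed=21)
        cohort, bl, fu, mask, truth = gen_cohort(spec)
        lc = cohort["intensity_r_bl"].to_numpy()
        cov = cohort[["age", "sex"]]
        forward = fit_voxelwise(fu, lc, cov, mask)
        reverse = fit_voxelwise(bl, cohort["intensity_r_fu"].to_numpy(),
                                cov, mask)
        voxels = [tuple(p) for p in truth["mtl_cluster_voxels"]]
        cs = self._cluster_set(mask.shape, voxels)
        comp = compare_directions(forward, reverse, cs)[0]
        assert comp.df == len(voxels) - 1
        assert comp.mean_difference > 0
        assert comp.t_stat > 2

    def test_single_voxel_cluster_rejected(self, rng):
        shape = (4, 4, 4)
        n = 20
        pred = rng.standard_normal(n)
        outs = rng.standard_normal((n, *shape))
        res = fit_voxelwise(_vols(outs), pred, mask=_mask(shape))
        cs = self._cluster_set(shape, [(0, 0, 0)])
        with pytest.raises(DegenerateClusterError):
            compare_directions(res, res, cs)
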