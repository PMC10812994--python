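import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from neurotx.core_io import BinaryMask, StatMap, SubjectDesign, VolumeGrid
from neurotx.group_glm import (ClusterRecord, DesignMatrix, ec_density_t_3d,
                               estimate_smoothness, fit_two_sample_glm,
                               grf_cluster_correction, grf_cluster_p,
                               make_cluster_table,
                               monte_carlo_cluster_threshold, one_sample_mask)
from neurotx.synthetic import make_designs


@pytest.fixture
def flat_mask():
    grid = VolumeGrid((10, 10, 10), np.diag([3.0, 3.0, 3.0, 1.0]))
    return BinaryMask(grid, np.ones(grid.shape, bool))


def _maps(rng, n, mask, offset=0.0):
    out = []
    for _ in range(n):
        m = rng.normal(size=mask.grid.shape) + offset
        out.append(m)
    return out


class TestOneSampleMask:
    def test_maps_at_null_value_give_empty_mask(self, flat_mask):
        maps = [np.ones(flat_mask.grid.shape)] * 4
        # zero variance everywhere -> everything excluded
        union = one_sample_mask({"case": maps, "control": maps}, flat_mask,
                                null_value=1.0)
        assert union.sum() == 0

    def test_offset_region_included(self, flat_mask):
        rng = np.random.default_rng(0)
        maps = []
        for _ in range(10):
            m = 1.0 + 0.05 * rng.normal(size=flat_mask.grid.shape)
            m[:5] += 2.0
            maps.append(m)
        union = one_sample_mask({"case": maps}, flat_mask, null_value=1.0)
        assert union[:5].mean() > 0.99

    def test_matches_closed_form_t(self, flat_mask):
        rng = np.random.default_rng(1)
        maps = _maps(rng, 8, flat_mask)
        Y = np.stack([m[flat_mask.inside] for m in maps])
        t = (Y.mean(0) - 1.0) / (Y.std(0, ddof=1) / math.sqrt(8))
        p = 2 * stats.t.sf(np.abs(t), 7)
        union = one_sample_mask({"g": maps}, flat_mask, null_value=1.0,
                                alpha=0.05)
        np.testing.assert_array_equal(union[flat_mask.inside], p < 0.05)


class TestTwoSampleGlm:
    def test_no_covariates_equals_pooled_t(self, flat_mask):
        rng = np.random.default_rng(2)
        designs = make_designs(9, 11, seed=3)
        maps = _maps(rng, 20, flat_mask)
        design = DesignMatrix.from_designs(designs, covariates=False)
        tmap = fit_two_sample_glm(maps, design, flat_mask)
        Y = np.stack([m[flat_mask.inside] for m in maps])
        a, b = Y[:9], Y[9:]
        sp = np.sqrt(((8) * a.var(0, ddof=1) + (10) * b.var(0, ddof=1)) / 18)
        t_pool = (a.mean(0) - b.mean(0)) / (sp * math.sqrt(1 / 9 + 1 / 11))
        np.testing.assert_allclose(tmap.in_mask_values(), t_pool, rtol=1e-10)
        assert tmap.dof == 18

    def test_with_covariates_matches_normal_equations_oracle(self, flat_mask):
        rng = np.random.default_rng(3)
        designs = make_designs(10, 10, seed=4)
        maps = _maps(rng, 20, flat_mask)
        design = DesignMatrix.from_designs(designs)
        tmap = fit_two_sample_glm(maps, design, flat_mask)
        Y = np.stack([m[flat_mask.inside] for m in maps])
        X, c = design.X, design.contrast
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ Y
        resid = Y - X @ beta
        dof = 20 - X.shape[1]
        t_oracle = (c @ beta) / np.sqrt(
            (resid ** 2).sum(0) / dof * (c @ xtx_inv @ c))
        np.testing.assert_allclose(tmap.in_mask_values(), t_oracle,
                                   rtol=1e-10)

    def test_label_swap_flips_sign_exactly(self, flat_mask):
        rng = np.random.default_rng(4)
        designs = make_designs(8, 8, seed=5)
        swapped = [SubjectDesign(d.subject_id,
                                 "control" if d.group == "case" else "case",
                                 d.age, d.sex, d.education, d.bmi)
                   for d in designs]
        maps = _maps(rng, 16, flat_mask)
        t1 = fit_two_sample_glm(maps, DesignMatrix.from_designs(designs),
                                flat_mask)
        t2 = fit_two_sample_glm(maps, DesignMatrix.from_designs(swapped),
                                flat_mask)
        np.testing.assert_allclose(t1.in_mask_values(),
                                   -t2.in_mask_values(), rtol=1e-9)

    def test_collinear_covariate_rejected(self):
        designs = [SubjectDesign(f"s{i}", "case" if i < 4 else "control",
                                 40.0, "male", 12.0,
                                 30.0 if i < 4 else 20.0)
                   for i in range(8)]
        # bmi is a perfect linear function of group
        with pytest.raises(ValueError, match="rank deficient"):
            DesignMatrix.from_designs(designs)

    def test_invariant_to_affine_covariate_rescaling(self, flat_mask):
        rng = np.random.default_rng(5)
        designs = make_designs(10, 10, seed=6)
        rescaled = [SubjectDesign(d.subject_id, d.group, 10 * d.age - 3,
                                  d.sex, d.education, 0.1 * d.bmi + 7)
                    for d in designs]
        maps = _maps(rng, 20, flat_mask)
        t1 = fit_two_sample_glm(maps, DesignMatrix.from_designs(designs),
                                flat_mask)
        t2 = fit_two_sample_glm(maps, DesignMatrix.from_designs(rescaled),
                                flat_mask)
        np.testing.assert_allclose(t1.in_mask_values(), t2.in_mask_values(),
                                   rtol=1e-8)


class TestSmoothness:
    def test_independent_noise_analytic_limit(self, flat_mask):
        # gradient-ratio formula: ratio -> 2, FWHM -> voxel * sqrt(2 ln 2)
        rng = np.random.default_rng(6)
        resid = rng.normal(size=(100, flat_mask.n_voxels))
        est = estimate_smoothness(resid, flat_mask, 50)
        expected = 3.0 * math.sqrt(2 * math.log(2))
        np.testing.assert_allclose(est.fwhm_mm, expected, rtol=0.1)

    def test_six_mm_kernel_recovered(self, flat_mask):
        rng = np.random.default_rng(7)
        sigma = 6.0 / (2 * math.sqrt(2 * math.log(2))) / 3.0
        resid = np.stack([
            ndimage.gaussian_filter(rng.normal(size=flat_mask.grid.shape),
                                    sigma)[flat_mask.inside]
            for _ in range(60)])
        est = estimate_smoothness(resid, flat_mask, 50)
        assert np.all(est.fwhm_mm > 5.1) and np.all(est.fwhm_mm < 6.9)

    def test_voxel_size_equivariance(self):
        rng = np.random.default_rng(8)
        g1 = VolumeGrid((10, 10, 10), np.diag([3.0, 3.0, 3.0, 1.0]))
        g2 = VolumeGrid((10, 10, 10), np.diag([6.0, 6.0, 6.0, 1.0]))
        m1 = BinaryMask(g1, np.ones(g1.shape, bool))
        m2 = BinaryMask(g2, np.ones(g2.shape, bool))
        resid = rng.normal(size=(20, m1.n_voxels))
        e1 = estimate_smoothness(resid, m1, 18)
        e2 = estimate_smoothness(resid, m2, 18)
        np.testing.assert_allclose(e2.fwhm_mm, 2 * e1.fwhm_mm, rtol=1e-10)


def _oracle_cluster_p(extent, u, dof, n_vox, resels, two_tailed=True):
    """Independent re-derivation of the RFT cluster-level p."""
    nu = float(dof)
    rho3 = ((4 * math.log(2)) ** 1.5 / (2 * math.pi) ** 2
            * (1 + u * u / nu) ** (-(nu - 1) / 2)
            * ((nu - 1) / nu * u * u - 1))
    em = resels * rho3
    en = n_vox * stats.t.sf(u, dof)
    beta = (math.gamma(2.5) * em / en) ** (2.0 / 3.0)
    pnk = math.exp(-beta * extent ** (2.0 / 3.0))
    total = em * (2.0 if two_tailed else 1.0)
    return 1.0 - math.exp(-total * pnk)


class TestGrfCorrection:
    def test_cluster_p_matches_numerical_oracle(self):
        for extent, u, dof, resels in [(10, 3.3, 56, 500), (41, 3.6, 56, 800),
                                       (5, 3.1, 20, 100), (100, 3.4, 40, 50)]:
            got = grf_cluster_p(extent, u, dof, 6000, resels)
            want = _oracle_cluster_p(extent, u, dof, 6000, resels)
            assert got == pytest.approx(want, abs=1e-6)

    def test_all_zero_tmap_yields_no_clusters(self, flat_mask):
        tmap = StatMap(flat_mask.grid, np.zeros(flat_mask.grid.shape), 30,
                       flat_mask)
        est = estimate_smoothness(
            np.random.default_rng(9).normal(size=(10, flat_mask.n_voxels)),
            flat_mask, 30)
        with pytest.warns(UserWarning):
            assert grf_cluster_correction(tmap, est) == []

    def test_seeded_blob_survives(self, flat_mask):
        rng = np.random.default_rng(10)
        vals = 0.1 * rng.normal(size=flat_mask.grid.shape)
        vals[3:7, 3:7, 3:7] = 8.0
        tmap = StatMap(flat_mask.grid, vals, 56, flat_mask)
        sigma = 6.0 / 2.3548 / 3.0
        resid = np.stack([
            ndimage.gaussian_filter(rng.normal(size=flat_mask.grid.shape),
                                    sigma)[flat_mask.inside]
            for _ in range(30)])
        est = estimate_smoothness(resid, flat_mask, 56)
        records = grf_cluster_correction(tmap, est)
        assert len(records) == 1
        assert records[0].sign == "increase"
        assert records[0].extent_voxels == 64


class TestMonteCarlo:
    def test_same_seed_reproducible(self, flat_mask):
        a = monte_carlo_cluster_threshold(flat_mask, 6.0, n_iter=200, seed=1)
        b = monte_carlo_cluster_threshold(flat_mask, 6.0, n_iter=200, seed=1)
        assert a == b

    def test_threshold_nondecreasing_in_fwhm(self, flat_mask):
        lo = monte_carlo_cluster_threshold(flat_mask, 6.0, n_iter=400, seed=2)
        hi = monte_carlo_cluster_threshold(flat_mask, 12.0, n_iter=400, seed=2)
        assert hi >= lo

    def test_too_few_iterations_rejected(self, flat_mask):
        with pytest.raises(ValueError):
            monte_carlo_cluster_threshold(flat_mask, 6.0, n_iter=50, seed=0)


class TestClusterTable:
    def test_table_two_row_rendering(self):
        rec = ClusterRecord(1, (-15.0, -33.0, -3.0), 41, 5.294, 0.001,
                            "increase")
        table = make_cluster_table([rec])
        row = table.iloc[0]
        assert (row.peak_x_mm, row.peak_y_mm, row.peak_z_mm) == (-15, -33, -3)
        assert row.extent_voxels == 41
        assert row.peak_t == pytest.approx(5.294)
        assert row.side == "L"

    def test_empty_records_give_header_only(self):
        table = make_cluster_table([])
        assert len(table) == 0
        assert "peak_t" in table.columns

    def test_negative_t_renders_decrease(self):
        rec = ClusterRecord(1, (6.0, -72.0, 57.0), 50, -4.776, 0.01,
                            "decrease")
        table = make_cluster_table([rec])
        assert table.iloc[0].direction == "decrease"
        assert table.iloc[0].side == "R"
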