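"""From-scratch GLM machinery: HRF, designs, OLS, contrasts, FWE, clusters."""

import numpy as np
import pytest
from scipy import stats

from affectfuse.glm import (
    DesignMatrix,
    HrfModel,
    StatMap,
    build_design,
    canonical_hrf,
    convolve_regressor,
    exclusion_contrast,
    f_contrast,
    fit_glm,
    fwe_threshold,
    local_maxima_table,
)


class TestHrf:
    def test_canonical_shape(self):
        dt = 0.1
        k = canonical_hrf(dt)
        t_peak = np.argmax(k) * dt
        assert 5.0 <= t_peak <= 6.0
        assert k.max() == 1.0
        # single late negative lobe
        neg = np.where(k < 0)[0]
        assert neg.size > 0 and neg[0] * dt > 8.0
        assert np.all(np.diff(neg) == 1)

    def test_dt_refinement_consistent(self):
        coarse = canonical_hrf(2.0)
        fine = canonical_hrf(1.0)
        # agreement up to interpolation error: the sampled peak used for
        # normalisation differs between a 2 s and a 1 s grid
        ratio = fine[::2].max() / coarse.max()
        np.testing.assert_allclose(coarse * ratio, fine[::2], rtol=1e-6, atol=1e-12)

    def test_matches_reference_double_gamma(self):
        # independent cross-check against nilearn's SPM HRF (shape only)
        from nilearn.glm.first_level import spm_hrf

        ours = canonical_hrf(0.5)
        ref = spm_hrf(0.5, oversampling=1, time_length=32.5)
        # the reference grid is offset by a sample; align before comparing
        best = 0.0
        for s in (-2, -1, 0, 1, 2):
            a, b = ours[max(0, s):], ref[max(0, -s):]
            n = min(a.size, b.size)
            best = max(best, np.corrcoef(a[:n], b[:n])[0, 1])
        assert best > 0.999

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HrfModel(peak_delay=-1.0)
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


class TestConvolution:
    def test_impulse_returns_kernel(self):
        k = canonical_hrf(1.0)
        x = np.zeros(40)
        x[0] = 1.0
        out = convolve_regressor(x, k)
        np.testing.assert_allclose(out[: k.size], k)
        np.testing.assert_allclose(out[k.size :], 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        k = canonical_hrf(2.0)
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        np.testing.assert_allclose(
            convolve_regressor(a + b, k),
            convolve_regressor(a, k) + convolve_regressor(b, k),
            atol=1e-12,
        )

    def test_boxcar_matches_direct_summation(self):
        k = canonical_hrf(2.0)
        x = np.zeros(60)
        x[5:15] = 1.0  # 20 s boxcar at TR 2
        out = convolve_regressor(x, k)
        oracle = np.array(
            [sum(x[j] * k[i - j] for j in range(i + 1) if i - j < k.size)
             for i in range(60)]
        )
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            convolve_regressor(np.array([]), canonical_hrf(1.0))


class TestDesign:
    def test_intercept_only(self):
        d = build_design({}, None, n_volumes=50, drift_order=0, tr=2.0)
        assert d.n_columns == 1 and d.names == ["intercept"]

    def test_column_bookkeeping(self):
        rng = np.random.default_rng(1)
        d = build_design(
            {"eff": rng.standard_normal(300)},
            {"conf": rng.standard_normal(300)},
            n_volumes=300,
            drift_order=3,
            tr=2.0,
        )
        # effect + confound + 3 drift + intercept (constant lives in the
        # intercept, not in the drift basis)
        assert d.n_columns == 6
        assert d.effect_indices == [0]
        eff = d.matrix[:, 0]
        assert abs(eff.mean()) < 1e-12 and eff.std() == pytest.approx(1.0)

    def test_duplicated_regressor_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(
                {"a": x, "b": x}, None, n_volumes=100, drift_order=1, tr=2.0
            )

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            build_design({"a": np.zeros(50)}, None, n_volumes=50, drift_order=0, tr=2.0)


def _simple_fit(n=120, n_vox=5, seed=3, noise=1.0):
    rng = np.random.default_rng(seed)
    reg = rng.standard_normal(n)
    design = build_design({"eff": reg}, None, n_volumes=n, drift_order=2, tr=2.0)
    beta_true = rng.standard_normal(n_vox)
    y = np.outer(design.matrix[:, 0], beta_true).T
    if noise:
        y = y + noise * rng.standard_normal((n_vox, n))
    return design, y, beta_true


class TestFit:
    def test_noiseless_recovery_is_exact(self):
        design, y, beta_true = _simple_fit(noise=0.0)
        fit = fit_glm(y, design)
        np.testing.assert_allclose(fit.beta[0], beta_true, atol=1e-10)
        np.testing.assert_allclose(fit.sigma2, 0.0, atol=1e-18)

    def test_matches_normal_equations_oracle(self):
        from affectfuse.experiments import glm_oracle_study

        res = glm_oracle_study(n_instances=30, seed=9)
        assert res["max_beta_rel_err"] < 1e-8
        assert res["max_f_rel_err"] < 1e-8

    def test_non_finite_voxel_rejected(self):
        design, y, _ = _simple_fit()
        y[2, 10] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_glm(y, design)

    def test_dof_accounts_for_rank(self):
        design, y, _ = _simple_fit(n=100)
        fit = fit_glm(y, design)
        assert fit.dof == 100 - design.n_columns


class TestFContrast:
    def test_f_equals_t_squared_for_single_row(self):
        design, y, _ = _simple_fit()
        fit = fit_glm(y, design)
        c = np.zeros(design.n_columns)
        c[0] = 1.0
        statmap = f_contrast(fit, c)
        x = design.matrix
        var_c = c @ np.linalg.inv(x.T @ x) @ c
        t = fit.beta[0] / np.sqrt(fit.sigma2 * var_c)
        np.testing.assert_allclose(statmap.f_values, t**2, rtol=1e-10)

    def test_zero_effect_noiseless_voxel_gives_zero_f(self):
        design, _, _ = _simple_fit()
        y = np.outer(design.matrix[:, -1], [2.0]).T  # intercept only
        fit = fit_glm(y, design)
        c = np.zeros(design.n_columns)
        c[0] = 1.0
        assert f_contrast(fit, c).f_values[0] == pytest.approx(0.0, abs=1e-18)

    def test_zero_rank_contrast_rejected(self):
        design, y, _ = _simple_fit()
        fit = fit_glm(y, design)
        with pytest.raises(ValueError, match="rank"):
            f_contrast(fit, np.zeros(design.n_columns))


class TestFwe:
    def test_single_voxel_reduces_to_uncorrected(self):
        statmap = StatMap(
            f_values=np.array([5.0]), p_values=np.array([0.03]), dof=(1, 50)
        )
        assert fwe_threshold(statmap, alpha=0.05, method="bonferroni")[0]
        assert not fwe_threshold(statmap, alpha=0.01, method="bonferroni")[0]

    def test_invalid_alpha_rejected(self):
        statmap = StatMap(np.ones(2), np.full(2, 0.5), (1, 10))
        with pytest.raises(ValueError, match="alpha"):
            fwe_threshold(statmap, alpha=1.5)

    def test_permutation_no_more_conservative_than_bonferroni(self):
        rng = np.random.default_rng(11)
        n, n_vox = 150, 40
        reg = rng.standard_normal(n)
        design = build_design({"eff": reg}, None, n_volumes=n, drift_order=1, tr=2.0)
        y = rng.standard_normal((n_vox, n))
        y[:8] += 0.8 * design.matrix[:, 0]
        fit = fit_glm(y, design)
        statmap = f_contrast(fit, design.contrast_for_effects())
        bonf = fwe_threshold(statmap, 0.05, "bonferroni")
        perm = fwe_threshold(
            statmap, 0.05, "permutation_maxT", fit=fit, bold=y,
            n_permutations=300, rng=np.random.default_rng(0),
        )
        assert perm[bonf].all()
        assert perm.sum() >= bonf.sum()


class TestExclusion:
    def test_identities(self):
        rng = np.random.default_rng(12)
        a = rng.random((6, 6, 6)) < 0.3
        b = rng.random((6, 6, 6)) < 0.3
        c = exclusion_contrast(a, b)
        assert not np.any(c & b)
        assert np.all(a[c])
        assert c.sum() == a.sum() - (a & b).sum()
        # brute-force voxelwise oracle
        oracle = np.zeros_like(a)
        for idx in np.ndindex(a.shape):
            oracle[idx] = bool(a[idx]) and not bool(b[idx])
        np.testing.assert_array_equal(c, oracle)

    def test_empty_and_superset_cases(self):
        a = np.zeros((3, 3, 3), dtype=bool)
        a[0, 0, 0] = True
        assert exclusion_contrast(a, np.zeros_like(a)).sum() == 1
        assert exclusion_contrast(a, a).sum() == 0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            exclusion_contrast(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))


def _flood_fill_sizes(mask):
    """Independent 26-connectivity component sizes via BFS."""
    mask = mask.copy()
    sizes = []
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    while mask.any():
        seed = tuple(np.argwhere(mask)[0])
        stack, size = [seed], 0
        mask[seed] = False
        while stack:
            cur = stack.pop()
            size += 1
            for off in offsets:
                nb = tuple(np.add(cur, off))
                if all(0 <= n < s for n, s in zip(nb, mask.shape)) and mask[nb]:
                    mask[nb] = False
                    stack.append(nb)
        sizes.append(size)
    return sorted(sizes)


class TestClusters:
    AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])

    def _maps(self, shape=(8, 8, 8), seed=13):
        rng = np.random.default_rng(seed)
        f = rng.random(shape) * 10
        p = stats.f.sf(f, 1, 100)
        return f, p

    def test_single_voxel_cluster(self):
        f, p = self._maps()
        mask = np.zeros(f.shape, bool)
        mask[2, 3, 4] = True
        table = local_maxima_table(f, p, mask, self.AFFINE)
        assert len(table) == 1
        assert table.loc[0, "voxels"] == 1
        assert (table.loc[0, ["x_mm", "y_mm", "z_mm"]] == [6.0, 9.0, 12.0]).all()

    def test_adjacent_voxels_merge(self):
        f, p = self._maps()
        mask = np.zeros(f.shape, bool)
        mask[1, 1, 1] = mask[1, 1, 2] = True
        assert local_maxima_table(f, p, mask, self.AFFINE).loc[0, "voxels"] == 2

    def test_diagonal_connectivity_rules(self):
        f, p = self._maps()
        mask = np.zeros(f.shape, bool)
        mask[1, 1, 1] = mask[2, 2, 2] = True
        t26 = local_maxima_table(f, p, mask, self.AFFINE, connectivity=26)
        t6 = local_maxima_table(f, p, mask, self.AFFINE, connectivity=6)
        assert len(t26) == 1 and len(t6) == 2

    def test_random_blob_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(14)
        f, p = self._maps()
        mask = rng.random(f.shape) < 0.2
        table = local_maxima_table(f, p, mask, self.AFFINE)
        assert sorted(table["voxels"].tolist()) == _flood_fill_sizes(mask)
        # every reported peak lies inside the mask and carries the max F
        for _, row in table.iterrows():
            idx = tuple((np.array([row.x_mm, row.y_mm, row.z_mm]) / 3.0).astype(int))
            assert mask[idx]
            assert row.f_peak == f[idx]

    def test_empty_mask_gives_empty_table(self):
        f, p = self._maps()
        table = local_maxima_table(f, p, np.zeros(f.shape, bool), self.AFFINE)
        assert len(table) == 0
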