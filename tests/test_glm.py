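"""GLM fitting, contrasts, second level, ROI rules, quintiles, ANCOVA
and the Monte-Carlo cluster threshold."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cohera.design import DesignMatrix, TrialTiming, build_design, prepare_modulator
from cohera.glm import (
    BoldDataset,
    RoiDefinition,
    anova_2x2,
    cluster_threshold_montecarlo,
    contrast,
    fit_glm,
    mean_displacement,
    quintile_effects,
    roi_build,
    roi_effect,
    second_level,
)
from cohera.synthetic import BoldSimSpec, generate_bold


def small_design(n_vol=80, tr=2.2):
    timings = [
        TrialTiming("extended_planning", 10.0, 8.0),
        TrialTiming("extended_production", 18.0, 50.0),
        TrialTiming("automatic_planning", 90.0, 8.0),
        TrialTiming("automatic_production", 98.0, 15.0),
    ]
    vals = np.linspace(80, 30, 10)
    mod = prepare_modulator(vals, np.zeros(10, dtype=int),
                            trial_ids=np.full(10, 1))
    return build_design(timings, {"coherence": mod}, None, n_vol, tr)


class TestFitGlm:
    def test_noiseless_recovery(self):
        D = small_design()
        spec = BoldSimSpec(dims=(5, 5, 5), noise_sd=0.0, ar1=0.0)
        ds, bmaps = generate_bold(D, spec, seed=1,
                                  effect_columns={"extended_production": 2.0})
        fit = fit_glm(ds, D)
        j = D.names.index("extended_production")
        recovered = fit.betas[j]
        assert np.allclose(recovered, bmaps["extended_production"].ravel(),
                           atol=1e-8)

    def test_pure_noise_mean_t_near_zero(self):
        D = small_design()
        spec = BoldSimSpec(dims=(8, 8, 8), noise_sd=1.0, ar1=0.0)
        ds, _ = generate_bold(D, spec, seed=2, effect_columns={})
        fit = fit_glm(ds, D)
        w = np.zeros(len(D.names))
        w[D.names.index("extended_production")] = 1.0
        t = contrast(fit, w).t
        se = t.std() / np.sqrt(len(t))
        assert abs(t.mean()) < 3 * se + 0.05

    def test_constant_shift_changes_only_intercept(self):
        D = small_design()
        spec = BoldSimSpec(dims=(4, 4, 4), noise_sd=0.5, ar1=0.0)
        ds, _ = generate_bold(D, spec, seed=3, effect_columns={})
        fit_a = fit_glm(ds, D)
        ds_b = BoldDataset(data=ds.data + 10.0, affine=ds.affine,
                           mask=ds.mask, tr=ds.tr)
        fit_b = fit_glm(ds_b, D)
        icpt = D.names.index("intercept_run0")
        for j in range(len(D.names)):
            if j == icpt:
                assert np.allclose(fit_b.betas[j], fit_a.betas[j] + 10.0)
            else:
                assert np.allclose(fit_b.betas[j], fit_a.betas[j], atol=1e-8)

    def test_df_uses_rank(self):
        D = small_design()
        spec = BoldSimSpec(dims=(3, 3, 3), noise_sd=0.1, ar1=0.0)
        ds, _ = generate_bold(D, spec, seed=4, effect_columns={})
        fit = fit_glm(ds, D)
        assert fit.df == ds.n_volumes - np.linalg.matrix_rank(
            D.matrix.to_numpy()
        )

    def test_rank_deficient_design_warns(self):
        D = small_design()
        M = D.matrix.copy()
        M["dup"] = M["extended_planning"]
        D2 = DesignMatrix(matrix=M, tr=D.tr, run_ids=D.run_ids)
        spec = BoldSimSpec(dims=(3, 3, 3), noise_sd=0.1, ar1=0.0)
        ds, _ = generate_bold(D, spec, seed=5, effect_columns={})
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_glm(ds, D2)


class TestContrast:
    def test_zero_weights_zero_map(self):
        D = small_design()
        spec = BoldSimSpec(dims=(3, 3, 3), noise_sd=0.5, ar1=0.0)
        ds, _ = generate_bold(D, spec, seed=6, effect_columns={})
        fit = fit_glm(ds, D)
        res = contrast(fit, np.zeros(len(D.names)))
        assert np.allclose(res.effect, 0.0)
        assert np.allclose(res.t, 0.0)

    def test_planted_effect_estimated(self):
        D = small_design()
        spec = BoldSimSpec(dims=(6, 6, 6), noise_sd=0.05, ar1=0.0,
                           active_fraction=1.0)
        ds, _ = generate_bold(D, spec, seed=7,
                              effect_columns={"mod_coherence": 2.0})
        fit = fit_glm(ds, D)
        w = np.zeros(len(D.names))
        w[D.names.index("mod_coherence")] = 1.0
        res = contrast(fit, w)
        assert np.abs(res.effect - 2.0).max() < 0.1

    def test_sign_flip(self):
        D = small_design()
        spec = BoldSimSpec(dims=(3, 3, 3), noise_sd=0.5, ar1=0.0)
        ds, _ = generate_bold(D, spec, seed=8,
                              effect_columns={"extended_planning": 1.0})
        fit = fit_glm(ds, D)
        w = np.zeros(len(D.names))
        w[0] = 1.0
        a = contrast(fit, w)
        b = contrast(fit, -w)
        assert np.array_equal(a.effect, -b.effect)
        assert np.array_equal(a.t, -b.t)

    def test_wrong_length_raises(self):
        D = small_design()
        spec = BoldSimSpec(dims=(3, 3, 3), noise_sd=0.5, ar1=0.0)
        ds, _ = generate_bold(D, spec, seed=9, effect_columns={})
        fit = fit_glm(ds, D)
        with pytest.raises(ValueError):
            contrast(fit, np.zeros(3))


class TestSecondLevel:
    def test_identical_maps_infinite_t_flagged(self):
        maps = np.tile([1.0, -2.0, 0.0], (5, 1))
        res = second_level(maps)["intercept"]
        assert res.t[0] == np.inf
        assert res.t[1] == -np.inf
        assert res.t[2] == 0.0

    def test_covariate_slope_recovery(self):
        rng = np.random.default_rng(11)
        n, v = 16, 50
        cov = rng.normal(size=n)
        maps = 0.5 + np.outer(cov, np.full(v, 1.5)) + rng.normal(
            0, 0.2, (n, v)
        )
        res = second_level(maps, pd.DataFrame({"coh": cov}))
        slope = res["coh"]
        assert (slope.effect > 0).all()
        crit = stats.t.isf(0.05, slope.df)
        assert (slope.t > crit).mean() > 0.9

    def test_orthogonal_covariate_leaves_intercept_effect(self):
        rng = np.random.default_rng(12)
        n, v = 10, 20
        maps = rng.normal(1.0, 0.5, (n, v))
        cov = rng.normal(size=n)
        cov -= cov.mean()
        # orthogonalize the covariate to every voxel's data
        plain = second_level(maps)["intercept"]
        with_cov = second_level(maps, pd.DataFrame({"c": cov}))["intercept"]
        assert np.allclose(with_cov.effect, plain.effect, atol=1e-10)

    def test_too_few_participants_raises(self):
        with pytest.raises(ValueError):
            second_level(np.ones((2, 5)))

    def test_collinear_covariates_raise(self):
        maps = np.random.default_rng(0).normal(size=(6, 4))
        covs = pd.DataFrame({"a": np.arange(6.0), "b": 2 * np.arange(6.0)})
        with pytest.raises(ValueError, match="collinear"):
            second_level(maps, covs)


class TestMeanDisplacement:
    def test_constant_parameters_zero(self):
        assert mean_displacement(np.ones((10, 6))) == 0.0

    def test_one_stepping_parameter(self):
        M = np.zeros((11, 6))
        M[:, 2] = np.arange(11.0)
        assert mean_displacement(M) == pytest.approx(1 / 6)

    def test_linearity_in_scale(self):
        rng = np.random.default_rng(13)
        M = rng.normal(size=(20, 6))
        assert mean_displacement(2 * M) == pytest.approx(
            2 * mean_displacement(M)
        )


def brute_force_max_cluster(field_bool):
    """Independent flood-fill max-cluster size, 26-connectivity."""
    visited = np.zeros_like(field_bool, dtype=bool)
    best = 0
    dims = field_bool.shape
    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) != (0, 0, 0)]
    for idx in zip(*np.nonzero(field_bool)):
        if visited[idx]:
            continue
        stack, size = [idx], 0
        visited[idx] = True
        while stack:
            x, y, z = stack.pop()
            size += 1
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (0 <= nx < dims[0] and 0 <= ny < dims[1]
                        and 0 <= nz < dims[2] and field_bool[nx, ny, nz]
                        and not visited[nx, ny, nz]):
                    visited[nx, ny, nz] = True
                    stack.append((nx, ny, nz))
        best = max(best, size)
    return best


class TestClusterThreshold:
    def test_unsmoothed_matches_binomial_oracle(self):
        # with no smoothing the suprathreshold field is iid Bernoulli;
        # an independent simulation (Bernoulli draws + flood fill)
        # gives the same max-cluster distribution
        mask = np.ones((8, 8, 8), dtype=bool)
        p = 0.05
        res = cluster_threshold_montecarlo(
            mask, smoothness_fwhm=2.0, voxel_p=p, n_sim=2000, seed=21,
            voxel_size=2.0,
        )
        rng = np.random.default_rng(22)
        oracle = np.array([
            brute_force_max_cluster(rng.random(mask.shape) < p)
            for _ in range(2000)
        ])
        q_ours = np.quantile(res.max_cluster_sizes, [0.5, 0.9, 0.95])
        q_oracle = np.quantile(oracle, [0.5, 0.9, 0.95])
        assert np.abs(q_ours - q_oracle).max() <= 1.0

    def test_smoothness_increases_min_cluster(self):
        mask = np.ones((16, 16, 16), dtype=bool)
        sizes = [
            cluster_threshold_montecarlo(
                mask, fwhm, voxel_p=0.01, n_sim=400, seed=23
            ).min_cluster_size
            for fwhm in (2.0, 6.0, 12.0)
        ]
        assert sizes[0] < sizes[1] < sizes[2]

    def test_voxel_p_one_fills_mask(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        res = cluster_threshold_montecarlo(mask, 2.0, voxel_p=1.0 - 1e-12,
                                           n_sim=100, seed=24)
        assert res.max_cluster_sizes.max() == mask.sum()

    def test_small_nsim_warns(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.warns(UserWarning, match="unstable"):
            cluster_threshold_montecarlo(mask, 2.0, n_sim=50, seed=25)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            cluster_threshold_montecarlo(np.zeros((4, 4, 4), dtype=bool), 2.0)


class TestRoi:
    def test_strict_threshold_and_medial_cut(self):
        # hand-built 3-voxel atlas along x: probabilities .29/.30/.31
        atlas = np.zeros((3, 1, 1))
        atlas[0, 0, 0] = 0.29
        atlas[1, 0, 0] = 0.30
        atlas[2, 0, 0] = 0.31
        affine = np.diag([40.0, 1.0, 1.0, 1.0])  # x = 0, 40, 80 mm
        roi = roi_build(atlas, affine, threshold=0.30, medial_cut_mm=None)
        assert roi.mask.sum() == 1 and roi.mask[2, 0, 0]
        # with a medial cut at |x| < 30 mm a voxel at x=0 is dropped
        atlas2 = np.full((3, 1, 1), 0.5)
        roi2 = roi_build(atlas2, affine, threshold=0.30, medial_cut_mm=30.0)
        assert not roi2.mask[0, 0, 0]
        assert roi2.mask[1, 0, 0] and roi2.mask[2, 0, 0]

    def test_all_above_threshold_minus_medial(self):
        atlas = np.full((4, 2, 2), 0.31)
        affine = np.eye(4)
        affine[0, 0] = 20.0
        affine[0, 3] = -20.0  # x = -20, 0, 20, 40
        roi = roi_build(atlas, affine, threshold=0.30, medial_cut_mm=30.0)
        assert roi.mask.sum() == 4  # only the x=40 plane survives
        assert roi.mask[3].all()

    def test_empty_roi_raises(self):
        atlas = np.full((2, 2, 2), 0.1)
        with pytest.raises(ValueError):
            roi_build(atlas, np.eye(4), threshold=0.30)

    def test_roi_effect_mean_and_linearity(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = mask[2, 2, 2] = True
        roi = RoiDefinition(name="hand", mask=mask)
        img = np.arange(27.0).reshape(3, 3, 3)
        expected = (img[0, 0, 0] + img[1, 1, 1] + img[2, 2, 2]) / 3
        assert roi_effect(img, roi) == pytest.approx(expected)
        assert roi_effect(np.full((3, 3, 3), 7.0), roi) == 7.0
        a = np.random.default_rng(1).normal(size=(3, 3, 3))
        b = np.random.default_rng(2).normal(size=(3, 3, 3))
        assert roi_effect(a + 2 * b, roi) == pytest.approx(
            roi_effect(a, roi) + 2 * roi_effect(b, roi)
        )


class TestQuintiles:
    def make_blocks(self, n_blocks=25, n_time=120, seed=0, slope=0.0):
        rng = np.random.default_rng(seed)
        X = np.zeros((n_time, n_blocks))
        for b in range(n_blocks):
            X[4 * b : 4 * b + 4, b] = 1.0
        values = rng.uniform(0, 100, n_blocks)
        y = X @ (1.0 + slope * (values - values.mean()) / 100.0)
        y = y + rng.normal(0, 0.01, n_time)
        return values, X, y

    def test_constant_parameter_zero_relative(self):
        values, X, _ = self.make_blocks()
        y = X @ np.full(25, 2.0)
        res = quintile_effects(np.full(25, 7.0), X, y)
        assert np.allclose(res["relative_effect"], 0.0, atol=1e-8)

    def test_planted_linear_effect_monotone(self):
        values, X, y = self.make_blocks(slope=50.0, seed=3)
        res = quintile_effects(values, X, y)
        assert (np.diff(res["effect"]) > 0).all()

    def test_count_weighted_relative_effects_sum_to_zero(self):
        values, X, y = self.make_blocks(n_blocks=23, seed=4, slope=10.0)
        res = quintile_effects(values, X, y)
        total = np.sum(res["relative_effect"] * res["n_blocks"])
        assert abs(total) < 1e-8

    def test_too_few_blocks_raises(self):
        with pytest.raises(ValueError):
            quintile_effects(np.arange(3.0), np.zeros((10, 3)), np.zeros(10))


class TestAnova2x2:
    def make_table(self, values):
        rows = []
        for p, cells in enumerate(values):
            for (h, r), v in zip(
                [("L", "BA45"), ("L", "BA47"), ("R", "BA45"), ("R", "BA47")],
                cells,
            ):
                rows.append({"participant": f"s{p}", "hemisphere": h,
                             "region": r, "value": v})
        return pd.DataFrame(rows)

    def test_identical_cells_all_f_zero(self):
        tab = self.make_table([[1.0, 1.0, 1.0, 1.0]] * 6)
        res = anova_2x2(tab)
        assert np.allclose(res["F"], 0.0)

    def test_planted_hemisphere_effect_zero_noise(self):
        # L cells 2.0, R cells 1.0, no interaction
        tab = self.make_table([[2.0, 2.0, 1.0, 1.0]] * 6)
        res = anova_2x2(tab).set_index("effect")
        assert res.loc["hemisphere", "F"] == np.inf
        assert res.loc["hemisphere:region", "F"] == 0.0

    def test_label_swap_swaps_main_effects(self):
        rng = np.random.default_rng(31)
        tab = self.make_table(rng.normal(1.0, 0.3, size=(8, 4)))
        res = anova_2x2(tab).set_index("effect")
        swapped = tab.rename(columns={"hemisphere": "region",
                                      "region": "hemisphere"})
        res_sw = anova_2x2(swapped).set_index("effect")
        assert res.loc["hemisphere", "F"] == pytest.approx(
            res_sw.loc["region", "F"]
        )
        assert res.loc["region", "F"] == pytest.approx(
            res_sw.loc["hemisphere", "F"]
        )

    def test_covariate_df(self):
        rng = np.random.default_rng(32)
        tab = self.make_table(rng.normal(1.0, 0.3, size=(15, 4)))
        res = anova_2x2(tab, covariate=rng.normal(size=15))
        assert (res["df1"] == 1).all()
        assert (res["df2"] == 13).all()  # n - 2 with the covariate

    def test_missing_cell_raises(self):
        tab = self.make_table([[1.0, 2.0, 3.0, 4.0]] * 4).iloc[:-1]
        with pytest.raises(ValueError, match="four cells"):
            anova_2x2(tab)
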