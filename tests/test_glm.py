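"""GLM-engine tests: HRF, design assembly, smoothing, filtering, contrasts."""

import warnings

import numpy as np
import pytest

from dynabody.glm import (
    build_design,
    canonical_hrf,
    contrast_t,
    contrast_tmap,
    dct_basis,
    fit_glm,
    fwhm_to_sigma,
    highpass_filter,
    smooth_volume,
)
from dynabody.motion import BlockMotion
from dynabody.synthetic import SyntheticBoldSpec, make_bold


def _block_motions(schedule, values=None):
    stim = schedule.stimulus_blocks()
    if values is None:
        values = np.linspace(1000, 2000, len(stim))
    return [
        BlockMotion(block_id=f"b{i}", clip_ids=("",) * 5,
                    cumulative_motion=float(v),
                    condition="body" if b.condition.startswith("body") else "object")
        for i, (b, v) in enumerate(zip(stim, values))
    ]


class TestCanonicalHrf:
    def test_zero_at_onset(self):
        assert canonical_hrf(np.array([0.0]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_peak_near_five_seconds_with_unit_height(self):
        t = np.arange(0, 32, 0.01)
        h = canonical_hrf(t)
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.02)
        assert h.max() == pytest.approx(1.0, abs=1e-6)

    def test_net_response_positive(self):
        t = np.arange(0, 32, 0.1)
        assert np.trapezoid(canonical_hrf(t), t) > 0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            canonical_hrf(np.array([-1.0]))


class TestBuildDesign:
    def test_row_count_and_names(self, schedule):
        hm = np.random.default_rng(0).normal(size=(246, 6))
        X = build_design(schedule, block_motions=_block_motions(schedule),
                         head_motion=hm, n_volumes=246, tr_s=2.6)
        assert X.full_rank
        assert X.matrix.shape[0] == 246
        assert X.names[:3] == ["body", "non_body", "motion_covariate"]
        assert sum(n.startswith("motion_param") for n in X.names) == 6
        assert X.names[-1] == "intercept"

    def test_dct_column_count_for_run_length(self, schedule):
        X = build_design(schedule, n_volumes=246, tr_s=2.6,
                         highpass_cutoff_s=128.0)
        # floor(2 * 246 * 2.6 / 128) = 9 drift components
        assert sum(n.startswith("drift") for n in X.names) == 9

    def test_drift_columns_orthonormal(self, schedule):
        X = build_design(schedule, n_volumes=246)
        drift = X.matrix[:, [i for i, n in enumerate(X.names)
                             if n.startswith("drift")]]
        assert np.allclose(drift.T @ drift, np.eye(drift.shape[1]), atol=1e-10)

    def test_equal_block_motions_center_to_zero_column(self, schedule):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            X = build_design(schedule,
                             block_motions=_block_motions(
                                 schedule, np.full(36, 1500.0)))
        assert np.allclose(X.column("motion_covariate"), 0.0)
        assert not X.full_rank

    def test_mismatched_block_motion_count_rejected(self, schedule):
        with pytest.raises(ValueError, match="per stimulus block"):
            build_design(schedule, block_motions=_block_motions(schedule)[:-1])

    def test_raw_covariate_mode(self, schedule):
        X = build_design(schedule, block_motions=_block_motions(schedule),
                         covariate_mode="raw")
        col = X.column("motion_covariate")
        assert col.std() > 0
        t = np.arange(246) * 2.6  # box values appear only during blocks
        baseline_scans = np.ones(246, dtype=bool)
        for b in schedule.stimulus_blocks():
            baseline_scans &= ~((t >= b.onset_s) & (t < b.onset_s + b.duration_s))
        assert np.allclose(col[baseline_scans], 0.0)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        vol = rng.normal(size=(8, 8, 8))
        assert np.array_equal(smooth_volume(vol, 0.0, 3.0), vol)

    def test_mass_conservation_on_delta(self):
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        sm = smooth_volume(vol, 8.0, 3.0)
        assert sm.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.unravel_index(np.argmax(sm), sm.shape) == (10, 10, 10)

    def test_sigma_conversion(self):
        assert fwhm_to_sigma(8.0) == pytest.approx(3.3973, abs=5e-5)

    def test_4d_smoothing_leaves_time_axis_alone(self, rng):
        vol = rng.normal(size=(6, 6, 6, 4))
        sm = smooth_volume(vol, 8.0, 3.0)
        for t in range(4):
            assert np.allclose(sm[..., t], smooth_volume(vol[..., t], 8.0, 3.0))

    def test_bad_voxel_size_rejected(self):
        with pytest.raises(ValueError):
            smooth_volume(np.zeros((4, 4, 4)), 8.0, 0.0)


class TestHighpass:
    def test_constant_series_filters_to_zero(self):
        assert np.allclose(highpass_filter(np.full(246, 7.0)), 0.0, atol=1e-10)

    def test_pure_drift_component_removed(self):
        basis = dct_basis(246, 2.6, 128.0)
        assert np.allclose(highpass_filter(basis[:, 2]), 0.0, atol=1e-10)

    def test_white_noise_variance_reduction_matches_projection_dim(self, rng):
        # removing a (K+1)-dimensional subspace (K drift terms plus the mean)
        # cuts white-noise variance by (K+1)/n on average
        n, runs = 246, 200
        k = dct_basis(n, 2.6, 128.0).shape[1]
        ratios = []
        for _ in range(runs):
            y = rng.normal(size=n)
            ratios.append((highpass_filter(y) ** 2).sum() / (y**2).sum())
        assert np.mean(ratios) == pytest.approx(1 - (k + 1) / n, abs=0.01)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            highpass_filter(np.array([1.0]))


class TestFitAndContrast:
    def test_exact_recovery_without_noise(self, rng):
        X = np.column_stack([rng.normal(size=(30, 3)), np.ones(30)])
        beta0 = np.array([[1.0, -2.0], [0.5, 0.0], [3.0, 1.0], [10.0, 10.0]])
        fit = fit_glm(X @ beta0, X)
        assert np.allclose(fit.beta, beta0, atol=1e-10)
        assert np.allclose(fit.sigma2, 0.0, atol=1e-18)

    def test_matches_normal_equations_oracle(self, rng):
        X = np.column_stack([rng.normal(size=(20, 3)), np.ones(20)])
        Y = rng.normal(size=(20, 50))
        fit = fit_glm(Y, X)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.allclose(fit.beta, beta_oracle, atol=1e-10)

    def test_voxel_permutation_equivariance(self, rng):
        X = np.column_stack([rng.normal(size=(25, 2)), np.ones(25)])
        Y = rng.normal(size=(25, 12))
        perm = rng.permutation(12)
        a = fit_glm(Y, X)
        b = fit_glm(Y[:, perm], X)
        assert np.allclose(a.beta[:, perm], b.beta)
        assert np.allclose(a.sigma2[perm], b.sigma2)

    def test_residuals_orthogonal_to_design(self, rng):
        X = np.column_stack([rng.normal(size=(40, 4)), np.ones(40)])
        Y = rng.normal(size=(40, 30))
        fit = fit_glm(Y, X)
        resid = Y - X @ fit.beta
        scale = np.abs(X).max() * np.abs(Y).max()
        assert np.abs(X.T @ resid).max() < 1e-8 * scale

    def test_rank_deficient_design_warns_and_reduces_df(self, rng):
        X = np.column_stack([rng.normal(size=(20, 2)), np.ones(20), np.ones(20)])
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            fit = fit_glm(rng.normal(size=(20, 5)), X)
        assert fit.df_resid == 20 - 3

    def test_zero_contrast_gives_zero_map(self, rng):
        X = np.column_stack([rng.normal(size=(20, 2)), np.ones(20)])
        fit = fit_glm(rng.normal(size=(20, 8)), X)
        assert np.allclose(contrast_t(fit, np.zeros(3)), 0.0)

    def test_noise_free_effect_saturates_only_planted_voxels(self, rng):
        X = np.column_stack([rng.normal(size=(30, 1)), np.ones(30)])
        Y = np.zeros((30, 4))
        Y[:, 2] = 5.0 * X[:, 0]
        fit = fit_glm(Y, X)
        t = contrast_t(fit, np.array([1.0, 0.0]))
        assert t[2] >= 1e6
        assert np.allclose(np.delete(t, 2), 0.0)

    def test_covariate_orthogonal_when_block_motions_equal(self, schedule, rng):
        spec = SyntheticBoldSpec(grid_shape=(6, 6, 6), schedule=schedule, seed=8)
        img, _ = make_bold(spec)
        Y = np.asarray(img.dataobj).reshape(-1, 246).T
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            Xc = build_design(schedule,
                              block_motions=_block_motions(
                                  schedule, np.full(36, 1500.0)))
        X0 = build_design(schedule)
        t_with = contrast_t(fit_glm(Y, Xc),
                            Xc.contrast({"body": 1, "non_body": -1}))
        t_without = contrast_t(fit_glm(Y, X0),
                               X0.contrast({"body": 1, "non_body": -1}))
        assert np.allclose(t_with, t_without, atol=1e-8)

    def test_parameter_recovery_is_unbiased(self, schedule):
        # mean recovered amplitude over seeds within 2 SE of the plant
        amp, noise_sd, n_seeds = 2.0, 1.0, 100
        X = build_design(schedule)
        c_body = X.contrast({"body": 1.0})
        betas = []
        for seed in range(n_seeds):
            spec = SyntheticBoldSpec(
                grid_shape=(3, 3, 3), schedule=schedule, noise_sd=noise_sd,
                active_sites=(((0.0, 0.0, 0.0), "body", amp),),
                site_radius_mm=1.0, seed=seed,
            )
            img, truth = make_bold(spec)
            vox = tuple(truth["sites"][0]["voxel"])
            y = np.asarray(img.dataobj)[vox]
            fit = fit_glm(y, X)
            betas.append(float(c_body @ fit.beta[:, 0]))
        betas = np.array(betas)
        se = betas.std(ddof=1) / np.sqrt(n_seeds)
        assert abs(betas.mean() - amp) < 2 * se + 1e-12


class TestContrastTmap:
    def test_map_assembly_with_mask(self, rng):
        X = np.column_stack([rng.normal(size=(20, 2)), np.ones(20)])
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        fit = fit_glm(rng.normal(size=(20, int(mask.sum()))), X)
        sm = contrast_tmap(fit, np.array([1.0, 0, 0]), (4, 4, 4), np.eye(4),
                           mask=mask)
        assert sm.values.shape == (4, 4, 4)
        assert np.allclose(sm.values[~mask], 0.0)
        assert sm.df == fit.df_resid
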