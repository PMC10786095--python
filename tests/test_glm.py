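"""Design matrices, per-run OLS, pooled condition t-maps."""

import numpy as np
import pytest

from bmrsa.glm import (condition_tmaps, fit_run_glm, make_design_matrix)
from bmrsa.simulate import (DesignSpec, EffectSpec, attribute_signs,
                            build_timeline, default_effects, plant_amplitudes,
                            make_mask, default_rois, simulate_run,
                            simulate_subject)


@pytest.fixture(scope="module")
def timeline():
    return build_timeline(DesignSpec(), seed=0)


@pytest.fixture(scope="module")
def nuisance(timeline):
    rng = np.random.default_rng(0)
    n = rng.standard_normal((6, timeline.n_volumes))
    return n - n.mean(axis=1, keepdims=True)


class TestDesignMatrix:
    def test_column_budget(self, timeline, nuisance):
        dm = make_design_matrix(timeline, nuisance, drift_order=1)
        # 8 stimuli + 6 motion + intercept + linear & cosine drift
        assert dm.matrix.shape == (219, 8 + 6 + 1 + 2)
        assert dm.names[:8] == tuple(f"stim_{i}" for i in range(8))

    def test_identical_timelines_identical_matrices(self, timeline, nuisance):
        a = make_design_matrix(timeline, nuisance)
        b = make_design_matrix(timeline, nuisance)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_absent_stimulus_raises_rank_error_naming_column(self, nuisance):
        tl = build_timeline(DesignSpec(), seed=0)
        tl.events = [(sid if sid != 3 else 2, on, dur)
                     for sid, on, dur in tl.events]
        with pytest.raises(ValueError, match="stim_3"):
            make_design_matrix(tl, nuisance)

    def test_hrf_matches_external_reference(self):
        # cross-check against nilearn's canonical double-gamma
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        from bmrsa.simulate import double_gamma_hrf

        t = np.arange(0, 32, 0.1)
        h = double_gamma_hrf(t)
        assert h.max() == pytest.approx(1.0)
        ref = spm_hrf(1.0, oversampling=10, time_length=32.0)
        ref = ref / ref.max()
        n = min(len(ref), len(h))
        assert np.corrcoef(h[:n], ref[:n])[0, 1] > 0.995
        assert abs(t[np.argmax(h)] - 0.1 * np.argmax(ref)) < 0.5


class TestFitRunGLM:
    def test_noiseless_beta_recovery(self, timeline, nuisance):
        eff = EffectSpec(grid_shape=(4, 4, 4), noise_sd=0.0, drift=0.0,
                         nuisance_coupling=0.0)
        rng = np.random.default_rng(1)
        amp = 100.0 + rng.standard_normal((10, 8))
        series, _ = simulate_run(timeline, amp, eff, rng)
        dm = make_design_matrix(timeline, np.zeros((0, timeline.n_volumes)))
        betas = fit_run_glm(series.astype(float), dm)
        np.testing.assert_allclose(betas, amp - 100.0, atol=1e-4)

    def test_constant_offset_moves_only_intercept(self, timeline, nuisance):
        rng = np.random.default_rng(2)
        series = rng.standard_normal((5, timeline.n_volumes))
        dm = make_design_matrix(timeline, nuisance)
        b0 = fit_run_glm(series, dm, return_all=True)
        b1 = fit_run_glm(series + 10.0, dm, return_all=True)
        icpt = dm.names.index("intercept")
        np.testing.assert_allclose(b1[:, icpt] - b0[:, icpt], 10.0, atol=1e-8)
        others = [i for i in range(len(dm.names)) if i != icpt]
        np.testing.assert_allclose(b0[:, others], b1[:, others], atol=1e-8)

    def test_voxel_permutation_equivariance(self, timeline, nuisance):
        rng = np.random.default_rng(3)
        series = rng.standard_normal((7, timeline.n_volumes))
        dm = make_design_matrix(timeline, nuisance)
        perm = rng.permutation(7)
        np.testing.assert_allclose(fit_run_glm(series, dm)[perm],
                                   fit_run_glm(series[perm], dm), atol=1e-12)

    def test_residuals_orthogonal_to_design(self, timeline, nuisance):
        rng = np.random.default_rng(4)
        series = rng.standard_normal((6, timeline.n_volumes))
        dm = make_design_matrix(timeline, nuisance)
        betas = fit_run_glm(series, dm, return_all=True)
        resid = series - betas @ dm.matrix.T
        assert np.abs(resid @ dm.matrix).max() < 1e-8

    def test_nonfinite_series_rejected(self, timeline, nuisance):
        dm = make_design_matrix(timeline, nuisance)
        series = np.zeros((2, timeline.n_volumes))
        series[1, 5] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fit_run_glm(series, dm)


class TestConditionTmaps:
    def _simulate(self, noise_sd, seed=0, grid=(8, 8, 8)):
        design = DesignSpec()
        eff = default_effects(grid_shape=grid, roi_size=3, noise_sd=noise_sd)
        subj = simulate_subject(design, eff, seed=seed)
        dms = [make_design_matrix(t, n)
               for t, n in zip(subj.timelines, subj.nuisance)]
        return subj, eff, condition_tmaps(subj.runs, dms)

    def test_t_sign_matches_planted_contrast_at_high_snr(self):
        subj, eff, res = self._simulate(noise_sd=5.0)
        signs = attribute_signs()["facing"]
        roi_v = eff.roi_masks["facing"][subj.mask]
        gain = (subj.truth[roi_v] - eff.baseline) @ signs / (2 * 4)
        tc = res.tmaps[:, roi_v].T @ signs
        # per-voxel contrast sign follows the planted gain sign
        agree = np.mean(np.sign(tc) == np.sign(gain))
        assert agree > 0.95

    def test_doubling_noise_halves_t(self):
        _, eff1, res1 = self._simulate(noise_sd=20.0, seed=5)
        subj, eff2, res2 = self._simulate(noise_sd=40.0, seed=5)
        signs = attribute_signs()["gender"]
        roi_v = eff1.roi_masks["gender"][subj.mask]
        c1 = np.abs(res1.tmaps[:, roi_v].T @ signs).mean()
        c2 = np.abs(res2.tmaps[:, roi_v].T @ signs).mean()
        assert 1.7 < c1 / c2 < 2.3

    def _null_tail(self, ar1, seed=9):
        from scipy import stats

        design = DesignSpec()
        eff = default_effects(grid_shape=(8, 8, 8), roi_size=3, noise_sd=30.0,
                              ar1=ar1)
        subj = simulate_subject(design, eff, seed=seed)
        dms = [make_design_matrix(t, n)
               for t, n in zip(subj.timelines, subj.nuisance)]
        res = condition_tmaps(subj.runs, dms)
        any_roi = np.zeros(subj.mask.sum(), dtype=bool)
        for roi in eff.roi_masks.values():
            any_roi |= roi[subj.mask]
        t_null = res.tmaps[:, ~any_roi].ravel()
        frac = np.mean(np.abs(t_null) > 2.0)
        expected = 2 * stats.t.sf(2.0, res.dof)
        return frac, expected, t_null.size

    def test_null_voxels_follow_student_t_under_white_noise(self):
        frac, expected, n = self._null_tail(ar1=0.0)
        se = np.sqrt(expected * (1 - expected) / n)
        # voxels share run noise realizations only weakly; allow a loose CI
        assert abs(frac - expected) < max(5 * se, 0.02)

    def test_unwhitened_ar1_noise_inflates_null_tail(self):
        # OLS without prewhitening underestimates SEs of low-frequency
        # regressors under AR(1) noise; tail grows but stays bounded
        frac, expected, _ = self._null_tail(ar1=0.3)
        assert expected < frac < 0.2

    def test_needs_two_runs(self, timeline, nuisance):
        dm = make_design_matrix(timeline, nuisance)
        with pytest.raises(ValueError, match="2 runs"):
            condition_tmaps([np.zeros((3, 219))], [dm])
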