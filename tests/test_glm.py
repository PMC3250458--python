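import numpy as np
import pytest

from frontostriatal import glm, synthetic as syn
from frontostriatal.designs import build_task1_schedule, build_task2_schedule, build_task3_schedule
from frontostriatal.pipeline import ANTI_LABELS, PRO_LABELS
from tests.conftest import single_condition_schedule


class TestHRFRegressor:
    def test_single_event_matches_hrf_shape(self):
        tr = 2.1
        col = glm.hrf_regressor([0.0], 20, tr)
        expected = glm.double_gamma_hrf(np.arange(20) * tr)
        # the convolution kernel is truncated at 32 s; beyond that the
        # analytic undershoot tail is < 2e-4
        assert np.allclose(col, expected, atol=2e-4)
        assert np.allclose(col[:15], expected[:15], atol=1e-12)
        assert np.argmax(col) * tr == pytest.approx(6.0, abs=tr)  # peak near 5-6 s

    def test_linearity_of_separated_events(self):
        tr, n = 2.1, 60
        both = glm.hrf_regressor([0.0, 30.0], n, tr)
        a = glm.hrf_regressor([0.0], n, tr)
        b = glm.hrf_regressor([30.0], n, tr)
        assert np.allclose(both, a + b, atol=1e-12)

    def test_empty_onsets_zero_column_with_warning(self):
        with pytest.warns(UserWarning):
            col = glm.hrf_regressor([], 20, 2.1)
        assert np.all(col == 0)

    def test_out_of_run_onset_rejected(self):
        with pytest.raises(ValueError):
            glm.hrf_regressor([100.0], 20, 2.1)

    def test_cross_check_against_nilearn_canonical_hrf(self):
        """Our double-gamma matches the SPM-style canonical HRF up to scale."""
        nilearn_glm = pytest.importorskip("nilearn.glm.first_level")
        ref = nilearn_glm.spm_hrf(0.1, oversampling=1, time_length=32.0)
        ours = glm.double_gamma_hrf(np.linspace(0, 32.0, ref.size, endpoint=False))
        r = np.corrcoef(ref, ours)[0, 1]
        assert r > 0.999


class TestDesignBuilders:
    def test_task1_model1_has_12_event_regressors(self, task1_schedule):
        d = glm.build_task1_design(task1_schedule, 229, 2.1, model=1)
        assert len(d.columns_of_kind("event")) == 12

    def test_task1_model2_has_14_event_regressors(self, task1_schedule):
        d = glm.build_task1_design(task1_schedule, 229, 2.1, model=2)
        assert len(d.columns_of_kind("event")) == 14

    def test_physio_columns_counted_as_nuisance(self, task1_schedule):
        import pandas as pd
        pm = pd.DataFrame(np.random.default_rng(0).normal(size=(229, 20)),
                          columns=[f"p{i}" for i in range(20)])
        d = glm.build_task1_design(task1_schedule, 229, 2.1, model=1, physio_matrix=pm)
        assert len(d.columns_of_kind("nuisance_physio")) == 20
        assert len(d.columns_of_kind("baseline")) == 1

    def test_task2_block_design(self):
        s = build_task2_schedule()
        d = glm.build_block_design(s, ["stim"], 229, 2.1)
        assert len(d.columns_of_kind("block")) == 1
        assert "baseline" in d.labels

    def test_task3_block_design(self):
        s = build_task3_schedule(480.0)
        d = glm.build_block_design(s, ["horizontal", "vertical"], 229, 2.1)
        assert len(d.columns_of_kind("block")) == 2

    def test_unknown_block_label_rejected(self):
        s = build_task2_schedule()
        with pytest.raises(ValueError):
            glm.build_block_design(s, ["saccade"], 229, 2.1)

    def test_missing_condition_yields_zero_column(self):
        sched = single_condition_schedule([10.0], run_duration=100.0)
        with pytest.warns(UserWarning):
            d = glm.build_task1_design(sched, 60, 2.1, model=1)
        j = d.labels.index("target_R_large_anti")
        assert np.all(d.matrix[:, j] == 0)


class TestPrewhitenedFit:
    def test_noiseless_recovery_exact(self, task1_schedule):
        d = glm.build_task1_design(task1_schedule, 229, 2.1, model=1)
        rng = np.random.default_rng(0)
        beta_true = rng.normal(size=d.matrix.shape[1])
        y = d.matrix @ beta_true
        fit = glm.fit_prewhitened(y, d)
        est = fit.betas[:len(beta_true), 0]
        assert np.max(np.abs(est - beta_true)) < 1e-6 * max(1, np.abs(beta_true).max())

    def _ar1_noise(self, rng, n, rho=0.3):
        eps = rng.normal(0, np.sqrt(1 - rho**2), n)
        noise = np.empty(n)
        noise[0] = rng.normal()
        for i in range(1, n):
            noise[i] = rho * noise[i - 1] + eps[i]
        return noise

    @pytest.mark.parametrize("design", ["minimal", "task1"])
    def test_ar1_rho_estimated_within_tolerance(self, design):
        """Mean estimated rho over 20 AR(1) noise seeds within +-0.05 of 0.3.

        The estimator subtracts the projection-induced bias, so the result
        holds for a minimal design and for the full 47-column task design.
        """
        n, tr = 400, 2.1
        if design == "minimal":
            d = glm.DesignMatrix(np.ones((n, 1)), ["baseline"], ["baseline"], tr)
        else:
            sched = build_task1_schedule(70, seed=0)
            d = glm.build_task1_design(sched, n, tr, model=1)
        rng = np.random.default_rng(1)
        rhos = [glm.fit_prewhitened(self._ar1_noise(rng, n) + 100.0, d).ar1_rho[0]
                for _ in range(20)]
        assert np.mean(rhos) == pytest.approx(0.3, abs=0.05)

    def test_nullspace_drift_leaves_task_betas_clean(self, task1_schedule):
        """Drift within the high-pass span leaks < 1e-3 of its amplitude."""
        n, tr = 229, 2.1
        hp = glm.dct_highpass_basis(n, tr, 128.0)
        drift = 5.0 * hp[:, 2] / np.abs(hp[:, 2]).max()  # period > 128 s
        d = glm.build_task1_design(task1_schedule, n, tr, model=1)
        fit = glm.fit_prewhitened(100.0 + drift, d)
        ev = fit.design.columns_of_kind("event")
        assert np.max(np.abs(fit.betas[ev, 0])) < 1e-3 * 5.0

    def test_offbasis_drift_leakage_is_small_but_nonzero(self, task1_schedule):
        """An off-basis 300 s cosine leaks a few percent, not more."""
        n, tr = 229, 2.1
        t = np.arange(n) * tr
        drift = 5.0 * np.cos(2 * np.pi * t / 300.0 + 0.7)
        d = glm.build_task1_design(task1_schedule, n, tr, model=1)
        fit = glm.fit_prewhitened(100.0 + drift, d)
        ev = fit.design.columns_of_kind("event")
        assert np.max(np.abs(fit.betas[ev, 0])) < 0.05 * 5.0

    def test_rank_deficient_design_rejected_with_names(self, task1_schedule):
        d = glm.build_task1_design(task1_schedule, 100, 2.1, model=1)
        M = np.column_stack([d.matrix, d.matrix[:, 0]])
        dd = glm.DesignMatrix(M, d.labels + ["dup_of_first"], d.kinds + ["event"], 2.1)
        with pytest.raises(ValueError, match="rank-deficient"):
            glm.fit_prewhitened(np.ones(100), dd)

    def test_whitened_residuals_decorrelated(self, task1_schedule):
        """After pre-whitening, residual lag-1 autocorrelation is ~ 0."""
        n, tr = 229, 2.1
        d = glm.build_task1_design(task1_schedule, n, tr, model=1)
        acs = []
        for s in range(10):
            m = np.zeros((2, 2, 2), bool); m[0, 0, 0] = True
            truth = syn.GroundTruth(region_masks={"r": m}, effect_amplitudes={},
                                    noise=syn.NoiseParams(rho=0.4, sd=1.0, drift_sd=0.0),
                                    physio=syn.PhysioParams(pulsatility_sd=0.0),
                                    shape=(2, 2, 2))
            Y = syn.simulate_bold_run(task1_schedule, truth, tr=tr, n_volumes=n,
                                      seed=s).reshape(-1, n).T
            fit = glm.fit_prewhitened(Y[:, :1], d)
            rho = fit.ar1_rho[0]
            from frontostriatal.glm import _whiten
            Wy = _whiten(Y[:, :1], rho)
            Wx = _whiten(fit.design.matrix, rho)
            r = (Wy - Wx @ fit.betas[:, :1])[:, 0]
            acs.append(np.sum(r[1:] * r[:-1]) / np.sum(r * r))
        assert abs(np.mean(acs)) < 0.05

    def test_nested_physio_columns_reduce_residual(self, task1_schedule):
        """Adding RETROICOR columns never increases the OLS residual."""
        import pandas as pd
        n = 229
        rng = np.random.default_rng(3)
        pm = pd.DataFrame(rng.normal(size=(n, 20)), columns=[f"p{i}" for i in range(20)])
        d0 = glm.build_task1_design(task1_schedule, n, 2.1, model=1)
        d1 = glm.build_task1_design(task1_schedule, n, 2.1, model=1, physio_matrix=pm)
        y = rng.normal(size=n) + 100
        r0 = y - d0.matrix @ np.linalg.lstsq(d0.matrix, y, rcond=None)[0]
        r1 = y - d1.matrix @ np.linalg.lstsq(d1.matrix, y, rcond=None)[0]
        assert np.sum(r1**2) <= np.sum(r0**2) + 1e-9


class TestContrasts:
    def _fit(self, seed=0, n=200, amps=None):
        shape = (4, 4, 2)
        m = np.zeros(shape, bool)
        m[1:3, 1:3, :] = True
        truth = syn.GroundTruth(region_masks={"roi": m},
                                effect_amplitudes={"roi": amps or {"anti": 2.0, "pro": 1.0}},
                                physio=syn.PhysioParams(pulsatility_sd=0.0), shape=shape)
        sched = build_task1_schedule(33, seed=seed)
        Y = syn.simulate_bold_run(sched, truth, tr=2.1, n_volumes=n, seed=seed + 100)
        d = glm.build_task1_design(sched, n, 2.1, model=1)
        fit = glm.fit_prewhitened(Y.reshape(-1, n).T, d)
        return fit, d, m

    def test_zero_contrast_rejected(self):
        fit, d, _ = self._fit()
        with pytest.raises(ValueError):
            glm.contrast_t(fit, np.zeros(len(d.labels)))

    def test_planted_effect_detected(self):
        """1% anti-pro effect at default noise: region-mean t ~ 3.4 (10 seeds)."""
        ts = []
        for s in range(10):
            fit, d, m = self._fit(seed=s)
            cm = glm.contrast_t(fit, d.contrast_vector(ANTI_LABELS, PRO_LABELS))
            ts.append(cm.t[m.ravel()].mean())
        assert np.mean(ts) > 3.0
        assert min(ts) > 2.5

    def test_label_swap_flips_sign(self):
        fit, d, m = self._fit(seed=1)
        c = d.contrast_vector(ANTI_LABELS, PRO_LABELS)
        a = glm.contrast_t(fit, c)
        b = glm.contrast_t(fit, -c)
        assert np.allclose(a.t, -b.t, equal_nan=True)


class TestGroupTTest:
    def test_identical_images_masked_nan(self):
        imgs = np.ones((5, 3, 3, 3))
        cm = glm.group_ttest(imgs)
        assert np.all(np.isnan(cm.t))
        assert cm.df == 4

    def test_sampling_distribution_matches_theory(self):
        """mu=1, SD=1, n=13: mean t over 50 seeds ~ mu*sqrt(n) = 3.6 +- 1."""
        rng = np.random.default_rng(0)
        ts = [glm.group_ttest(rng.normal(1.0, 1.0, size=(13, 4)))
              .t.mean() for _ in range(50)]
        assert np.mean(ts) == pytest.approx(np.sqrt(13), abs=1.0)

    def test_sign_flip(self):
        rng = np.random.default_rng(1)
        imgs = rng.normal(size=(6, 4, 4))
        a = glm.group_ttest(imgs)
        b = glm.group_ttest(-imgs)
        assert np.allclose(a.t, -b.t, equal_nan=True)

    def test_single_image_rejected(self):
        with pytest.raises(ValueError):
            glm.group_ttest(np.ones((1, 4)))


class TestSmoothing:
    def test_mean_preserved(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(20, 20, 12))
        sm = glm.smooth_fwhm(vol, 2.0, 4.0)
        assert sm.mean() == pytest.approx(vol.mean(), rel=1e-9)

    def test_4d_no_temporal_mixing(self):
        vol = np.zeros((8, 8, 8, 3))
        vol[4, 4, 4, 1] = 1.0
        sm = glm.smooth_fwhm(vol, 2.0, 4.0)
        assert np.all(sm[..., 0] == 0) and np.all(sm[..., 2] == 0)
        assert sm[..., 1].sum() == pytest.approx(1.0)
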