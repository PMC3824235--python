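"""Residualization, pattern likelihood, ML fitting, gamma recovery and standard errors."""

import numpy as np
import pandas as pd
import pytest

import dietme as dm
from dietme.data import slot_labels
from dietme.estimation import (
    FitOptions,
    FitResult,
    ParamPacker,
    RankDeficiencyError,
    _loglik_stats,
    _pattern_stats,
)


def make_dataset(values: np.ndarray, J: int = 2, covariates=None) -> dm.ValidationDataset:
    meas = pd.DataFrame(values, columns=slot_labels(J))
    return dm.ValidationDataset(J=J, measurements=meas, covariates=covariates or {})


def simulated(scenario_params, sens, n=20000, seed=0, **spec_kwargs):
    spec = dm.SimulationSpec(n=n, params=scenario_params, sens=sens, seed=seed,
                             **spec_kwargs)
    return dm.gen_dataset(spec)


class TestResidualize:
    def test_no_covariates_is_demeaning(self, scenario_params, sens_default):
        data, _ = simulated(scenario_params, sens_default, n=500)
        out = dm.residualize(data)
        np.testing.assert_allclose(
            out.values(), data.values() - data.values().mean(axis=0), atol=1e-10)
        assert np.abs(np.nanmean(out.values(), axis=0)).max() < 1e-10

    def test_removes_covariate_association(self):
        rng = np.random.default_rng(1)
        n = 5000
        z = rng.normal(size=n)
        vals = np.column_stack([2 + 3 * z + rng.normal(size=n) for _ in range(6)])
        zdf = pd.DataFrame({"z": z})
        data = make_dataset(vals, covariates={"T": {0: zdf, 1: zdf.copy()}})
        out = dm.residualize(data)
        for c in range(6):
            assert abs(np.corrcoef(out.values()[:, c], z)[0, 1]) < 3 / np.sqrt(n)
        assert "residual_fits" in out.meta

    def test_duplicated_covariate_column_rejected(self):
        rng = np.random.default_rng(2)
        n = 100
        z = rng.normal(size=n)
        zdf = pd.DataFrame({"a": z, "b": z})
        data = make_dataset(rng.normal(size=(n, 6)),
                            covariates={"T": {0: zdf, 1: zdf.copy()}})
        with pytest.raises(RankDeficiencyError, match="collinear"):
            dm.residualize(data)


class TestGroupPatterns:
    def test_complete_data_single_pattern(self):
        data = make_dataset(np.random.default_rng(0).normal(size=(50, 6)))
        pats = dm.group_patterns(data)
        assert len(pats) == 1 and pats[0].count == 50 and all(pats[0].mask)

    def test_single_missing_cell_makes_two_patterns(self):
        vals = np.random.default_rng(0).normal(size=(50, 6))
        vals[7, 5] = np.nan  # M2 for one individual
        pats = dm.group_patterns(make_dataset(vals))
        assert len(pats) == 2
        assert sorted(p.count for p in pats) == [1, 49]

    def test_random_missingness_partitions_everyone(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(1000, 6))
        vals[rng.random(vals.shape) < 0.5] = np.nan
        data = make_dataset(vals)
        pats = dm.group_patterns(data)
        n_with_obs = int(np.isfinite(vals).any(axis=1).sum())
        assert sum(p.count for p in pats) == n_with_obs
        all_idx = np.concatenate([p.indices for p in pats])
        assert len(np.unique(all_idx)) == len(all_idx)


class TestLoglik:
    def test_standard_normal_point(self):
        """A single fully observed zero vector under N(0, I6)."""
        stats = _pattern_stats(make_dataset(np.zeros((1, 6))))
        val = _loglik_stats(stats, np.zeros(6), np.eye(6))
        assert val == pytest.approx(-3 * np.log(2 * np.pi), abs=1e-10)

    def test_additive_over_subsets(self, scenario_params, sens_default):
        data, _ = simulated(scenario_params, sens_default, n=400, seed=4)
        vals = data.values()
        whole = dm.loglik(scenario_params, sens_default, data)
        first = dm.loglik(scenario_params, sens_default, make_dataset(vals[:150]))
        second = dm.loglik(scenario_params, sens_default, make_dataset(vals[150:]))
        assert whole == pytest.approx(first + second, rel=1e-12)

    def test_invariant_to_row_order(self, scenario_params, sens_default):
        data, _ = simulated(scenario_params, sens_default, n=300, seed=6)
        vals = data.values().copy()
        vals[np.random.default_rng(0).random(vals.shape) < 0.3] = np.nan
        shuffled = vals[np.random.default_rng(1).permutation(len(vals))]
        a = dm.loglik(scenario_params, sens_default, make_dataset(vals))
        b = dm.loglik(scenario_params, sens_default, make_dataset(shuffled))
        assert a == pytest.approx(b, rel=1e-12)

    def test_gaussian_mle_beats_perturbations(self):
        """The unstructured sample mean/covariance maximizes the complete-data likelihood."""
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(300, 6)) @ rng.normal(size=(6, 6)) * 0.5
        stats = _pattern_stats(make_dataset(vals))
        mu = vals.mean(axis=0)
        S = np.cov(vals.T, ddof=0)
        best = _loglik_stats(stats, mu, S)
        for _ in range(20):
            D = rng.normal(scale=0.05, size=(6, 6))
            pert = S + D @ D.T * np.sign(rng.normal()) + 0.02 * (D + D.T)
            if np.linalg.eigvalsh(pert).min() <= 0:
                continue
            assert _loglik_stats(stats, mu, pert) < best

    def test_non_pd_returns_minus_inf(self, scenario_params):
        bad_sens = dm.SensitivitySetting(beta_R=1.0, rho_MM=0.0)
        p = scenario_params.copy()
        p.rho_QR[:] = 0.999  # jointly impossible with rho_QQ/rho_RR structure
        data = make_dataset(np.zeros((2, 6)))
        assert dm.loglik(p, bad_sens, data) == -np.inf


class TestFitML:
    def test_parameter_recovery_within_3_se(self, scenario_params):
        """n=20000 at a realistic generating set: every free parameter within 3 SEs."""
        sens = dm.SensitivitySetting(beta_R=0.75, rho_MM=0.4)
        data, _ = simulated(scenario_params, sens, n=20000, seed=42)
        rdata = dm.residualize(data)
        fit = dm.fit_ml(rdata, sens)
        assert fit.converged
        ses = dm.standard_errors(fit, rdata, method="delta")
        truth = ParamPacker(2, fit.options)
        true_vals = truth.natural(truth.pack(scenario_params))
        z = (ses.param_values - true_vals) / ses.param_se
        assert np.abs(z).max() < 3, dict(zip(ses.param_names, np.round(z, 2)))

    def test_vanishing_error_recovers_scaling_ratio(self):
        """With negligible errors the FFQ/record scaling ratio is exact."""
        p = dm.MEModelParams(
            J=2, beta_Q=0.8, beta_M=20.0, sigma2_T=0.5, sigma2_h=np.zeros(2),
            sigma2_Q=np.full(2, 1e-4), sigma2_R=np.full(2, 1e-4),
            sigma2_M=np.full(2, 1e-3), rho_QQ=np.zeros((2, 2)),
            rho_RR=np.zeros((2, 2)), rho_QR=np.zeros((2, 2)))
        sens = dm.SensitivitySetting(beta_R=0.5, rho_MM=0.0)
        data, _ = simulated(p, sens, n=3000, seed=7)
        fit = dm.fit_ml(dm.residualize(data), sens)
        assert fit.params.beta_Q / sens.beta_R == pytest.approx(0.8 / 0.5, abs=0.01)

    def test_recovery_biomarker_preset_matches_moment_estimator(self):
        """Unbiased-biomarker configuration: model RDR equals cov(M,Q)/var(Q)."""
        p = dm.MEModelParams(
            J=1, beta_Q=0.7, beta_M=1.0, sigma2_T=0.3, sigma2_h=np.zeros(1),
            sigma2_Q=np.full(1, 0.25), sigma2_R=np.full(1, 0.35),
            sigma2_M=np.full(1, 0.4), rho_QQ=np.zeros((1, 1)),
            rho_RR=np.zeros((1, 1)), rho_QR=np.zeros((1, 1)))
        sens = dm.SensitivitySetting(beta_R=1.0, rho_MM=0.0)
        data, _ = simulated(p, sens, n=100_000, seed=11)
        rdata = dm.residualize(data)
        fit = dm.fit_ml(rdata, sens, FitOptions(fix_beta_M=1.0, fix_rho_qr_same=0.0))
        vals = rdata.values()
        moment = np.cov(vals[:, 2], vals[:, 0])[0, 1] / np.var(vals[:, 0], ddof=1)
        assert dm.rdr(fit.params, sens, "Q", 0) == pytest.approx(moment, abs=0.01)

    def test_unidentified_design_refused(self):
        rng = np.random.default_rng(0)
        data = make_dataset(rng.normal(size=(200, 3)), J=1)
        with pytest.raises(dm.NotIdentifiedError, match="free covariance parameters"):
            dm.fit_ml(data, dm.SensitivitySetting())

    def test_just_identified_fit_reproduces_sample_covariance(self):
        """With moments and parameters in bijection, ML matches the sample covariance."""
        p = dm.MEModelParams(
            J=1, beta_Q=0.7, beta_M=10.0, sigma2_T=0.3, sigma2_h=np.zeros(1),
            sigma2_Q=np.full(1, 0.25), sigma2_R=np.full(1, 0.35),
            sigma2_M=np.full(1, 40.0), rho_QQ=np.zeros((1, 1)),
            rho_RR=np.zeros((1, 1)), rho_QR=np.zeros((1, 1)))
        sens = dm.SensitivitySetting(beta_R=1.0, rho_MM=0.0)
        data, _ = simulated(p, sens, n=3000, seed=13)
        rdata = dm.residualize(data)
        fit = dm.fit_ml(rdata, sens, FitOptions(fix_rho_qr_same=0.0))
        S = np.cov(rdata.values().T, ddof=0)
        implied = dm.build_implied_moments(fit.params, sens).cov
        np.testing.assert_allclose(implied, S, rtol=1e-4)


class TestGammaEstimation:
    def _covariate_setup(self, gamma_T=(3.0,), noiseless=False):
        J = 2
        sigma = 1e-12 if noiseless else None
        p = dm.fruit_veg_scenario_params().copy(
            alpha_Q=np.zeros(2), alpha_R=np.zeros(2), alpha_M=np.zeros(2),
            gamma_T=np.asarray(gamma_T, dtype=float))
        if noiseless:
            p = p.copy(sigma2_T=1e-12, sigma2_h=np.full(2, 0.0),
                       sigma2_Q=np.full(2, 1e-12), sigma2_R=np.full(2, 1e-12),
                       sigma2_M=np.full(2, 1e-8),
                       rho_QQ=np.zeros((2, 2)), rho_RR=np.zeros((2, 2)),
                       rho_QR=np.zeros((2, 2)))
        from dietme.simulate import CovariateBlockSpec, CovariateColumn
        cov = {"T": CovariateBlockSpec(columns=(CovariateColumn("z", "normal"),))}
        return p, cov

    def test_noiseless_slope_rescaled_by_beta_R(self):
        p, cov = self._covariate_setup(noiseless=True)
        sens = dm.SensitivitySetting(beta_R=0.75, rho_MM=0.0)
        data, _ = simulated(p, sens, n=500, seed=3, covariates=cov)
        est = dm.estimate_gamma_T(data, sens)
        assert est.coef[0] == pytest.approx(3.0, abs=1e-4)

    def test_null_effect_within_3_se(self):
        p, cov = self._covariate_setup(gamma_T=(0.0,))
        sens = dm.SensitivitySetting(beta_R=1.0, rho_MM=0.0)
        data, _ = simulated(p, sens, n=5000, seed=8, covariates=cov)
        est = dm.estimate_gamma_T(data, sens)
        assert abs(est.coef[0]) < 3 * est.se[0]

    def test_halving_beta_R_doubles_coefficients(self):
        p, cov = self._covariate_setup()
        data, _ = simulated(p, dm.SensitivitySetting(beta_R=1.0), n=2000, seed=5,
                            covariates=cov)
        a = dm.estimate_gamma_T(data, dm.SensitivitySetting(beta_R=1.0))
        b = dm.estimate_gamma_T(data, dm.SensitivitySetting(beta_R=0.5))
        np.testing.assert_allclose(b.coef, 2 * a.coef, rtol=1e-12)

    def _fake_fit(self, params, sens):
        return FitResult(params=params, sens=sens, loglik=0.0, converged=True,
                         message="", n_individuals=0, pattern_summary={},
                         options=FitOptions())

    def test_proportional_measurements_give_zero_gamma(self, scenario_params):
        """Q exactly (beta_Q/beta_R) * R leaves an identically zero response."""
        sens = dm.SensitivitySetting(beta_R=0.75, rho_MM=0.0)
        rng = np.random.default_rng(0)
        n = 400
        r = rng.normal(size=(n, 2))
        ratio = scenario_params.beta_Q / sens.beta_R
        vals = np.column_stack([ratio * r, r, rng.normal(size=(n, 2))])
        zdf = pd.DataFrame({"z": rng.normal(size=n)})
        data = make_dataset(vals, covariates={"Q": {0: zdf, 1: zdf.copy()}})
        est = dm.estimate_gamma_secondary(data, self._fake_fit(scenario_params, sens), "Q")
        assert np.abs(est.coef).max() < 1e-10

    def test_gamma_Q_recovery_and_permutation_null(self, scenario_params):
        from dietme.simulate import CovariateBlockSpec, CovariateColumn
        p = scenario_params.copy(gamma_Q=np.array([0.1, -0.2]))
        cov = {"Q": CovariateBlockSpec(columns=(CovariateColumn("z1", "normal"),
                                                CovariateColumn("z2", "normal")))}
        sens = dm.SensitivitySetting(beta_R=1.0, rho_MM=0.0)
        data, _ = simulated(p, sens, n=10000, seed=21, covariates=cov)
        fit = dm.fit_ml(dm.residualize(data), sens)
        est = dm.estimate_gamma_secondary(data, fit, "Q")
        z = (est.coef - np.array([0.1, -0.2])) / est.se
        assert np.abs(z).max() < 3
        # permuting the covariate rows breaks the association
        perm = np.random.default_rng(1).permutation(data.n)
        shuffled = {"Q": {j: blk.iloc[perm].reset_index(drop=True)
                          for j, blk in data.covariates["Q"].items()}}
        data_perm = dm.ValidationDataset(J=2, measurements=data.measurements.copy(),
                                         covariates=shuffled)
        est0 = dm.estimate_gamma_secondary(data_perm, fit, "Q")
        assert np.abs(est0.coef / est0.se).max() < 3

    def test_no_joint_rows_rejected(self, scenario_params):
        sens = dm.SensitivitySetting()
        vals = np.full((10, 6), np.nan)
        vals[:, 0] = 1.0  # only Q1 observed, never R
        data = make_dataset(vals)
        with pytest.raises(ValueError, match="no rows"):
            dm.estimate_gamma_secondary(data, self._fake_fit(scenario_params, sens), "Q")


class TestStandardErrors:
    def test_delta_and_bootstrap_agree(self, scenario_params):
        sens = dm.SensitivitySetting(beta_R=1.0, rho_MM=0.0)
        data, _ = simulated(scenario_params, sens, n=4000, seed=30)
        rdata = dm.residualize(data)
        fit = dm.fit_ml(rdata, sens)
        delta = dm.standard_errors(fit, rdata, method="delta")
        boot = dm.standard_errors(fit, rdata, method="bootstrap", B=120, seed=5)
        for name in ("beta_Q", "sigma2_T", "rho_QQ_12"):
            i = delta.param_names.index(name)
            ratio = boot.param_se[i] / delta.param_se[i]
            assert 0.75 < ratio < 1.3, (name, ratio)

    def test_se_shrinks_with_sqrt_n(self, scenario_params):
        sens = dm.SensitivitySetting(beta_R=1.0, rho_MM=0.2)
        out = {}
        for n in (4000, 16000):
            data, _ = simulated(scenario_params, sens, n=n, seed=31)
            rdata = dm.residualize(data)
            fit = dm.fit_ml(rdata, sens)
            ses = dm.standard_errors(fit, rdata, method="delta")
            out[n] = ses.param_se[ses.param_names.index("beta_Q")]
        assert 0.4 < out[16000] / out[4000] < 0.6

    def test_fixed_sensitivity_parameters_have_zero_se(self, scenario_params):
        sens = dm.SensitivitySetting(beta_R=0.75, rho_MM=0.2)
        data, _ = simulated(scenario_params, sens, n=3000, seed=32)
        rdata = dm.residualize(data)
        fit = dm.fit_ml(rdata, sens)
        ses = dm.standard_errors(fit, rdata, method="delta")
        d = ses.param_se_dict()
        assert d["beta_R"] == 0.0 and d["rho_MM"] == 0.0
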