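"""Shared fixtures: reference parameter sets and random valid parameter draws."""

from __future__ import annotations

import numpy as np
import pytest

from dietme import MEModelParams, ModelValidationError, SensitivitySetting
from dietme.simulate import fruit_veg_scenario_params


@pytest.fixture
def scenario_params() -> MEModelParams:
    """Two-visit realistic scenario with zeroed intercepts (residualized scale)."""
    return fruit_veg_scenario_params().copy(
        alpha_Q=np.zeros(2), alpha_R=np.zeros(2), alpha_M=np.zeros(2))


@pytest.fixture
def sens_default() -> SensitivitySetting:
    return SensitivitySetting(beta_R=0.75, rho_MM=0.4)


def random_valid_params(rng: np.random.Generator, J: int = 2,
                        rho_MM: float = 0.0) -> tuple[MEModelParams, SensitivitySetting]:
    """Draw a random parameter set satisfying all model invariants.

    Correlations are drawn modest and shrunk until the joint error
    correlation matrix is positive definite.
    """
    sens = SensitivitySetting(beta_R=float(rng.uniform(0.4, 1.2)), rho_MM=rho_MM)
    sigma2_T = float(rng.uniform(0.05, 0.5))
    while True:
        def corr():
            return float(rng.uniform(-0.5, 0.7))
        rho_QQ = np.zeros((J, J))
        rho_RR = np.zeros((J, J))
        rho_QR = np.zeros((J, J))
        for j in range(J):
            for k in range(j + 1, J):
                rho_QQ[j, k] = rho_QQ[k, j] = corr()
                rho_RR[j, k] = rho_RR[k, j] = corr()
        for j in range(J):
            for k in range(J):
                rho_QR[j, k] = corr()
        params = MEModelParams(
            J=J,
            beta_Q=float(rng.uniform(0.3, 1.5)),
            beta_M=float(rng.uniform(5.0, 60.0)),
            sigma2_T=sigma2_T,
            sigma2_h=rng.uniform(0.0, 0.4 * sigma2_T, size=J),
            sigma2_Q=rng.uniform(0.1, 0.5, size=J),
            sigma2_R=rng.uniform(0.1, 0.6, size=J),
            sigma2_M=rng.uniform(50.0, 300.0, size=J),
            rho_QQ=rho_QQ, rho_RR=rho_RR, rho_QR=rho_QR,
        )
        try:
            params.validate(sens)
            return params, sens
        except ModelValidationError:
            continue


def slope_mc_se(x: np.ndarray, y: np.ndarray) -> float:
    """Standard error of the OLS slope of y on x (Monte-Carlo uncertainty)."""
    xc = x - x.mean()
    resid = y - y.mean() - (xc @ (y - y.mean()) / (xc @ xc)) * xc
    return float(np.sqrt((resid @ resid) / (len(x) - 2) / (xc @ xc)))


def corr_mc_se(r: float, n: int) -> float:
    """Approximate standard error of a sample correlation."""
    return float((1.0 - r**2) / np.sqrt(n - 3))


def cov_mc_se(cov: np.ndarray, n: int) -> np.ndarray:
    """Elementwise standard error of a sample covariance matrix under normality."""
    d = np.diag(cov)
    return np.sqrt((np.outer(d, d) + cov**2) / n)
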