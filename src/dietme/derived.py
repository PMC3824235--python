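"""Derived quantities: regression dilution ratios, correlations with true intake,
original-scale back-transformation, and identifiability accounting.

The regression dilution ratio (RDR) is the multiplicative bias in a linear
diet-disease coefficient when the error-prone measurement X_ij replaces the
true exposure; regression calibration divides the observed coefficient by it.
With the exposure taken as the long-term average intake T_i,

    lambda_longterm(X, j)     = beta_X * sigma2_T / var(X_ij | Z),

and with the time-specific exposure T_ij = T_i + h_ij,

    lambda_timespecific(X, j) = beta_X * (sigma2_T + sigma2_h[j]) / var(X_ij | Z),

both following from cov(T, X | Z) under the model.  Correlations with true
intake, corr(X_ij, T | Z), use the same covariances and determine study power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    DegenerateInstrumentError,
    MEModelParams,
    SensitivitySetting,
    build_implied_moments,
    slot_index,
)

EXPOSURES = ("longterm", "timespecific")


def _check_exposure(exposure: str) -> None:
    if exposure not in EXPOSURES:
        raise ValueError(f"exposure must be one of {EXPOSURES}, got {exposure!r}")


def _truth_cov(params: MEModelParams, instrument: str, j: int,
               exposure: str, sens: SensitivitySetting) -> float:
    """cov(X_ij, T | Z) where T is T_i (longterm) or T_ij (timespecific)."""
    beta = params.scaling(instrument, sens)
    if exposure == "longterm":
        return beta * params.sigma2_T
    return beta * (params.sigma2_T + params.sigma2_h[j])


def rdr(params: MEModelParams, sens: SensitivitySetting, instrument: str,
        j: int, exposure: str = "longterm") -> float:
    """Regression dilution ratio for instrument 'Q' or 'R' at time index ``j`` (0-based).

    Conditional on the truth covariates; closed form and deterministic.
    """
    _check_exposure(exposure)
    if instrument not in ("Q", "R"):
        raise ValueError("RDRs are defined for the self-report instruments 'Q' and 'R'")
    params.validate(sens)
    beta = params.scaling(instrument, sens)
    if beta == 0:
        raise DegenerateInstrumentError(
            f"beta_{instrument} = 0: instrument carries no intake signal, RDR undefined")
    moments = build_implied_moments(params, sens)
    var_x = moments.cov[slot_index(params.J, instrument, j),
                        slot_index(params.J, instrument, j)]
    return _truth_cov(params, instrument, j, exposure, sens) / var_x


def corr_with_true(params: MEModelParams, sens: SensitivitySetting, instrument: str,
                   j: int, exposure: str = "longterm") -> float:
    """Correlation corr(X_ij, T | Z) for instrument in {'Q', 'R', 'M'}."""
    _check_exposure(exposure)
    params.validate(sens)
    moments = build_implied_moments(params, sens)
    var_x = moments.cov[slot_index(params.J, instrument, j),
                        slot_index(params.J, instrument, j)]
    if var_x <= 0:
        raise DegenerateInstrumentError(f"instrument {instrument} has zero variance at j={j}")
    var_t = params.sigma2_T if exposure == "longterm" else params.sigma2_T + params.sigma2_h[j]
    return _truth_cov(params, instrument, j, exposure, sens) / np.sqrt(var_x * var_t)


def backtransform_rdr(params: MEModelParams, sens: SensitivitySetting, instrument: str,
                      j: int, exposure: str = "longterm", n_mc: int = 100_000,
                      seed: int | None = 0) -> float:
    """RDR on the original (exponentiated) measurement scale, by Monte Carlo.

    When the model holds on the log scale but the diet-disease model uses
    untransformed intake, the original-scale RDR is the slope of the
    regression of exp(T) on exp(X_ij).  Simulates the bivariate normal
    (T, X_ij) implied by the model, exponentiates both coordinates, and
    returns cov(e^T, e^X) / var(e^X) from the sample.

    Seed-reproducible; ``n_mc`` must be at least 10^4 for a stable slope.
    """
    _check_exposure(exposure)
    if n_mc < 10_000:
        raise ValueError(f"n_mc must be >= 10000, got {n_mc}")
    params.validate(sens)
    beta = params.scaling(instrument, sens)
    var_t = params.sigma2_T if exposure == "longterm" else params.sigma2_T + params.sigma2_h[j]
    moments = build_implied_moments(params, sens)
    idx = slot_index(params.J, instrument, j)
    var_x = moments.cov[idx, idx]
    cov_tx = _truth_cov(params, instrument, j, exposure, sens)
    mean = np.array([0.0, moments.mean[idx]])
    cov = np.array([[var_t, cov_tx], [cov_tx, var_x]])
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, cov, size=n_mc)
    et, ex = np.exp(draws[:, 0]), np.exp(draws[:, 1])
    s = np.cov(et, ex)
    return float(s[0, 1] / s[1, 1])


@dataclass
class DerivedQuantities:
    """RDRs and correlations with true intake, optionally with standard errors.

    Keys of the dictionaries are ``(instrument, j)`` with 0-based time index;
    RDRs cover instruments Q and R, correlations also M.
    """

    rdr_longterm: dict = field(default_factory=dict)
    rdr_timespecific: dict = field(default_factory=dict)
    corr_longterm: dict = field(default_factory=dict)
    corr_timespecific: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)  # (quantity_name, instrument, j) -> SE

    @classmethod
    def from_params(cls, params: MEModelParams, sens: SensitivitySetting) -> "DerivedQuantities":
        out = cls()
        for j in range(params.J):
            for x in ("Q", "R"):
                out.rdr_longterm[(x, j)] = rdr(params, sens, x, j, "longterm")
                out.rdr_timespecific[(x, j)] = rdr(params, sens, x, j, "timespecific")
            for x in ("Q", "R", "M"):
                out.corr_longterm[(x, j)] = corr_with_true(params, sens, x, j, "longterm")
                out.corr_timespecific[(x, j)] = corr_with_true(params, sens, x, j, "timespecific")
        return out

    def flat(self) -> dict[str, float]:
        """Flattened {name: value} view, names like 'rdr_longterm_Q1'."""
        out: dict[str, float] = {}
        for attr in ("rdr_longterm", "rdr_timespecific", "corr_longterm", "corr_timespecific"):
            for (x, j), v in getattr(self, attr).items():
                out[f"{attr}_{x}{j + 1}"] = float(v)
        return out


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Degree-of-freedom accounting for a measurement design."""

    n_free: int
    n_moments: int
    identified: bool
    note: str

    def __str__(self) -> str:
        status = "identified" if self.identified else "NOT identified"
        return (f"{self.n_free} free covariance parameters vs {self.n_moments} "
                f"distinct observed second moments: {status}. {self.note}")


@dataclass(frozen=True)
class DesignConstraints:
    """Which otherwise-free parameters a fitting preset holds fixed."""

    free_rho_qr_same: bool = True
    free_beta_M: bool = True
    free_rho_qq: bool = True
    free_rho_rr: bool = True
    free_rho_qr_diff: bool = True


def dof_check(J: int, design: dict[str, list[int]] | None = None,
              constraints: DesignConstraints = DesignConstraints()) -> IdentifiabilityReport:
    """Count free covariance parameters against available second moments.

    ``design`` maps instrument -> list of 0-based time indices at which that
    measurement exists; ``None`` means all 3J slots.  The count is purely
    combinatorial: a free-parameter count not exceeding the moment count is
    necessary, not sufficient, for identifiability (no rank computation is
    attempted).  Within-person variances sigma2_h[j] are counted as free only
    when at least two time points are observed overall and at least two
    instrument types are observed at time j; otherwise they are absorbed
    into sigma2_T.
    """
    if J < 1:
        raise ValueError(f"J must be >= 1, got {J}")
    if design is None:
        design = {x: list(range(J)) for x in ("Q", "R", "M")}
    design = {x: sorted(set(design.get(x, []))) for x in ("Q", "R", "M")}
    slots = sum(len(v) for v in design.values())
    if slots == 0:
        raise ValueError("empty design: no measurement slots")
    for x, js in design.items():
        if any(not 0 <= j < J for j in js):
            raise ValueError(f"design for {x} has time indices outside 0..{J - 1}: {js}")
    n_moments = slots * (slots + 1) // 2

    times_observed = sorted({j for js in design.values() for j in js})
    n_free = 1  # sigma2_T
    if len(times_observed) >= 2:
        n_free += sum(
            1 for j in times_observed
            if sum(1 for x in ("Q", "R", "M") if j in design[x]) >= 2
        )
    n_free += slots  # one error variance per observed slot
    if design["Q"]:
        n_free += 1  # beta_Q
    if design["M"] and constraints.free_beta_M:
        n_free += 1  # beta_M
    q, r = len(design["Q"]), len(design["R"])
    if constraints.free_rho_qq:
        n_free += q * (q - 1) // 2
    if constraints.free_rho_rr:
        n_free += r * (r - 1) // 2
    same = len(set(design["Q"]) & set(design["R"]))
    if constraints.free_rho_qr_same:
        n_free += same
    if constraints.free_rho_qr_diff:
        n_free += sum(1 for j in design["Q"] for k in design["R"] if j != k)

    identified = n_free <= n_moments
    note = ("Counting heuristic only: parameter count <= moment count is necessary, "
            "not sufficient (rank degeneracies are not detected).")
    return IdentifiabilityReport(n_free=n_free, n_moments=n_moments,
                                 identified=identified, note=note)


__all__ = [
    "EXPOSURES",
    "DerivedQuantities",
    "DesignConstraints",
    "IdentifiabilityReport",
    "backtransform_rdr",
    "corr_with_true",
    "dof_check",
    "rdr",
]
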