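"""Core longitudinal measurement error model for dietary validation studies.

The model relates, for individual ``i`` at time point ``j = 1..J``, three
error-prone measurements of dietary intake to a latent time-specific true
intake ``T_ij = T_i + h_ij`` (long-term average ``T_i`` plus an independent
within-person deviation ``h_ij``):

    Q_ij = alpha_Qj + beta_Q * T_ij + gamma_Q' Z_Qij + eps_Qij   (FFQ)
    R_ij = alpha_Rj + beta_R * T_ij +                 eps_Rij    (food record)
    M_ij = alpha_Mj + beta_M * T_ij + gamma_M' Z_Mij + eps_Mij   (biomarker)

conditional on covariates, with ``T_i = gamma_T' Zbar_i + e_Ti``,
``var(e_Ti) = sigma2_T`` and ``var(h_ij) = sigma2_h[j]``.  Errors are jointly
normal with time-specific variances; errors in repeated self-reports and in
FFQ-vs-record pairs may be correlated, self-report errors are uncorrelated
with biomarker errors, and repeated biomarker errors share a single
correlation ``rho_MM``.  The pair ``(beta_R, rho_MM)`` is not identified by
the data and is fixed at values supplied through :class:`SensitivitySetting`.

All second-moment structure is expressed against the fixed slot ordering
``(Q_1..Q_J, R_1..R_J, M_1..M_J)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml


class ModelValidationError(ValueError):
    """A parameter value violates the model's constraints."""


class DegenerateInstrumentError(ValueError):
    """Requested quantity is undefined for a zero-scaling or zero-variance instrument."""


INSTRUMENTS = ("Q", "R", "M")


def slot_labels(J: int) -> list[str]:
    """Measurement slot names in the canonical ordering Q_1..Q_J, R_1..R_J, M_1..M_J."""
    return [f"{x}{j + 1}" for x in INSTRUMENTS for j in range(J)]


def slot_index(J: int, instrument: str, j: int) -> int:
    """Position of measurement ``instrument`` at time index ``j`` (0-based) in the slot ordering."""
    if instrument not in INSTRUMENTS:
        raise ValueError(f"unknown instrument {instrument!r}; expected one of {INSTRUMENTS}")
    if not 0 <= j < J:
        raise ValueError(f"time index {j} out of range for J={J}")
    return INSTRUMENTS.index(instrument) * J + j


@dataclass(frozen=True)
class SensitivitySetting:
    """The two parameters fixed (not estimated) in every fit.

    Parameters
    ----------
    beta_R
        Scaling of the food record on true intake.  ``beta_R = 1`` is the
        conventional no-scaling-bias assumption; recovery-biomarker studies
        of nutrients report values roughly 0.3-0.8.
    rho_MM
        Correlation between error terms of repeated biomarker measurements,
        shared across all pairs of distinct time points.
    """

    beta_R: float = 1.0
    rho_MM: float = 0.0

    def validate(self) -> None:
        if not np.isfinite(self.beta_R) or self.beta_R <= 0:
            raise ModelValidationError(f"beta_R must be a positive real, got {self.beta_R}")
        if not (0.0 <= self.rho_MM < 1.0):
            raise ModelValidationError(f"rho_MM must lie in [0, 1), got {self.rho_MM}")


def _as_vector(x, J: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.shape != (J,):
        raise ModelValidationError(f"{name} must have length J={J}, got shape {arr.shape}")
    return arr


def _as_square(x, J: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (J, J):
        raise ModelValidationError(f"{name} must be {J}x{J}, got shape {arr.shape}")
    return arr


@dataclass
class MEModelParams:
    """All free parameters of the longitudinal measurement error model.

    Correlation containers are ``(J, J)`` arrays against the time-point grid:
    ``rho_QQ[j, k]`` (symmetric, diagonal unused) is the correlation between
    FFQ errors at times j and k; likewise ``rho_RR``; ``rho_QR[j, k]`` is the
    correlation between the FFQ error at time j and the record error at time
    k -- its diagonal holds the same-time correlations and off-diagonal
    entries are *ordered* (``rho_QR[0, 1] != rho_QR[1, 0]`` in general).

    ``gamma_R`` is identically zero: covariate effects on food-record
    reporting are not identified and are fixed away.
    """

    J: int
    beta_Q: float
    beta_M: float
    sigma2_T: float
    sigma2_h: np.ndarray
    sigma2_Q: np.ndarray
    sigma2_R: np.ndarray
    sigma2_M: np.ndarray
    rho_QQ: np.ndarray
    rho_RR: np.ndarray
    rho_QR: np.ndarray
    alpha_Q: np.ndarray = None  # type: ignore[assignment]
    alpha_R: np.ndarray = None  # type: ignore[assignment]
    alpha_M: np.ndarray = None  # type: ignore[assignment]
    gamma_T: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gamma_Q: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gamma_M: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        J = int(self.J)
        if J < 1:
            raise ModelValidationError(f"J must be >= 1, got {J}")
        self.J = J
        self.sigma2_h = _as_vector(self.sigma2_h, J, "sigma2_h")
        self.sigma2_Q = _as_vector(self.sigma2_Q, J, "sigma2_Q")
        self.sigma2_R = _as_vector(self.sigma2_R, J, "sigma2_R")
        self.sigma2_M = _as_vector(self.sigma2_M, J, "sigma2_M")
        for name in ("alpha_Q", "alpha_R", "alpha_M"):
            val = getattr(self, name)
            setattr(self, name, np.zeros(J) if val is None else _as_vector(val, J, name))
        self.rho_QQ = _as_square(self.rho_QQ, J, "rho_QQ")
        self.rho_RR = _as_square(self.rho_RR, J, "rho_RR")
        self.rho_QR = _as_square(self.rho_QR, J, "rho_QR")
        for name in ("gamma_T", "gamma_Q", "gamma_M"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))

    @property
    def gamma_R(self) -> np.ndarray:
        """Covariate effects on food-record reporting, fixed at zero (not identified)."""
        return np.zeros(0)

    def scaling(self, instrument: str, sens: SensitivitySetting) -> float:
        """Scaling coefficient beta_X of the given instrument on true intake."""
        if instrument == "Q":
            return self.beta_Q
        if instrument == "R":
            return sens.beta_R
        if instrument == "M":
            return self.beta_M
        raise ValueError(f"unknown instrument {instrument!r}")

    def error_variances(self) -> np.ndarray:
        """Error variances stacked in slot order (length 3J)."""
        return np.concatenate([self.sigma2_Q, self.sigma2_R, self.sigma2_M])

    def error_correlation(self, sens: SensitivitySetting) -> np.ndarray:
        """The 3J x 3J correlation matrix of the error vector in slot order.

        Self-report/biomarker correlations are structurally zero; the
        biomarker block carries ``rho_MM`` on every off-diagonal pair.
        """
        J = self.J
        C = np.eye(3 * J)
        for j in range(J):
            for k in range(J):
                if j != k:
                    C[j, k] = self.rho_QQ[j, k]
                    C[J + j, J + k] = self.rho_RR[j, k]
                    C[2 * J + j, 2 * J + k] = sens.rho_MM
                C[j, J + k] = self.rho_QR[j, k]
                C[J + k, j] = self.rho_QR[j, k]
        return C

    def validate(self, sens: SensitivitySetting) -> None:
        """Check all invariants; raise ModelValidationError naming the offending entry."""
        sens.validate()
        if not np.isfinite(self.beta_Q):
            raise ModelValidationError(f"beta_Q must be finite, got {self.beta_Q}")
        if not np.isfinite(self.beta_M):
            raise ModelValidationError(f"beta_M must be finite, got {self.beta_M}")
        if not (np.isfinite(self.sigma2_T) and self.sigma2_T > 0):
            raise ModelValidationError(f"sigma2_T must be > 0, got {self.sigma2_T}")
        if np.any(self.sigma2_h < 0) or not np.all(np.isfinite(self.sigma2_h)):
            raise ModelValidationError(f"sigma2_h must be >= 0, got {self.sigma2_h}")
        for name in ("sigma2_Q", "sigma2_R", "sigma2_M"):
            v = getattr(self, name)
            if np.any(v <= 0) or not np.all(np.isfinite(v)):
                raise ModelValidationError(f"{name} must be > 0 elementwise, got {v}")
        for name in ("rho_QQ", "rho_RR"):
            m = getattr(self, name)
            if not np.allclose(m, m.T):
                raise ModelValidationError(f"{name} must be symmetric")
        for name in ("rho_QQ", "rho_RR", "rho_QR"):
            m = getattr(self, name)
            off = m[~np.eye(self.J, dtype=bool)] if name != "rho_QR" else m.ravel()
            if off.size and (np.any(np.abs(off) >= 1) or not np.all(np.isfinite(off))):
                raise ModelValidationError(f"{name} entries must lie in (-1, 1), got {m}")
        C = self.error_correlation(sens)
        eigmin = float(np.linalg.eigvalsh(C).min())
        if eigmin <= 1e-12:
            raise ModelValidationError(
                "implied 3Jx3J error-correlation matrix is not positive definite "
                f"(smallest eigenvalue {eigmin:.3e}); check the rho_* entries and rho_MM"
            )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "J": self.J,
            "beta_Q": float(self.beta_Q),
            "beta_M": float(self.beta_M),
            "sigma2_T": float(self.sigma2_T),
        }
        for name in ("sigma2_h", "sigma2_Q", "sigma2_R", "sigma2_M",
                     "alpha_Q", "alpha_R", "alpha_M", "gamma_T", "gamma_Q", "gamma_M"):
            d[name] = [float(v) for v in getattr(self, name)]
        for name in ("rho_QQ", "rho_RR", "rho_QR"):
            d[name] = [[float(v) for v in row] for row in getattr(self, name)]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MEModelParams":
        kwargs = dict(d)
        for name in ("sigma2_h", "sigma2_Q", "sigma2_R", "sigma2_M",
                     "alpha_Q", "alpha_R", "alpha_M", "gamma_T", "gamma_Q", "gamma_M",
                     "rho_QQ", "rho_RR", "rho_QR"):
            if name in kwargs:
                kwargs[name] = np.asarray(kwargs[name], dtype=float)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MEModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def copy(self, **changes) -> "MEModelParams":
        base = {f: getattr(self, f) for f in (
            "J", "beta_Q", "beta_M", "sigma2_T", "sigma2_h", "sigma2_Q", "sigma2_R",
            "sigma2_M", "rho_QQ", "rho_RR", "rho_QR", "alpha_Q", "alpha_R", "alpha_M",
            "gamma_T", "gamma_Q", "gamma_M")}
        base = {k: (np.array(v, copy=True) if isinstance(v, np.ndarray) else v)
                for k, v in base.items()}
        base.update(changes)
        return MEModelParams(**base)


@dataclass(frozen=True)
class ImpliedMoments:
    """Mean and covariance of the observed measurement vector, conditional on covariates.

    ``order`` gives slot labels; ``mean`` holds the intercepts (covariate
    contributions excluded); ``cov`` is the implied 3J x 3J covariance.
    """

    order: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray


def loading_matrix(params: MEModelParams, sens: SensitivitySetting) -> np.ndarray:
    """The 3J x J matrix mapping (T_i1..T_iJ) into the measurement slots."""
    J = params.J
    L = np.zeros((3 * J, J))
    for j in range(J):
        L[j, j] = params.beta_Q
        L[J + j, j] = sens.beta_R
        L[2 * J + j, j] = params.beta_M
    return L


def truth_covariance(params: MEModelParams) -> np.ndarray:
    """Covariance of the latent time-specific intakes (T_i1..T_iJ) given covariates."""
    return params.sigma2_T * np.ones((params.J, params.J)) + np.diag(params.sigma2_h)


def build_implied_moments(params: MEModelParams, sens: SensitivitySetting) -> ImpliedMoments:
    """Moment structure of (Q_1..Q_J, R_1..R_J, M_1..M_J) implied by the model.

    The covariance decomposes as ``L Sigma_T L' + D C D`` where L carries the
    scalings, Sigma_T the latent-intake covariance, D the error standard
    deviations and C the error correlation matrix.
    """
    params.validate(sens)
    L = loading_matrix(params, sens)
    sigma_T = truth_covariance(params)
    sd = np.sqrt(params.error_variances())
    C = params.error_correlation(sens)
    cov = L @ sigma_T @ L.T + (sd[:, None] * C) * sd[None, :]
    mean = np.concatenate([params.alpha_Q, params.alpha_R, params.alpha_M])
    return ImpliedMoments(order=tuple(slot_labels(params.J)), mean=mean, cov=cov)


__all__ = [
    "INSTRUMENTS",
    "DegenerateInstrumentError",
    "ImpliedMoments",
    "MEModelParams",
    "ModelValidationError",
    "SensitivitySetting",
    "build_implied_moments",
    "loading_matrix",
    "slot_index",
    "slot_labels",
    "truth_covariance",
]
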