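"""Full-cohort maximum likelihood fitting of the measurement error model.

Fitting assumes multivariate normality of the measurement vector conditional
on covariates and uses every individual with at least one observed
measurement: individuals are grouped by observed-slot pattern and each
pattern contributes the marginal normal log density of its observed
subvector.  This full-cohort likelihood is valid and efficient when
measurements are missing at random.

Covariates are handled by the two-step residual approach: measurements are
first replaced by residuals from per-slot OLS regressions on the
measurement's own covariates plus the truth covariates, the covariance
structure is fitted to the residuals with means fixed at zero, and covariate
coefficients (gamma_T, gamma_Q, gamma_M) are then recovered from
random-intercept mixed models.

The optimizer works on an unconstrained transformed scale (log variances,
atanh correlations) with the fixed sensitivity pair (beta_R, rho_MM) held at
its configured values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .data import ValidationDataset, group_patterns
from .derived import DerivedQuantities, DesignConstraints, dof_check
from .model import (
    MEModelParams,
    ModelValidationError,
    SensitivitySetting,
    build_implied_moments,
)

logger = logging.getLogger(__name__)

_BIG = 1e12  # optimizer-safe sentinel for invalid parameter regions


class NotIdentifiedError(ValueError):
    """The requested fit has more free covariance parameters than moments."""


class RankDeficiencyError(ValueError):
    """A covariate design matrix is rank deficient."""


@dataclass
class FitOptions:
    """Options controlling the ML fit.

    ``fix_*`` entries hold the named parameter group at a value instead of
    estimating it (``None`` = free).  ``free_intercepts`` adds the per-slot
    intercepts alpha_Xj to the free set (use for raw, non-residualized data).
    ``multistart`` adds that many jittered restarts around the moment start.
    """

    free_intercepts: bool = False
    fix_beta_M: float | None = None
    fix_sigma2_h: float | None = None
    fix_rho_qq: float | None = None
    fix_rho_rr: float | None = None
    fix_rho_qr_same: float | None = None
    fix_rho_qr_diff: float | None = None
    maxiter: int = 2000
    gtol: float = 1e-8
    ftol: float = 1e-13
    multistart: int = 0
    jitter_scale: float = 0.2
    seed: int = 0
    start: MEModelParams | None = None

    def constraints(self) -> DesignConstraints:
        return DesignConstraints(
            free_rho_qr_same=self.fix_rho_qr_same is None,
            free_beta_M=self.fix_beta_M is None,
            free_rho_qq=self.fix_rho_qq is None,
            free_rho_rr=self.fix_rho_rr is None,
            free_rho_qr_diff=self.fix_rho_qr_diff is None,
        )


def _pairs(J: int):
    return [(j, k) for j in range(J) for k in range(j + 1, J)]


def _offpairs(J: int):
    return [(j, k) for j in range(J) for k in range(J) if j != k]


class ParamPacker:
    """Bijection between free parameters and an unconstrained vector.

    Variances enter as logs and correlations via atanh so that box-free
    quasi-Newton optimization respects the elementwise constraints; joint
    positive definiteness of the implied covariance is enforced by the
    likelihood sentinel instead.
    """

    def __init__(self, J: int, options: FitOptions):
        self.J = J
        self.options = options
        if J == 1 and options.fix_sigma2_h is None:
            # with a single time point sigma2_h is indistinguishable from sigma2_T
            options = replace(options, fix_sigma2_h=0.0)
            self.options = options
        names: list[str] = ["beta_Q"]
        if options.fix_beta_M is None:
            names.append("beta_M")
        names.append("sigma2_T")
        self._free_h = options.fix_sigma2_h is None
        if self._free_h:
            names += [f"sigma2_h{j + 1}" for j in range(J)]
        for x in ("Q", "R", "M"):
            names += [f"sigma2_{x}{j + 1}" for j in range(J)]
        if options.fix_rho_qq is None:
            names += [f"rho_QQ_{j + 1}{k + 1}" for j, k in _pairs(J)]
        if options.fix_rho_rr is None:
            names += [f"rho_RR_{j + 1}{k + 1}" for j, k in _pairs(J)]
        if options.fix_rho_qr_same is None:
            names += [f"rho_QR_{j + 1}{j + 1}" for j in range(J)]
        if options.fix_rho_qr_diff is None:
            names += [f"rho_QR_{j + 1}{k + 1}" for j, k in _offpairs(J)]
        if options.free_intercepts:
            for x in ("Q", "R", "M"):
                names += [f"alpha_{x}{j + 1}" for j in range(J)]
        self.names = names
        self.k = len(names)

    # transforms per name ------------------------------------------------

    @staticmethod
    def _fwd(name: str, v: float) -> float:
        if name.startswith("sigma2"):
            return np.log(max(v, 1e-12))
        if name.startswith("rho"):
            return np.arctanh(np.clip(v, -0.999999, 0.999999))
        return v

    @staticmethod
    def _inv(name: str, x: float) -> float:
        if name.startswith("sigma2"):
            return np.exp(np.clip(x, -60.0, 60.0))
        if name.startswith("rho"):
            return np.tanh(x)
        return x

    def pack(self, params: MEModelParams) -> np.ndarray:
        vals = self._natural_from_params(params)
        return np.array([self._fwd(n, v) for n, v in zip(self.names, vals)])

    def _natural_from_params(self, p: MEModelParams) -> list[float]:
        J, o = self.J, self.options
        out: list[float] = [p.beta_Q]
        if o.fix_beta_M is None:
            out.append(p.beta_M)
        out.append(p.sigma2_T)
        if self._free_h:
            out += list(p.sigma2_h)
        out += list(p.sigma2_Q) + list(p.sigma2_R) + list(p.sigma2_M)
        if o.fix_rho_qq is None:
            out += [p.rho_QQ[j, k] for j, k in _pairs(J)]
        if o.fix_rho_rr is None:
            out += [p.rho_RR[j, k] for j, k in _pairs(J)]
        if o.fix_rho_qr_same is None:
            out += [p.rho_QR[j, j] for j in range(J)]
        if o.fix_rho_qr_diff is None:
            out += [p.rho_QR[j, k] for j, k in _offpairs(J)]
        if o.free_intercepts:
            out += list(p.alpha_Q) + list(p.alpha_R) + list(p.alpha_M)
        return out

    def natural(self, x: np.ndarray) -> np.ndarray:
        """Natural-scale values of the free parameters (same order as ``names``)."""
        return np.array([self._inv(n, v) for n, v in zip(self.names, x)])

    def unpack(self, x: np.ndarray) -> MEModelParams:
        J, o = self.J, self.options
        vals = iter(self.natural(x))
        beta_Q = next(vals)
        beta_M = next(vals) if o.fix_beta_M is None else o.fix_beta_M
        sigma2_T = next(vals)
        if self._free_h:
            sigma2_h = np.array([next(vals) for _ in range(J)])
        else:
            sigma2_h = np.full(J, float(o.fix_sigma2_h))
        sigma2_Q = np.array([next(vals) for _ in range(J)])
        sigma2_R = np.array([next(vals) for _ in range(J)])
        sigma2_M = np.array([next(vals) for _ in range(J)])
        rho_QQ = np.eye(J) * 0.0
        rho_RR = np.eye(J) * 0.0
        rho_QR = np.zeros((J, J))
        if o.fix_rho_qq is None:
            for j, k in _pairs(J):
                rho_QQ[j, k] = rho_QQ[k, j] = next(vals)
        else:
            for j, k in _pairs(J):
                rho_QQ[j, k] = rho_QQ[k, j] = o.fix_rho_qq
        if o.fix_rho_rr is None:
            for j, k in _pairs(J):
                rho_RR[j, k] = rho_RR[k, j] = next(vals)
        else:
            for j, k in _pairs(J):
                rho_RR[j, k] = rho_RR[k, j] = o.fix_rho_rr
        for j in range(J):
            rho_QR[j, j] = next(vals) if o.fix_rho_qr_same is None else o.fix_rho_qr_same
        for j, k in _offpairs(J):
            rho_QR[j, k] = next(vals) if o.fix_rho_qr_diff is None else o.fix_rho_qr_diff
        alpha_Q = alpha_R = alpha_M = None
        if o.free_intercepts:
            alpha_Q = np.array([next(vals) for _ in range(J)])
            alpha_R = np.array([next(vals) for _ in range(J)])
            alpha_M = np.array([next(vals) for _ in range(J)])
        return MEModelParams(
            J=J, beta_Q=beta_Q, beta_M=beta_M, sigma2_T=sigma2_T, sigma2_h=sigma2_h,
            sigma2_Q=sigma2_Q, sigma2_R=sigma2_R, sigma2_M=sigma2_M,
            rho_QQ=rho_QQ, rho_RR=rho_RR, rho_QR=rho_QR,
            alpha_Q=alpha_Q, alpha_R=alpha_R, alpha_M=alpha_M,
        )


# ---------------------------------------------------------------------------
# residual covariate adjustment
# ---------------------------------------------------------------------------

def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # walk columns to name the first that adds no rank
        bad = []
        for c in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :c]) < c:
                bad.append(names[c - 1])
        raise RankDeficiencyError(
            f"covariate design is rank deficient; collinear column(s): {bad}")


def residualize(data: ValidationDataset) -> ValidationDataset:
    """Replace each measurement column by OLS residuals on (Z_X, Z_T) plus intercept.

    Regressions are fitted separately per measurement type and time point
    using the rows where that measurement is observed.  The fitted
    coefficients are retained in ``meta['residual_fits']`` for later
    recovery of covariate effects.  With empty covariate blocks this reduces
    to per-column mean removal.
    """
    meas = data.measurements.copy()
    fits: dict[str, dict] = {}
    role_of = {"Q": "Q", "R": None, "M": "M"}  # food-record covariates structurally absent
    for x in ("Q", "R", "M"):
        for j in range(data.J):
            col = f"{x}{j + 1}"
            y = meas[col]
            obs = y.notna()
            blocks = []
            names: list[str] = []
            if role_of[x] is not None:
                zb = data.covariate_block(role_of[x], j)
                blocks.append(zb.to_numpy(dtype=float))
                names += [f"Z{role_of[x]}:{c}" for c in zb.columns]
            zt = data.covariate_block("T", j)
            blocks.append(zt.to_numpy(dtype=float))
            names += [f"ZT:{c}" for c in zt.columns]
            Z = np.hstack([b for b in blocks if b.size] or [np.zeros((data.n, 0))])
            X = np.column_stack([np.ones(data.n), Z])
            n_obs = int(obs.sum())
            if n_obs == 0:
                fits[col] = {"names": names, "coef": None}
                continue
            if n_obs < X.shape[1] + 2:
                raise ValueError(
                    f"slot {col}: {n_obs} observations are too few for a "
                    f"{X.shape[1]}-column regression")
            _check_full_rank(X[obs.to_numpy()], ["intercept"] + names)
            coef, *_ = np.linalg.lstsq(X[obs.to_numpy()], y[obs].to_numpy(), rcond=None)
            resid = y.to_numpy(dtype=float) - X @ coef
            resid[~obs.to_numpy()] = np.nan
            meas[col] = resid
            fits[col] = {"names": ["intercept"] + names, "coef": coef}
    out = ValidationDataset(J=data.J, measurements=meas, covariates=data.covariates,
                            meta=dict(data.meta))
    out.meta["residual_fits"] = fits
    out.meta["residualized"] = True
    return out


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

@dataclass
class _PatternStats:
    obs: np.ndarray      # observed slot indices
    n: int
    mean: np.ndarray     # sample mean of observed subvector
    scatter: np.ndarray  # sum of centered outer products


def _pattern_stats(data: ValidationDataset) -> list[_PatternStats]:
    vals = data.values()
    out = []
    for pat in group_patterns(data):
        obs = np.flatnonzero(np.array(pat.mask))
        sub = vals[np.ix_(pat.indices, obs)]
        m = sub.mean(axis=0)
        d = sub - m
        out.append(_PatternStats(obs=obs, n=pat.count, mean=m, scatter=d.T @ d))
    return out


_LOG2PI = np.log(2.0 * np.pi)


def _loglik_stats(stats: list[_PatternStats], mean: np.ndarray, cov: np.ndarray) -> float:
    total = 0.0
    for st in stats:
        sub = cov[np.ix_(st.obs, st.obs)]
        try:
            L = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            return -np.inf
        k = len(st.obs)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        d = st.mean - mean[st.obs]
        # tr(Sigma^-1 S) + n * d' Sigma^-1 d via triangular solves
        sol_s = np.linalg.solve(sub, st.scatter)
        z = np.linalg.solve(L, d)
        quad = np.trace(sol_s) + st.n * float(z @ z)
        total += -0.5 * (st.n * (k * _LOG2PI + logdet) + quad)
    return float(total)


def loglik(params: MEModelParams, sens: SensitivitySetting,
           data: ValidationDataset) -> float:
    """Full-cohort log likelihood: sum over individuals of the marginal normal
    log density of each observed subvector under the implied moments.

    Returns ``-inf`` (never raises) when the implied covariance is not
    positive definite, so the value is safe inside an optimizer.
    """
    try:
        moments = build_implied_moments(params, sens)
    except ModelValidationError:
        return -np.inf
    return _loglik_stats(_pattern_stats(data), moments.mean, moments.cov)


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _clip_rho(v: float) -> float:
    return float(np.clip(v, -0.9, 0.9)) if np.isfinite(v) else 0.3


def moment_start(data: ValidationDataset, sens: SensitivitySetting,
                 options: FitOptions) -> MEModelParams:
    """Moment-based starting values from the pairwise-complete sample covariance.

    Maps the sample covariance through the model equations where invertible
    (cross-instrument, cross-time covariances isolate the scaling/variance
    products); falls back to neutral defaults for any entry the data cannot
    support.
    """
    J = data.J
    df = data.measurements
    S = df.cov()  # pairwise complete
    means = df.mean()

    def cv(a: str, b: str) -> float:
        v = S.loc[a, b]
        return float(v) if np.isfinite(v) else np.nan

    neutral = dict(beta_Q=1.0, beta_M=1.0, sigma2_T=np.nan)
    beta_R = sens.beta_R
    if J >= 2:
        rm = np.nanmean([cv(f"R{j+1}", f"M{k+1}") for j, k in _offpairs(J)])
        qm = np.nanmean([cv(f"Q{j+1}", f"M{k+1}") for j, k in _offpairs(J)])
        mm = np.nanmean([cv(f"M{j+1}", f"M{k+1}") for j, k in _pairs(J)])
        var_m = np.array([cv(f"M{j+1}", f"M{j+1}") for j in range(J)])
        bm_s2t = rm / beta_R  # beta_M * sigma2_T
        beta_M = options.fix_beta_M if options.fix_beta_M is not None else np.nan
        sigma2_M = 0.5 * var_m
        for _ in range(4):
            if options.fix_beta_M is None:
                num = mm - sens.rho_MM * np.sqrt(np.prod(sigma2_M[:2])) if J == 2 else mm
                if J > 2:
                    num = mm - sens.rho_MM * float(np.mean(np.sqrt(sigma2_M))) ** 2
                beta_M = num / bm_s2t if bm_s2t and np.isfinite(num / bm_s2t) else np.nan
            if not np.isfinite(beta_M) or abs(beta_M) < 1e-8:
                break
            sigma2_T = bm_s2t / beta_M
            if not np.isfinite(sigma2_T) or sigma2_T <= 0:
                break
            sigma2_M = np.clip(var_m - beta_M**2 * sigma2_T * 1.2,
                               0.05 * var_m, None)
        else:
            pass
        if not np.isfinite(beta_M) or not np.isfinite(bm_s2t / beta_M) or bm_s2t / beta_M <= 0:
            beta_M = 1.0
            sigma2_T = abs(rm / beta_R) if np.isfinite(rm) and rm != 0 else 0.5
        else:
            sigma2_T = bm_s2t / beta_M
        beta_Q = qm / (beta_M * sigma2_T) if np.isfinite(qm) else 1.0
        if not np.isfinite(beta_Q):
            beta_Q = 1.0
    else:
        beta_M = options.fix_beta_M if options.fix_beta_M is not None else 1.0
        rm1 = cv("R1", "M1")
        sigma2_T = rm1 / (beta_R * beta_M) if np.isfinite(rm1) and rm1 > 0 else 0.5
        qm1 = cv("Q1", "M1")
        beta_Q = qm1 / (beta_M * sigma2_T) if np.isfinite(qm1) else 1.0
        if not np.isfinite(beta_Q):
            beta_Q = 1.0

    if not np.isfinite(sigma2_T) or sigma2_T <= 0:
        v = cv("R1", "R1")
        sigma2_T = 0.5 * v / beta_R**2 if np.isfinite(v) and v > 0 else 1.0

    # within-person variances from same-time self-report/biomarker covariances
    sigma2_h = np.zeros(J)
    if options.fix_sigma2_h is not None or J == 1:
        sigma2_h[:] = options.fix_sigma2_h or 0.0
    else:
        for j in range(J):
            cands = []
            if abs(beta_Q * beta_M) > 1e-12:
                cands.append(cv(f"Q{j+1}", f"M{j+1}") / (beta_Q * beta_M) - sigma2_T)
            if abs(beta_R * beta_M) > 1e-12:
                cands.append(cv(f"R{j+1}", f"M{j+1}") / (beta_R * beta_M) - sigma2_T)
            est = np.nanmean(cands) if cands else np.nan
            sigma2_h[j] = float(np.clip(est, 0.02 * sigma2_T, 2.0 * sigma2_T)) \
                if np.isfinite(est) else 0.1 * sigma2_T

    betas = {"Q": beta_Q, "R": beta_R, "M": beta_M}
    sigma2 = {}
    for x in ("Q", "R", "M"):
        v = np.array([cv(f"{x}{j+1}", f"{x}{j+1}") for j in range(J)])
        sig = v - betas[x] ** 2 * (sigma2_T + sigma2_h)
        fallback = np.where(np.isfinite(v), 0.5 * v, 1.0)
        sig = np.where(np.isfinite(sig), sig, fallback)
        sigma2[x] = np.clip(sig, np.where(np.isfinite(v), 0.05 * v, 0.05), None)
    sd = {x: np.sqrt(sigma2[x]) for x in sigma2}

    rho_QQ = np.zeros((J, J))
    rho_RR = np.zeros((J, J))
    rho_QR = np.zeros((J, J))
    for j, k in _pairs(J):
        rho_QQ[j, k] = rho_QQ[k, j] = _clip_rho(
            (cv(f"Q{j+1}", f"Q{k+1}") - beta_Q**2 * sigma2_T) / (sd["Q"][j] * sd["Q"][k]))
        rho_RR[j, k] = rho_RR[k, j] = _clip_rho(
            (cv(f"R{j+1}", f"R{k+1}") - beta_R**2 * sigma2_T) / (sd["R"][j] * sd["R"][k]))
    for j in range(J):
        if options.fix_rho_qr_same is not None:
            rho_QR[j, j] = options.fix_rho_qr_same
        else:
            rho_QR[j, j] = _clip_rho(
                (cv(f"Q{j+1}", f"R{j+1}") - beta_Q * beta_R * (sigma2_T + sigma2_h[j]))
                / (sd["Q"][j] * sd["R"][j]))
    for j, k in _offpairs(J):
        if options.fix_rho_qr_diff is not None:
            rho_QR[j, k] = options.fix_rho_qr_diff
        else:
            rho_QR[j, k] = _clip_rho(
                (cv(f"Q{j+1}", f"R{k+1}") - beta_Q * beta_R * sigma2_T)
                / (sd["Q"][j] * sd["R"][k]))
    if options.fix_rho_qq is not None:
        rho_QQ[~np.eye(J, dtype=bool)] = options.fix_rho_qq
    if options.fix_rho_rr is not None:
        rho_RR[~np.eye(J, dtype=bool)] = options.fix_rho_rr

    alphas = {}
    for x in ("Q", "R", "M"):
        mu = np.array([means.get(f"{x}{j+1}", 0.0) for j in range(J)])
        alphas[x] = np.where(np.isfinite(mu), mu, 0.0) if options.free_intercepts \
            else np.zeros(J)

    params = MEModelParams(
        J=J, beta_Q=float(beta_Q), beta_M=float(beta_M), sigma2_T=float(sigma2_T),
        sigma2_h=sigma2_h, sigma2_Q=sigma2["Q"], sigma2_R=sigma2["R"],
        sigma2_M=sigma2["M"], rho_QQ=rho_QQ, rho_RR=rho_RR, rho_QR=rho_QR,
        alpha_Q=alphas["Q"], alpha_R=alphas["R"], alpha_M=alphas["M"],
    )
    try:
        params.validate(sens)
    except ModelValidationError:
        # shrink correlations towards zero until the error block is PD
        for shrink in (0.7, 0.4, 0.0):
            params = params.copy(rho_QQ=params.rho_QQ * shrink,
                                 rho_RR=params.rho_RR * shrink,
                                 rho_QR=params.rho_QR * shrink)
            try:
                params.validate(sens)
                break
            except ModelValidationError:
                continue
    return params


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a maximum likelihood fit."""

    params: MEModelParams
    sens: SensitivitySetting
    loglik: float
    converged: bool
    message: str
    n_individuals: int
    pattern_summary: dict
    options: FitOptions
    n_iter: int = 0
    vcov: np.ndarray | None = None  # of the transformed free parameters
    packer: ParamPacker | None = None
    x: np.ndarray | None = None

    def derived(self) -> DerivedQuantities:
        return DerivedQuantities.from_params(self.params, self.sens)

    def param_table(self) -> pd.DataFrame:
        nat = self.packer.natural(self.x)
        return pd.DataFrame({"parameter": self.packer.names, "estimate": nat})


def fit_ml(data: ValidationDataset, sens: SensitivitySetting,
           options: FitOptions | None = None) -> FitResult:
    """Maximize the full-cohort likelihood with (beta_R, rho_MM) held fixed.

    Expects residualized data (means fixed at zero) unless
    ``options.free_intercepts`` is set, in which case per-slot intercepts are
    estimated alongside the covariance structure.  Deterministic given data,
    options and starting values.
    """
    options = options or FitOptions()
    sens.validate()
    data = data.drop_empty_individuals()
    report = dof_check(data.J, data.design(), options.constraints())
    if not report.identified:
        raise NotIdentifiedError(f"design is not identified: {report}")

    packer = ParamPacker(data.J, options)
    options = packer.options  # may have forced fix_sigma2_h for J=1
    stats = _pattern_stats(data)

    def nll(x: np.ndarray) -> float:
        params = packer.unpack(x)
        try:
            moments = build_implied_moments(params, sens)
        except ModelValidationError:
            return _BIG
        val = _loglik_stats(stats, moments.mean, moments.cov)
        return _BIG if not np.isfinite(val) else -val

    start_params = options.start or moment_start(data, sens, options)
    x0 = packer.pack(start_params)
    starts = [x0]
    if options.multistart > 0:
        rng = np.random.default_rng(options.seed)
        starts += [x0 + rng.normal(0, options.jitter_scale, size=len(x0))
                   for _ in range(options.multistart)]

    opt_kwargs = dict(
        method="L-BFGS-B", jac="3-point",
        options={"maxiter": options.maxiter, "ftol": options.ftol,
                 "gtol": options.gtol,
                 # 3-point gradients cost 2k+1 evaluations per iteration
                 "maxfun": (2 * packer.k + 2) * options.maxiter},
    )
    best = None
    for xs in starts:
        res = optimize.minimize(nll, xs, **opt_kwargs)
        # restarting clears the quasi-Newton history and escapes premature
        # ftol termination; repeat while it still improves materially
        for _ in range(3):
            res2 = optimize.minimize(nll, res.x, **opt_kwargs)
            improved = res2.fun < res.fun - 1e-9 * (1.0 + abs(res.fun))
            # keep the success flag when a restart merely confirms the optimum
            if res2.fun < res.fun or (res2.fun <= res.fun and res2.success):
                res = res2
            if not improved:
                break
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    params = packer.unpack(best.x)
    ll = -float(best.fun)
    converged = bool(best.success and np.isfinite(ll))
    if not converged and np.isfinite(ll) and best.jac is not None:
        # a failed line search at an already-stationary point (e.g. an exact
        # warm start) is convergence: accept when the relative gradient is at
        # finite-difference noise level
        relgrad = float(np.max(np.abs(best.jac) * np.maximum(1.0, np.abs(best.x)))
                        / max(1.0, abs(best.fun)))
        converged = relgrad < 1e-6
    if not converged:
        logger.warning("fit_ml did not converge: %s", best.message)
    patterns = group_patterns(data)
    summary = {"n_patterns": len(patterns),
               "largest": max(p.count for p in patterns),
               "counts": {"".join("1" if b else "0" for b in p.mask): p.count
                          for p in patterns}}
    return FitResult(params=params, sens=sens, loglik=ll, converged=converged,
                     message=str(best.message), n_individuals=data.n,
                     pattern_summary=summary, options=options,
                     n_iter=int(best.nit), packer=packer, x=np.asarray(best.x))


# ---------------------------------------------------------------------------
# covariate coefficient recovery (two-step, mixed models)
# ---------------------------------------------------------------------------

@dataclass
class GammaEstimate:
    """Covariate coefficients with standard errors."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    method: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"covariate": self.names, "estimate": self.coef,
                             "se": self.se})


def _stack_long(data: ValidationDataset, response: dict[int, pd.Series],
                role: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Assemble long-format response/design/groups across time points."""
    ys, Xs, gs = [], [], []
    names: list[str] | None = None
    for j, y in response.items():
        obs = y.notna()
        if obs.sum() == 0:
            continue
        Z = data.covariate_block(role, j)
        if names is None:
            names = list(Z.columns)
        X = np.column_stack([np.ones(int(obs.sum())), Z.loc[obs].to_numpy(dtype=float)]) \
            if len(Z.columns) else np.ones((int(obs.sum()), 1))
        ys.append(y[obs].to_numpy(dtype=float))
        Xs.append(X)
        gs.append(np.asarray(data.measurements.index[obs.to_numpy()]))
    if not ys:
        raise ValueError("no rows with the required measurements observed")
    return (np.concatenate(ys), np.vstack(Xs), np.concatenate(gs), names or [])


def _mixed_or_ols(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                  names: list[str]) -> tuple[np.ndarray, np.ndarray, str]:
    """Random-intercept mixed model by ML; OLS fallback when degenerate."""
    import statsmodels.api as sm

    _, counts = np.unique(groups, return_counts=True)
    has_repeats = bool((counts > 1).any())
    if has_repeats:
        for fit_kwargs in ({"reml": False}, {"reml": False, "method": "lbfgs"}):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.MixedLM(y, X, groups=groups).fit(**fit_kwargs)
                coef = np.asarray(fit.fe_params)
                se = np.asarray(fit.bse_fe)
                if np.all(np.isfinite(coef)) and np.all(np.isfinite(se)):
                    return coef, se, "mixed"
            except Exception:  # singular/degenerate variance structures
                continue
        logger.warning("mixed model failed; falling back to ordinary regression")
    else:
        logger.warning("no repeated measurements; using ordinary regression for gamma")
    ols = sm.OLS(y, X).fit()
    return np.asarray(ols.params), np.asarray(ols.bse), "ols"


def estimate_gamma_T(data: ValidationDataset, sens: SensitivitySetting) -> GammaEstimate:
    """Covariate effects on true intake, from the food-record regression.

    Fits a random-intercept mixed regression of R_ij on Z_T (raw,
    non-residualized data) and divides slopes and standard errors by beta_R:
    because the record has no covariate effects of its own, its regression on
    Z_T estimates beta_R * gamma_T.
    """
    response = {j: data.measurements[f"R{j + 1}"] for j in range(data.J)}
    y, X, groups, names = _stack_long(data, response, "T")
    coef, se, method = _mixed_or_ols(y, X, groups, names)
    return GammaEstimate(names=names, coef=coef[1:] / sens.beta_R,
                         se=se[1:] / sens.beta_R, method=method)


def estimate_gamma_secondary(data: ValidationDataset, fit: FitResult,
                             which: str) -> GammaEstimate:
    """Covariate effects on FFQ reporting (which='Q') or biomarker error (which='M').

    Uses the constructed response X_ij - (beta_X / beta_R) * R_ij, which
    removes the intake signal, regressed on the instrument's own covariates
    with a random intercept.  Standard errors ignore the uncertainty in the
    plugged-in scaling estimates.
    """
    if which not in ("Q", "M"):
        raise ValueError("which must be 'Q' or 'M'")
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to construct the response")
    beta_x = fit.params.beta_Q if which == "Q" else fit.params.beta_M
    ratio = beta_x / fit.sens.beta_R
    response = {}
    for j in range(data.J):
        x = data.measurements[f"{which}{j + 1}"]
        r = data.measurements[f"R{j + 1}"]
        response[j] = x - ratio * r  # NaN wherever either is missing
    y, X, groups, names = _stack_long(data, response, which)
    coef, se, method = _mixed_or_ols(y, X, groups, names)
    return GammaEstimate(names=names, coef=coef[1:], se=se[1:], method=method)


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

def _numerical_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    h = step * np.maximum(1.0, np.abs(x))
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        for j in range(i, k):
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _numerical_jacobian(g, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    base = np.asarray(g(x), dtype=float)
    Jac = np.zeros((len(base), len(x)))
    h = step * np.maximum(1.0, np.abs(x))
    for i in range(len(x)):
        e = np.zeros(len(x)); e[i] = h[i]
        Jac[:, i] = (np.asarray(g(x + e)) - np.asarray(g(x - e))) / (2 * h[i])
    return Jac


@dataclass
class SEResult:
    """Standard errors for free parameters and derived quantities."""

    method: str
    param_names: list[str]
    param_values: np.ndarray
    param_se: np.ndarray
    derived: DerivedQuantities
    vcov_transformed: np.ndarray | None = None

    def param_se_dict(self) -> dict[str, float]:
        d = {n: float(s) for n, s in zip(self.param_names, self.param_se)}
        # quantities fixed by the sensitivity setting have no sampling variability
        d["beta_R"] = 0.0
        d["rho_MM"] = 0.0
        return d


def _derived_vector(params: MEModelParams, sens: SensitivitySetting) -> tuple[list[str], np.ndarray]:
    flat = DerivedQuantities.from_params(params, sens).flat()
    return list(flat.keys()), np.array(list(flat.values()))


def standard_errors(fit: FitResult, data: ValidationDataset, method: str = "delta",
                    B: int = 200, seed: int = 0) -> SEResult:
    """Standard errors by the delta method (observed information) or bootstrap.

    delta:  invert the numerical Hessian of the negative log likelihood at the
    optimum (transformed scale) and propagate through the natural-parameter
    and derived-quantity maps by numerical Jacobian.  Falls back to the
    bootstrap with a warning when the information matrix is singular.

    bootstrap:  nonparametric resampling of individuals with replacement,
    refitting from the point estimate; seed-reproducible.
    """
    if method not in ("delta", "bootstrap"):
        raise ValueError("method must be 'delta' or 'bootstrap'")
    packer, x = fit.packer, fit.x
    dnames, dvals = _derived_vector(fit.params, fit.sens)
    derived = fit.derived()

    if method == "delta":
        data_ = data.drop_empty_individuals()
        stats = _pattern_stats(data_)

        def nll(xv: np.ndarray) -> float:
            params = packer.unpack(xv)
            try:
                moments = build_implied_moments(params, fit.sens)
            except ModelValidationError:
                return _BIG
            val = _loglik_stats(stats, moments.mean, moments.cov)
            return _BIG if not np.isfinite(val) else -val

        H = _numerical_hessian(nll, x)
        eig = np.linalg.eigvalsh(H)
        if eig.min() <= 0 or eig.max() / max(eig.min(), 1e-300) > 1e12:
            logger.warning("observed information is singular or ill conditioned; "
                           "falling back to bootstrap standard errors")
            return standard_errors(fit, data, method="bootstrap", B=B, seed=seed)
        vcov = np.linalg.inv(H)

        def gmap(xv: np.ndarray) -> np.ndarray:
            params = packer.unpack(xv)
            nat = packer.natural(xv)
            _, dv = _derived_vector(params, fit.sens)
            return np.concatenate([nat, dv])

        Jac = _numerical_jacobian(gmap, x)
        full_cov = Jac @ vcov @ Jac.T
        se_all = np.sqrt(np.clip(np.diag(full_cov), 0, None))
        k = packer.k
        param_se = se_all[:k]
        derived_se = se_all[k:]
        for name, s in zip(dnames, derived_se):
            derived.se[name] = float(s)
        return SEResult(method="delta", param_names=list(packer.names),
                        param_values=packer.natural(x), param_se=param_se,
                        derived=derived, vcov_transformed=vcov)

    # bootstrap
    rng = np.random.default_rng(seed)
    data_ = data.drop_empty_individuals()
    draws = []
    opts = replace(fit.options, start=fit.params, multistart=0)
    for _ in range(B):
        idx = rng.integers(0, data_.n, size=data_.n)
        meas = data_.measurements.iloc[idx].reset_index(drop=True)
        cov = {role: {j: blk.iloc[idx].reset_index(drop=True)
                      for j, blk in blocks.items()}
               for role, blocks in data_.covariates.items()}
        bdata = ValidationDataset(J=data_.J, measurements=meas, covariates=cov)
        try:
            bfit = fit_ml(bdata, fit.sens, opts)
        except (NotIdentifiedError, ValueError):
            continue
        _, dv = _derived_vector(bfit.params, fit.sens)
        draws.append(np.concatenate([packer.natural(bfit.x), dv]))
    if len(draws) < max(10, B // 4):
        raise RuntimeError(f"bootstrap produced only {len(draws)} successful refits")
    arr = np.array(draws)
    se_all = arr.std(axis=0, ddof=1)
    k = packer.k
    for name, s in zip(dnames, se_all[k:]):
        derived.se[name] = float(s)
    return SEResult(method="bootstrap", param_names=list(packer.names),
                    param_values=packer.natural(x), param_se=se_all[:k],
                    derived=derived, vcov_transformed=None)


__all__ = [
    "FitOptions",
    "FitResult",
    "GammaEstimate",
    "NotIdentifiedError",
    "ParamPacker",
    "RankDeficiencyError",
    "SEResult",
    "estimate_gamma_T",
    "estimate_gamma_secondary",
    "fit_ml",
    "loglik",
    "moment_start",
    "residualize",
    "standard_errors",
]
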