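"""Synthetic validation datasets with the full stochastic structure of the model.

The generator draws latent long-term intakes, within-person deviations, and
a jointly normal 3J-dimensional error vector with the complete correlation
structure (including the fixed repeated-biomarker correlation and the
structural zeros between self-report and biomarker errors), assembles the
observed measurements, and can overlay missingness (MCAR or MAR) and
raw-scale artifacts (zero intakes in the self-reports, high biomarker
outliers) to exercise preprocessing end to end.

Self-reports are generated on the analysis (log) scale -- mirroring intake
data that are approximately normal after log transformation -- and the
biomarker on its natural scale.  A single master seed expands into
independent substreams for covariates, latent truth, errors, missingness and
artifacts, so each component can be varied without disturbing the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import ValidationDataset
from .model import (
    MEModelParams,
    SensitivitySetting,
    loading_matrix,
    slot_labels,
)


@dataclass(frozen=True)
class CovariateColumn:
    """One synthetic covariate column.

    kind 'binary' uses ``p``; 'normal' uses ``mean``/``sd``; 'categorical'
    uses ``probs`` over ``len(probs)`` levels and is emitted pre-encoded as
    ``len(probs) - 1`` dummy design columns (first level is the reference).
    """

    name: str
    kind: str = "normal"
    p: float = 0.5
    mean: float = 0.0
    sd: float = 1.0
    probs: tuple[float, ...] = ()

    def n_design_columns(self) -> int:
        if self.kind == "categorical":
            return max(len(self.probs) - 1, 0)
        return 1


@dataclass(frozen=True)
class CovariateBlockSpec:
    """Covariate columns for one role, optionally redrawn at each time point."""

    columns: tuple[CovariateColumn, ...] = ()
    time_varying: bool = False

    def n_design_columns(self) -> int:
        return sum(c.n_design_columns() for c in self.columns)


@dataclass(frozen=True)
class MissingnessSpec:
    """Elementwise deletion: MCAR at per-slot rates, or MAR driven by one slot.

    Under MAR the deletion probability for each targeted slot is
    ``expit(mar_intercept + mar_slope * driver_value)``; the driver slot is
    never deleted.
    """

    mechanism: str = "none"  # 'none' | 'mcar' | 'mar'
    rates: dict = field(default_factory=dict)  # slot label -> rate (mcar)
    mar_targets: tuple[str, ...] = ()
    mar_driver: str = "Q1"
    mar_intercept: float = 0.0
    mar_slope: float = 1.0

    def validate(self, J: int) -> None:
        if self.mechanism not in ("none", "mcar", "mar"):
            raise ValueError(f"unknown missingness mechanism {self.mechanism!r}")
        labels = set(slot_labels(J))
        for s, r in self.rates.items():
            if s not in labels:
                raise ValueError(f"unknown slot {s!r} in missingness rates")
            if not 0 <= r <= 1:
                raise ValueError(f"rate for {s} must be in [0,1], got {r}")
        if self.mechanism == "mar":
            if self.mar_driver not in labels:
                raise ValueError(f"unknown MAR driver slot {self.mar_driver!r}")
            if self.mar_driver in self.mar_targets:
                raise ValueError("the MAR driver slot must remain observed")


@dataclass(frozen=True)
class ArtifactSpec:
    """Raw-scale data artifacts: reported zero intakes and biomarker spikes."""

    zero_rate_Q: float = 0.0
    zero_rate_R: float = 0.0
    outlier_rate_M: float = 0.0
    outlier_shift_M: float = 150.0  # added to affected biomarker values

    def validate(self) -> None:
        for name in ("zero_rate_Q", "zero_rate_R", "outlier_rate_M"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class SimulationSpec:
    """Everything needed to generate one synthetic validation study."""

    n: int
    params: MEModelParams
    sens: SensitivitySetting
    covariates: dict[str, CovariateBlockSpec] = field(default_factory=dict)
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        self.params.validate(self.sens)
        self.missingness.validate(self.params.J)
        self.artifacts.validate()
        for role, spec in self.covariates.items():
            if role not in ("T", "Q", "M"):
                raise ValueError(f"unknown covariate role {role!r}")
            gamma = getattr(self.params, f"gamma_{role}")
            if len(gamma) != spec.n_design_columns():
                raise ValueError(
                    f"gamma_{role} has length {len(gamma)} but the covariate spec "
                    f"emits {spec.n_design_columns()} design columns")

    def substreams(self) -> dict[str, np.random.Generator]:
        kids = np.random.SeedSequence(self.seed).spawn(5)
        keys = ("covariates", "truth", "errors", "missingness", "artifacts")
        return {k: np.random.default_rng(s) for k, s in zip(keys, kids)}


def _draw_column(col: CovariateColumn, n: int, rng: np.random.Generator) -> pd.DataFrame:
    if col.kind == "binary":
        return pd.DataFrame({col.name: rng.binomial(1, col.p, size=n).astype(float)})
    if col.kind == "normal":
        return pd.DataFrame({col.name: rng.normal(col.mean, col.sd, size=n)})
    if col.kind == "categorical":
        probs = np.asarray(col.probs, dtype=float)
        if probs.size < 2 or not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"categorical column {col.name}: probs must sum to 1")
        levels = rng.choice(len(probs), size=n, p=probs)
        out = {f"{col.name}_{lvl}": (levels == lvl).astype(float)
               for lvl in range(1, len(probs))}
        return pd.DataFrame(out)
    raise ValueError(f"unknown covariate kind {col.kind!r}")


def gen_covariates(spec: SimulationSpec, rng: np.random.Generator | int | None = None,
                   ) -> dict[str, dict[int, pd.DataFrame]]:
    """Draw covariate design blocks per role and time point; reproducible per seed."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    J, n = spec.params.J, spec.n
    out: dict[str, dict[int, pd.DataFrame]] = {}
    for role, block in spec.covariates.items():
        if not block.columns:
            continue
        if block.time_varying:
            frames = {j: pd.concat([_draw_column(c, n, rng) for c in block.columns],
                                   axis=1) for j in range(J)}
        else:
            base = pd.concat([_draw_column(c, n, rng) for c in block.columns], axis=1)
            frames = {j: base.copy() for j in range(J)}
        out[role] = frames
    return out


def gen_dataset(spec: SimulationSpec) -> tuple[ValidationDataset, pd.DataFrame]:
    """Generate measurements plus the latent truth table (kept separate).

    Returns ``(dataset, truth)`` where ``truth`` holds ``T_i`` and
    ``T_i1..T_iJ`` (and the error draws for the biomarker slots, supporting
    error-structure diagnostics); the truth never enters the dataset itself.
    """
    spec.validate()
    streams = spec.substreams()
    p, sens, n, J = spec.params, spec.sens, spec.n, spec.params.J

    covariates = gen_covariates(spec, streams["covariates"])

    # latent truth: T_i around gamma_T' Zbar_i, plus within-person deviations
    rng_t = streams["truth"]
    if "T" in covariates and len(p.gamma_T):
        zbar = sum(b.to_numpy(dtype=float) for b in covariates["T"].values()) / J
        mean_T = zbar @ p.gamma_T
    else:
        mean_T = np.zeros(n)
    T_i = mean_T + rng_t.normal(0.0, np.sqrt(p.sigma2_T), size=n)
    h = rng_t.normal(0.0, 1.0, size=(n, J)) * np.sqrt(p.sigma2_h)[None, :]
    T_ij = T_i[:, None] + h

    # correlated error vector across all 3J slots
    sd = np.sqrt(p.error_variances())
    C = p.error_correlation(sens)
    chol = np.linalg.cholesky((sd[:, None] * C) * sd[None, :])
    eps = streams["errors"].normal(size=(n, 3 * J)) @ chol.T

    gamma_contrib = {x: np.zeros((n, J)) for x in ("Q", "R", "M")}
    for x in ("Q", "M"):
        gamma = getattr(p, f"gamma_{x}")
        if x in covariates and len(gamma):
            for j in range(J):
                gamma_contrib[x][:, j] = covariates[x][j].to_numpy(dtype=float) @ gamma

    L = loading_matrix(p, sens)
    signal = T_ij @ L.T  # (n, 3J): beta_X * T_ij in each slot
    alphas = np.concatenate([p.alpha_Q, p.alpha_R, p.alpha_M])
    gam = np.hstack([gamma_contrib["Q"], gamma_contrib["R"], gamma_contrib["M"]])
    obs = alphas[None, :] + signal + gam + eps

    meas = pd.DataFrame(obs, columns=slot_labels(J))
    meas.index.name = "id"
    data = ValidationDataset(J=J, measurements=meas, covariates=covariates)
    truth = pd.DataFrame({"T_i": T_i})
    for j in range(J):
        truth[f"T_i{j + 1}"] = T_ij[:, j]
    for j in range(J):
        truth[f"eps_M{j + 1}"] = eps[:, 2 * J + j]
    truth.index.name = "id"
    return data, truth


def apply_missingness(data: ValidationDataset, spec: SimulationSpec,
                      rng: np.random.Generator | None = None) -> ValidationDataset:
    """Delete cells per the missingness spec; drop (and count) all-missing rows."""
    ms = spec.missingness
    ms.validate(data.J)
    if rng is None:
        rng = spec.substreams()["missingness"]
    if ms.mechanism == "none":
        return data.copy()
    out = data.copy()
    vals = out.measurements
    if ms.mechanism == "mcar":
        for slot, rate in ms.rates.items():
            if rate <= 0:
                continue
            delete = rng.random(len(vals)) < rate
            vals.loc[delete, slot] = np.nan
    else:  # mar
        driver = vals[ms.mar_driver].to_numpy(dtype=float)
        driver = np.where(np.isfinite(driver), driver, np.nanmean(driver))
        prob = expit(ms.mar_intercept + ms.mar_slope * driver)
        for slot in ms.mar_targets:
            delete = rng.random(len(vals)) < prob
            vals.loc[delete, slot] = np.nan
    n_before = out.n
    out = out.drop_empty_individuals()
    dropped = n_before - out.n
    if dropped:
        import logging
        logging.getLogger(__name__).info(
            "apply_missingness: dropped %d individuals with no observed slot", dropped)
    out.meta["n_dropped_all_missing"] = dropped
    return out


def to_raw_scale(data: ValidationDataset) -> ValidationDataset:
    """Exponentiate the self-report slots (the biomarker stays on its natural scale)."""
    out = data.copy()
    for x in ("Q", "R"):
        for j in range(data.J):
            out.measurements[f"{x}{j + 1}"] = np.exp(out.measurements[f"{x}{j + 1}"])
    out.meta["scale"] = "raw"
    return out


def inject_artifacts(data: ValidationDataset, spec: SimulationSpec,
                     rng: np.random.Generator | None = None) -> ValidationDataset:
    """Overlay raw-scale artifacts: zero self-reports and high biomarker outliers.

    Expects data on the original (exponentiated) scale for the self-reports.
    """
    ar = spec.artifacts
    ar.validate()
    if rng is None:
        rng = spec.substreams()["artifacts"]
    out = data.copy()
    vals = out.measurements
    counts = {"zeros_Q": 0, "zeros_R": 0, "outliers_M": 0}
    for x, rate in (("Q", ar.zero_rate_Q), ("R", ar.zero_rate_R)):
        if rate <= 0:
            continue
        for j in range(data.J):
            col = f"{x}{j + 1}"
            hit = (rng.random(len(vals)) < rate) & vals[col].notna().to_numpy()
            vals.loc[hit, col] = 0.0
            counts[f"zeros_{x}"] += int(hit.sum())
    if ar.outlier_rate_M > 0:
        for j in range(data.J):
            col = f"M{j + 1}"
            hit = (rng.random(len(vals)) < ar.outlier_rate_M) & vals[col].notna().to_numpy()
            vals.loc[hit, col] = vals.loc[hit, col] + ar.outlier_shift_M
            counts["outliers_M"] += int(hit.sum())
    out.meta["injected_artifacts"] = counts
    return out


def fruit_veg_scenario_params(J: int = 2) -> MEModelParams:
    """A realistic parameter set for a two-visit fruit-and-vegetable-style study.

    Log-scale self-reports with moderate scaling bias, a biomarker measured
    in its own units with a large scaling coefficient, small within-person
    intake variability relative to between-person variability, and strong
    positive correlations among self-report errors.
    """
    if J != 2:
        raise ValueError("the reference scenario is defined for J=2")
    return MEModelParams(
        J=2,
        beta_Q=0.66,
        beta_M=50.0,
        sigma2_T=0.07,
        sigma2_h=np.array([0.014, 0.009]),
        sigma2_Q=np.array([0.25, 0.25]),
        sigma2_R=np.array([0.41, 0.34]),
        sigma2_M=np.array([117.0, 181.0]),
        rho_QQ=np.array([[0.0, 0.65], [0.65, 0.0]]),
        rho_RR=np.array([[0.0, 0.56], [0.56, 0.0]]),
        rho_QR=np.array([[0.45, 0.38], [0.44, 0.51]]),
        alpha_Q=np.array([5.98, 6.04]),
        alpha_R=np.array([5.34, 5.52]),
        alpha_M=np.array([53.0, 62.5]),
    )


__all__ = [
    "ArtifactSpec",
    "CovariateBlockSpec",
    "CovariateColumn",
    "MissingnessSpec",
    "SimulationSpec",
    "apply_missingness",
    "gen_covariates",
    "gen_dataset",
    "inject_artifacts",
    "fruit_veg_scenario_params",
    "to_raw_scale",
]
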