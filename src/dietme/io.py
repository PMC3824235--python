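"""Data ingestion, preprocessing filters and study configuration.

Input is a wide CSV, one row per individual, with columns mapped to the
measurement slots and covariate roles by a :class:`StudyConfig` (YAML on
disk).  Preprocessing converts raw-scale intake data to the analysis scale:
non-positive self-report values become missing before log transformation
(reported zero intakes are treated as missing, not as true zeros), and
implausibly high biomarker values -- above the 75th percentile plus a
multiple of the interquartile range, computed per time point -- are set
missing because they plausibly reflect supplement use rather than diet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data import ValidationDataset
from .model import slot_labels

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Column mapping, transforms and filter settings for one study file.

    ``columns`` maps each measurement slot to a CSV column, e.g.
    ``{"Q": ["ffq_1", "ffq_2"], "R": ["diary_1", "diary_2"], "M": ["vitc_1", "vitc_2"]}``.
    ``covariate_columns`` maps roles T/Q/M to either a flat list of columns
    (time-constant) or a per-time-point list of lists.
    """

    columns: dict[str, list[str]] = field(default_factory=dict)
    covariate_columns: dict[str, list] = field(default_factory=dict)
    transforms: dict[str, str] = field(
        default_factory=lambda: {"Q": "log", "R": "log", "M": "none"})
    zeros_to_missing: bool = True
    outlier_rule: bool = True
    outlier_multiplier: float = 2.0
    outlier_quantile: float = 0.75
    beta_R_values: list[float] = field(default_factory=lambda: [1.0, 0.75, 0.5])
    rho_MM_values: list[float] = field(default_factory=lambda: [0.0, 0.2, 0.4])
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.outlier_multiplier <= 0:
            raise ValueError("outlier multiplier must be > 0")
        for x, t in self.transforms.items():
            if t not in ("log", "none"):
                raise ValueError(f"transform for {x} must be 'log' or 'none', got {t!r}")

    @property
    def J(self) -> int:
        lens = {len(v) for v in self.columns.values()}
        if len(lens) != 1:
            raise ValueError(f"measurement roles map different numbers of columns: "
                             f"{ {k: len(v) for k, v in self.columns.items()} }")
        return lens.pop()

    def validate_columns(self) -> None:
        seen: dict[str, str] = {}
        for role, cols in self.columns.items():
            if role not in ("Q", "R", "M"):
                raise ValueError(f"unknown measurement role {role!r}")
            for c in cols:
                if c in seen:
                    raise ValueError(
                        f"column {c!r} mapped to both {seen[c]} and {role}")
                seen[c] = role

    def covariate_cols(self, role: str, j: int) -> list[str]:
        spec = self.covariate_columns.get(role, [])
        if spec and isinstance(spec[0], (list, tuple)):
            return list(spec[j]) if j < len(spec) else []
        return list(spec)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in (
            "columns", "covariate_columns", "transforms", "zeros_to_missing",
            "outlier_rule", "outlier_multiplier", "outlier_quantile",
            "beta_R_values", "rho_MM_values", "seed", "output_dir")}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def read_dataset(path, config: StudyConfig) -> ValidationDataset:
    """Load a wide CSV into a raw-scale dataset using the configured mapping."""
    config.validate_columns()
    df = pd.read_csv(path)
    J = config.J
    needed = [c for cols in config.columns.values() for c in cols]
    for role in ("T", "Q", "M"):
        for j in range(J):
            needed += config.covariate_cols(role, j)
    missing = [c for c in set(needed) if c not in df.columns]
    if missing:
        raise ValueError(
            f"mapped column(s) {sorted(missing)} not in file; available columns: "
            f"{list(df.columns)}")
    for c in set(needed):
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna() & (df[c].astype(str).str.strip() != "")
        if bad.any():
            raise ValueError(
                f"non-numeric value in column {c!r} at row index {int(np.flatnonzero(bad)[0])}")
        df[c] = coerced

    meas = pd.DataFrame(index=df.index)
    for x in ("Q", "R", "M"):
        for j, col in enumerate(config.columns.get(x, [])):
            meas[f"{x}{j + 1}"] = df[col]
    for lab in slot_labels(J):
        if lab not in meas.columns:
            meas[lab] = np.nan
    covariates: dict[str, dict[int, pd.DataFrame]] = {}
    for role in ("T", "Q", "M"):
        blocks = {}
        for j in range(J):
            cols = config.covariate_cols(role, j)
            if cols:
                blocks[j] = df[cols].copy()
        if blocks:
            covariates[role] = blocks
    data = ValidationDataset(J=J, measurements=meas, covariates=covariates)
    data.meta["scale"] = "raw"
    data.meta["source"] = str(path)
    logger.info("read %d individuals x %d slots from %s", data.n, 3 * J, path)
    return data.drop_empty_individuals()


def _iqr_threshold(values: np.ndarray, quantile: float, multiplier: float) -> float:
    """Upper fence: Q(quantile) + multiplier * IQR with linear-interpolation quantiles."""
    finite = values[np.isfinite(values)]
    q1, q3 = np.quantile(finite, [1.0 - quantile, quantile], method="linear")
    return float(q3 + multiplier * (q3 - q1))


def preprocess(data: ValidationDataset, config: StudyConfig) -> ValidationDataset:
    """Raw scale -> analysis scale: zero/outlier filters then transforms.

    Per configuration: non-positive values in log-transformed instruments are
    set missing before the log; biomarker values strictly above the per-time
    upper fence (default 75th percentile + 2 IQR over non-missing values)
    are set missing.  Exclusion counts are logged and recorded in
    ``meta['exclusions']``.  Idempotent: applying it to already-processed
    data changes nothing.
    """
    if data.meta.get("scale") == "analysis":
        return data.copy()
    out = data.copy()
    vals = out.measurements
    exclusions: dict[str, int] = {}
    for x in ("Q", "R", "M"):
        transform = config.transforms.get(x, "none")
        for j in range(data.J):
            col = f"{x}{j + 1}"
            n_zero = 0
            if transform == "log" and config.zeros_to_missing:
                nonpos = vals[col].notna() & (vals[col] <= 0)
                n_zero = int(nonpos.sum())
                vals.loc[nonpos, col] = np.nan
            exclusions[f"nonpositive_{col}"] = n_zero
            if x == "M" and config.outlier_rule and vals[col].notna().any():
                thr = _iqr_threshold(vals[col].to_numpy(dtype=float),
                                     config.outlier_quantile, config.outlier_multiplier)
                high = vals[col].notna() & (vals[col] > thr)
                exclusions[f"outlier_{col}"] = int(high.sum())
                vals.loc[high, col] = np.nan
            if transform == "log":
                vals[col] = np.log(vals[col])
        if all(not np.isfinite(vals[f"{x}{j + 1}"]).any() for j in range(data.J)) \
                and any(np.isfinite(data.measurements[f"{x}{j + 1}"]).any()
                        for j in range(data.J)):
            raise ValueError(f"instrument {x} is entirely missing after filtering")
    for k, v in exclusions.items():
        if v:
            logger.info("preprocess: %s -> %d values set missing", k, v)
    out.meta["exclusions"] = exclusions
    out.meta["scale"] = "analysis"
    return out


__all__ = ["StudyConfig", "preprocess", "read_dataset"]
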