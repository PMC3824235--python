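"""Wide-format validation dataset container and missingness-pattern grouping.

A validation dataset holds, per individual, up to J repeats of the three
measurement types (FFQ ``Q``, food record ``R``, biomarker ``M``; any cell
may be missing) plus covariate design blocks for the truth (``T``), FFQ
(``Q``) and biomarker (``M``) parts of the model.  Covariates for the food
record are structurally absent (their effects are not identified).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import INSTRUMENTS, slot_labels

COVARIATE_ROLES = ("T", "Q", "M")


@dataclass
class ValidationDataset:
    """Per-individual measurements and covariate blocks.

    Parameters
    ----------
    J
        Number of time points (identical across individuals; missingness
        encodes absence).
    measurements
        DataFrame indexed by individual identifier with columns
        ``Q1..QJ, R1..RJ, M1..MJ``; NaN marks a missing measurement.
    covariates
        Mapping role -> {time index (0-based) -> design DataFrame aligned to
        ``measurements.index``}.  Numeric design columns only (categoricals
        pre-encoded).  Time-constant covariates simply repeat across j.
    """

    J: int
    measurements: pd.DataFrame
    covariates: dict[str, dict[int, pd.DataFrame]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = slot_labels(self.J)
        missing_cols = [c for c in expected if c not in self.measurements.columns]
        if missing_cols:
            raise ValueError(f"measurements missing slot columns {missing_cols}")
        self.measurements = self.measurements[expected].astype(float)
        for role in self.covariates:
            if role not in COVARIATE_ROLES:
                raise ValueError(
                    f"unknown covariate role {role!r}; expected one of {COVARIATE_ROLES} "
                    "(food-record covariates are structurally absent)")
            for j, block in self.covariates[role].items():
                if not block.index.equals(self.measurements.index):
                    raise ValueError(f"covariate block Z_{role}[{j}] index mismatch")

    @property
    def n(self) -> int:
        return len(self.measurements)

    @property
    def slot_names(self) -> list[str]:
        return slot_labels(self.J)

    def values(self) -> np.ndarray:
        """(n, 3J) array in slot order; NaN marks missing."""
        return self.measurements.to_numpy(dtype=float)

    def covariate_block(self, role: str, j: int) -> pd.DataFrame:
        """Design block Z_role at time j; empty frame when none configured."""
        blocks = self.covariates.get(role, {})
        if j in blocks:
            return blocks[j]
        return pd.DataFrame(index=self.measurements.index)

    def mean_truth_covariates(self) -> pd.DataFrame:
        """Per-individual average of the truth covariates over time (Zbar_i)."""
        blocks = self.covariates.get("T", {})
        if not blocks:
            return pd.DataFrame(index=self.measurements.index)
        stacked = sum(b.to_numpy(dtype=float) for b in blocks.values()) / len(blocks)
        cols = next(iter(blocks.values())).columns
        return pd.DataFrame(stacked, index=self.measurements.index, columns=cols)

    def design(self) -> dict[str, list[int]]:
        """Which slots carry at least one observation, for identifiability checks."""
        vals = self.values()
        out: dict[str, list[int]] = {}
        for xi, x in enumerate(INSTRUMENTS):
            out[x] = [j for j in range(self.J)
                      if np.isfinite(vals[:, xi * self.J + j]).any()]
        return out

    def drop_empty_individuals(self) -> "ValidationDataset":
        """Remove individuals with no observed measurement at all."""
        keep = np.isfinite(self.values()).any(axis=1)
        return self.subset(pd.Series(keep, index=self.measurements.index))

    def subset(self, mask) -> "ValidationDataset":
        """Row-filtered copy (mask is a boolean Series/array over individuals)."""
        mask = np.asarray(mask, dtype=bool)
        meas = self.measurements.loc[mask].copy()
        cov = {role: {j: block.loc[mask].copy() for j, block in blocks.items()}
               for role, blocks in self.covariates.items()}
        return ValidationDataset(J=self.J, measurements=meas, covariates=cov,
                                 meta=dict(self.meta))

    def copy(self) -> "ValidationDataset":
        return self.subset(np.ones(self.n, dtype=bool))

    def fingerprint(self) -> str:
        """Stable content hash of the measurement table (for grid bookkeeping)."""
        import hashlib
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(np.nan_to_num(self.values(), nan=-1e308)).tobytes())
        h.update(str(list(self.measurements.index)).encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class MissingPattern:
    """One observed-slot mask and the individuals sharing it."""

    mask: tuple[bool, ...]
    count: int
    indices: np.ndarray  # positional row indices into the dataset

    @property
    def n_observed(self) -> int:
        return int(sum(self.mask))


def group_patterns(data: ValidationDataset) -> list[MissingPattern]:
    """Partition individuals by their observed-slot mask.

    Every retained individual appears in exactly one pattern; fully-missing
    rows are excluded (the dataset invariant requires at least one observed
    measurement per retained individual).
    """
    obs = np.isfinite(data.values())
    keep = obs.any(axis=1)
    masks, inverse = np.unique(obs[keep], axis=0, return_inverse=True)
    rows = np.flatnonzero(keep)
    patterns = []
    for m in range(len(masks)):
        idx = rows[inverse == m]
        patterns.append(MissingPattern(mask=tuple(bool(b) for b in masks[m]),
                                       count=len(idx), indices=idx))
    return patterns


def write_dataset(data: ValidationDataset, path) -> None:
    """Write the wide measurement table plus covariate columns to CSV."""
    out = data.measurements.copy()
    for role, blocks in data.covariates.items():
        for j, block in blocks.items():
            for col in block.columns:
                out[f"Z{role}{j + 1}_{col}"] = block[col]
    out.index.name = out.index.name or "id"
    out.to_csv(path)


def long_to_wide(df: pd.DataFrame, id_col: str = "id", time_col: str = "time",
                 value_cols: tuple[str, ...] = ("Q", "R", "M")) -> pd.DataFrame:
    """Convenience converter from long (one row per individual-time) to wide layout."""
    wide = df.pivot(index=id_col, columns=time_col, values=list(value_cols))
    wide.columns = [f"{x}{int(t)}" for x, t in wide.columns]
    return wide


__all__ = [
    "COVARIATE_ROLES",
    "MissingPattern",
    "ValidationDataset",
    "group_patterns",
    "long_to_wide",
    "write_dataset",
]
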