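"""Sensitivity analysis over the fixed, unidentified pair (beta_R, rho_MM).

Because the food-record scaling and the repeated-biomarker error correlation
cannot be estimated from the data, the model is refitted over a grid of
plausible fixed values and all conclusions are read across the grid.  The
default grid pairs beta_R in {1, 0.75, 0.5} with rho_MM in {0, 0.2, 0.4}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd

from .data import ValidationDataset
from .derived import DerivedQuantities
from .estimation import FitOptions, FitResult, SEResult, fit_ml, standard_errors
from .model import SensitivitySetting

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensitivityGrid:
    """The grid of fixed (beta_R, rho_MM) settings to sweep."""

    beta_R_values: tuple[float, ...] = (1.0, 0.75, 0.5)
    rho_MM_values: tuple[float, ...] = (0.0, 0.2, 0.4)

    def __post_init__(self) -> None:
        if not self.beta_R_values or not self.rho_MM_values:
            raise ValueError("grid value lists must be nonempty")
        if any(b <= 0 for b in self.beta_R_values):
            raise ValueError("beta_R values must be positive")
        if any(not 0 <= r < 1 for r in self.rho_MM_values):
            raise ValueError("rho_MM values must lie in [0, 1)")
        for name, vals in (("beta_R", self.beta_R_values), ("rho_MM", self.rho_MM_values)):
            if len(set(vals)) != len(vals):
                raise ValueError(f"duplicate {name} values in grid")

    def cells(self) -> list[SensitivitySetting]:
        return [SensitivitySetting(beta_R=b, rho_MM=r)
                for b, r in product(self.beta_R_values, self.rho_MM_values)]


@dataclass
class CellResult:
    """Fit and derived quantities for one grid cell, or its failure diagnostic."""

    sens: SensitivitySetting
    fit: FitResult | None = None
    derived: DerivedQuantities | None = None
    se: SEResult | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None and self.fit is not None and self.fit.converged


@dataclass
class SensitivityGridResult:
    """All cells of one sweep, fitted on one identical preprocessed dataset."""

    grid: SensitivityGrid
    cells: dict[tuple[float, float], CellResult]
    dataset_fingerprint: str

    def cell(self, beta_R: float, rho_MM: float) -> CellResult:
        return self.cells[(beta_R, rho_MM)]

    @property
    def n_failed(self) -> int:
        return sum(0 if c.ok else 1 for c in self.cells.values())


def rescale_food_record_scaling(params, c: float):
    """The exact parameter map induced by replacing beta_R with c * beta_R.

    Multiplying the food-record scaling by c while keeping the implied
    covariance fixed requires beta_Q -> c beta_Q, beta_M -> c beta_M,
    sigma2_T -> sigma2_T / c^2, sigma2_h -> sigma2_h / c^2, with error
    variances and correlations untouched.
    """
    return params.copy(beta_Q=c * params.beta_Q, beta_M=c * params.beta_M,
                       sigma2_T=params.sigma2_T / c**2,
                       sigma2_h=params.sigma2_h / c**2)


def run_grid(data: ValidationDataset, grid: SensitivityGrid | None = None,
             options: FitOptions | None = None, compute_se: bool = False,
             warm_start: bool = True) -> SensitivityGridResult:
    """Fit every grid cell on the identical dataset.

    Within a rho_MM column, later beta_R cells are warm-started from the
    column's first solution pushed through the exact beta_R rescaling map
    (results remain start-independent to optimizer tolerance); each new
    rho_MM column starts from fresh moment-based values because no exact
    map exists without re-solving.  Per-cell failures are recorded in the
    cell rather than aborting the sweep.
    """
    grid = grid or SensitivityGrid()
    options = options or FitOptions()
    cells: dict[tuple[float, float], CellResult] = {}
    column_fit: dict[float, FitResult] = {}
    for sens in grid.cells():
        key = (sens.beta_R, sens.rho_MM)
        opts = options
        anchor = column_fit.get(sens.rho_MM)
        if warm_start and anchor is not None and options.start is None:
            c = sens.beta_R / anchor.sens.beta_R
            opts = replace(options, start=rescale_food_record_scaling(anchor.params, c))
        try:
            fit = fit_ml(data, sens, opts)
            cell = CellResult(sens=sens, fit=fit, derived=fit.derived())
            if not fit.converged:
                cell.error = f"non-convergence: {fit.message}"
            elif compute_se:
                cell.se = standard_errors(fit, data, method="delta")
                cell.derived = cell.se.derived
            if sens.rho_MM not in column_fit and fit.converged:
                column_fit[sens.rho_MM] = fit
        except Exception as exc:  # recorded, run continues
            logger.warning("grid cell %s failed: %s", key, exc)
            cell = CellResult(sens=sens, error=f"{type(exc).__name__}: {exc}")
        cells[key] = cell
    return SensitivityGridResult(grid=grid, cells=cells,
                                 dataset_fingerprint=data.fingerprint())


def _fmt(value: float | None, se: float | None) -> str:
    if value is None or not np.isfinite(value):
        return "NC"
    if se is not None and np.isfinite(se):
        return f"{value:.3g} ({se:.2g})"
    return f"{value:.3g}"


@dataclass
class GridSummary:
    """A rendered sensitivity table plus its machine-readable twin."""

    table: pd.DataFrame   # formatted strings, rho_MM as columns
    values: pd.DataFrame  # tidy numeric rows: quantity, beta_R, rho_MM, value, se
    footnotes: list[str]

    def __str__(self) -> str:
        txt = self.table.to_string()
        if self.footnotes:
            txt += "\n" + "\n".join(f"[{i + 1}] {f}" for i, f in enumerate(self.footnotes))
        return txt

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index=False)


def _collect_rows(result: SensitivityGridResult, layout: str):
    rows = []
    for (b, r), cell in result.cells.items():
        if not cell.ok:
            rows.append({"quantity": "__failed__", "beta_R": b, "rho_MM": r,
                         "value": np.nan, "se": np.nan, "note": cell.error})
            continue
        se_dict = cell.se.param_se_dict() if cell.se else {}
        dflat = cell.derived.flat()
        dse = cell.derived.se if cell.derived else {}
        if layout == "rdr":
            for name, val in dflat.items():
                rows.append({"quantity": name, "beta_R": b, "rho_MM": r,
                             "value": val, "se": dse.get(name, np.nan), "note": ""})
        elif layout == "params":
            fit = cell.fit
            for name, val in zip(fit.packer.names, fit.packer.natural(fit.x)):
                rows.append({"quantity": name, "beta_R": b, "rho_MM": r,
                             "value": float(val), "se": se_dict.get(name, np.nan),
                             "note": ""})
        else:
            raise ValueError("layout must be one of 'rdr', 'params', 'covariates'")
    return rows


def summarize_grid(result: SensitivityGridResult, layout: str = "rdr",
                   gammas: dict | None = None) -> GridSummary:
    """Assemble a sensitivity table: rho_MM across columns, quantities (and
    beta_R where they depend on it) down the rows; failed cells render as NC.

    ``layout='covariates'`` formats externally supplied
    :class:`~dietme.estimation.GammaEstimate` objects keyed by
    ``(role, beta_R, rho_MM)`` since covariate effects are estimated in the
    second step rather than inside the covariance fit.
    """
    footnotes = [f"dataset fingerprint {result.dataset_fingerprint}"]
    failed = [(b, r) for (b, r), c in result.cells.items() if not c.ok]
    if failed:
        notes = {f"({b}, {r}): {result.cells[(b, r)].error}" for b, r in failed}
        footnotes += sorted(notes)

    if layout == "covariates":
        if not gammas:
            raise ValueError("layout='covariates' requires the gammas mapping")
        rows = []
        for (role, b, r), est in gammas.items():
            for name, coef, se in zip(est.names, est.coef, est.se):
                rows.append({"quantity": f"gamma_{role}:{name}", "beta_R": b,
                             "rho_MM": r, "value": float(coef), "se": float(se),
                             "note": est.method})
        values = pd.DataFrame(rows)
    else:
        values = pd.DataFrame(_collect_rows(result, layout))
    if values.empty:
        raise ValueError("no successful cells to summarize")

    ok = values[values["quantity"] != "__failed__"]
    piv = {}
    for (q, b), sub in ok.groupby(["quantity", "beta_R"]):
        row = {}
        for r in result.grid.rho_MM_values:
            hit = sub[sub["rho_MM"] == r]
            if len(hit):
                row[r] = _fmt(float(hit["value"].iloc[0]),
                              float(hit["se"].iloc[0]) if np.isfinite(hit["se"].iloc[0])
                              else None)
            else:
                row[r] = "NC"
        piv[(q, b)] = row
    table = pd.DataFrame.from_dict(piv, orient="index")
    table.index.names = ["quantity", "beta_R"]
    table.columns = [f"rho_MM={c}" for c in table.columns]
    return GridSummary(table=table, values=values, footnotes=footnotes)


__all__ = [
    "CellResult",
    "GridSummary",
    "SensitivityGrid",
    "SensitivityGridResult",
    "run_grid",
    "summarize_grid",
]
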