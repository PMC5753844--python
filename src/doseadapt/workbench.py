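"""Design x scenario grids: operating characteristics and factor effects.

Runs replicated simulated trials over a grid of (design, scenario) cells,
estimates family-wise type I error (flat dose-response cells) and
disjunctive power (effect-bearing cells) as per-cell success proportions
with binomial confidence intervals, and summarises how design options and
scenario assumptions move power with a normal linear model fitted to the
cell proportions (weighted by replicates).

Replicate seeds are bound to (base seed, cell index, replicate index), so
results are invariant to execution order and to the degree of parallelism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from statsmodels.stats.proportion import proportion_confint

from .ndlm import MCMCSettings
from .scenarios import DoseResponseCurve, ScenarioSpec
from .trial import DesignSpec, run_trial

__all__ = [
    "GridCell",
    "GridSpec",
    "run_grid",
    "estimate_error_rates",
    "factorial_effects",
    "default_grid",
]

logger = logging.getLogger(__name__)

_BOOKKEEPING = {"cell", "n_success", "n_reps", "n_failed", "prop", "ci_low", "ci_high", "null"}


@dataclass(frozen=True)
class GridCell:
    """One design x scenario combination with its factor labels for analysis."""

    design: DesignSpec
    scenario: ScenarioSpec
    factors: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.design.name or "+".join(f"{v}" for v in self.factors.values())


@dataclass(frozen=True)
class GridSpec:
    """A (possibly fractional) grid of cells with a replicate count and base seed."""

    cells: tuple[GridCell, ...]
    replicates: int = 200
    base_seed: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        if not self.cells:
            raise ValueError("grid needs at least one cell")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def cell_seed(self, cell_index: int, rep: int) -> np.random.SeedSequence:
        """Collision-free seed for one replicate, independent of run order."""
        return np.random.SeedSequence(
            entropy=self.base_seed, spawn_key=(cell_index, rep)
        )


def _run_one(grid: GridSpec, i: int, rep: int):
    cell = grid.cells[i]
    try:
        res = run_trial(cell.design, cell.scenario, grid.cell_seed(i, rep))
        return i, bool(res.success), None
    except Exception as exc:  # pragma: no cover - defensive
        logger.error("trial failed (cell %d rep %d): %s", i, rep, exc)
        return i, None, str(exc)


def run_grid(grid: GridSpec, n_jobs: int = 1, progress: bool = False) -> pd.DataFrame:
    """Run every cell x replicate; one row per cell with exact bookkeeping.

    Failed replicates are recorded in ``n_failed`` and excluded from the
    success proportion; the run continues.
    """
    tasks = [(i, r) for i in range(len(grid.cells)) for r in range(grid.replicates)]
    if n_jobs == 1:
        outcomes = [_run_one(grid, i, r) for i, r in tasks]
    else:
        outcomes = Parallel(n_jobs=n_jobs)(
            delayed(_run_one)(grid, i, r) for i, r in tasks
        )
    rows = []
    for i, cell in enumerate(grid.cells):
        mine = [o for o in outcomes if o[0] == i]
        n_failed = sum(1 for o in mine if o[1] is None)
        n_ok = len(mine) - n_failed
        n_success = sum(1 for o in mine if o[1])
        prop = n_success / n_ok if n_ok else np.nan
        lo, hi = (
            proportion_confint(n_success, n_ok, alpha=0.05, method="wilson")
            if n_ok
            else (np.nan, np.nan)
        )
        row = {"cell": cell.name, "null": cell.scenario.is_null}
        row.update(cell.factors)
        row.update(
            n_success=n_success,
            n_reps=n_ok,
            n_failed=n_failed,
            prop=prop,
            ci_low=float(lo),
            ci_high=float(hi),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _pooled(sub: pd.DataFrame) -> dict:
    n = int(sub["n_reps"].sum())
    k = int(sub["n_success"].sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return {
        "n_success": k,
        "n_trials": n,
        "proportion": k / n,
        "ci_low": float(lo),
        "ci_high": float(hi),
    }


def estimate_error_rates(table: pd.DataFrame, by: list[str] | None = None) -> dict:
    """Pooled type I error (null cells) and power (effect cells), with CIs.

    ``by`` optionally adds per-factor-level pooled summaries.  Returns a dict
    with keys ``type_i_error`` (absent, with a warning, if the table has no
    null rows), ``power``, and ``by_factor``.
    """
    out: dict = {"by_factor": {}}
    null_rows = table[table["null"]]
    effect_rows = table[~table["null"]]
    if len(null_rows):
        out["type_i_error"] = _pooled(null_rows)
    else:
        logger.warning("no null (flat-curve) cells: type I error summary absent")
    if len(effect_rows):
        out["power"] = _pooled(effect_rows)
    for factor in by or []:
        out["by_factor"][factor] = {
            "power": {
                str(level): _pooled(sub)
                for level, sub in effect_rows.groupby(factor)
            }
            if len(effect_rows)
            else {},
            "type_i_error": {
                str(level): _pooled(sub)
                for level, sub in null_rows.groupby(factor)
            }
            if len(null_rows)
            else {},
        }
    return out


def factorial_effects(
    table: pd.DataFrame,
    factors: list[str],
    two_way: list[tuple[str, str]] | None = None,
    references: dict | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """Normal-linear-model summary of factor effects on the success proportion.

    Fits cell proportions on factor main effects (plus requested two-way
    interactions) by (weighted) least squares, weights = replicates per cell.
    Returns one row per factor level: the estimated mean change in the
    success proportion relative to the reference level, its 95% CI and
    p-value; reference levels appear with effect 0 by construction.

    Fractional grids can alias terms; aliased columns are reported through
    the ``aliased`` attribute of the returned frame.
    """
    import statsmodels.api as sm
    from patsy import dmatrix

    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 observed levels")
    references = references or {}
    terms = []
    for f in factors:
        ref = references.get(f, sorted(table[f].astype(str).unique())[0])
        terms.append(f"C({f}, Treatment(reference={ref!r}))")
    for a, b in two_way or []:
        ra = references.get(a, sorted(table[a].astype(str).unique())[0])
        rb = references.get(b, sorted(table[b].astype(str).unique())[0])
        terms.append(
            f"C({a}, Treatment(reference={ra!r})):C({b}, Treatment(reference={rb!r}))"
        )
    tab = table.copy()
    for f in factors:
        tab[f] = tab[f].astype(str)
    X = dmatrix(" + ".join(terms), tab, return_type="dataframe")
    w = tab["n_reps"].to_numpy(dtype=float) if weighted else np.ones(len(tab))
    model = sm.WLS(tab["prop"].to_numpy(dtype=float), X, weights=w)
    fit = model.fit()

    rank = np.linalg.matrix_rank(X.to_numpy())
    aliased: list[str] = []
    if rank < X.shape[1]:
        # identify columns not independent of the preceding ones
        for c in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X.to_numpy()[:, : c + 1]) == np.linalg.matrix_rank(
                X.to_numpy()[:, :c]
            ):
                aliased.append(X.columns[c])
        logger.warning("aliased terms in fractional grid: %s", aliased)

    ci = fit.conf_int()
    rows = []
    for f in factors:
        ref = references.get(f, sorted(table[f].astype(str).unique())[0])
        rows.append(
            {"factor": f, "level": str(ref), "effect": 0.0, "ci_low": 0.0,
             "ci_high": 0.0, "pvalue": np.nan, "reference": True, "aliased": False}
        )
        for level in sorted(table[f].astype(str).unique()):
            if str(level) == str(ref):
                continue
            col = f"C({f}, Treatment(reference={ref!r}))[T.{level}]"
            if col not in X.columns:
                continue
            rows.append(
                {
                    "factor": f,
                    "level": str(level),
                    "effect": float(fit.params[col]),
                    "ci_low": float(ci.loc[col, 0]),
                    "ci_high": float(ci.loc[col, 1]),
                    "pvalue": float(fit.pvalues[col]),
                    "reference": False,
                    "aliased": col in aliased,
                }
            )
    for col in X.columns:
        if ":" in col:
            rows.append(
                {
                    "factor": "interaction",
                    "level": col,
                    "effect": float(fit.params[col]),
                    "ci_low": float(ci.loc[col, 0]),
                    "ci_high": float(ci.loc[col, 1]),
                    "pvalue": float(fit.pvalues[col]),
                    "reference": False,
                    "aliased": col in aliased,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["aliased"] = aliased
    out.attrs["rsquared"] = float(fit.rsquared)
    return out


def default_grid(
    replicates: int = 200,
    base_seed: int = 1,
    mcmc: MCMCSettings | None = None,
    include_null: bool = True,
    utility_m: int = 100,
) -> GridSpec:
    """A small documented orthogonal fraction of the design x scenario space.

    Covers both adaptation rules, both placebo rates, the three
    effect-bearing curve shapes and (optionally) flat null cells, at the
    reference noise level sigma_e = 17.9 mL, effect 16.4 mL, 4 enrolled per
    month, on the full six-dose grid with the evenly spread five-interim
    schedule.  Intended as a desk-scale template; real studies extend the
    cell list.
    """
    mcmc = mcmc or MCMCSettings()
    cells: list[GridCell] = []
    base_design = DesignSpec(mcmc=mcmc, utility_m=utility_m)
    shapes = ["monotone_plateau", "monotone_linear", "non_monotone"]
    for rule in ("play_the_winner", "ed95_precision"):
        for placebo in ("1/J", "2/J"):
            design = replace(base_design, rule=rule, placebo_rate=placebo)
            if include_null:
                cells.append(
                    GridCell(
                        design,
                        ScenarioSpec(curve=DoseResponseCurve("flat")),
                        {"rule": rule, "placebo": placebo, "shape": "flat"},
                    )
                )
            for shape in shapes:
                cells.append(
                    GridCell(
                        design,
                        ScenarioSpec(curve=DoseResponseCurve(shape)),
                        {"rule": rule, "placebo": placebo, "shape": shape},
                    )
                )
    return GridSpec(tuple(cells), replicates=replicates, base_seed=base_seed)
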