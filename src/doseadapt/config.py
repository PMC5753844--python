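"""YAML/JSON configuration for designs, scenarios and grids.

Config keys mirror the dataclass fields of :class:`~doseadapt.trial.DesignSpec`,
:class:`~doseadapt.scenarios.PopulationModel` and
:class:`~doseadapt.scenarios.DoseResponseCurve` exactly, e.g.::

    # design.yaml
    dose_grid: [0.4, 0.8, 1.0, 1.2, 1.5, 1.8]
    n_total: 100
    schedule: [16, 32, 50, 66, 84]
    placebo_rate: 2/J
    rule: ed95_precision
    mcmc: {n_retained: 2000, n_burn: 1000}

    # scenario.yaml
    population: {sigma_e: 17.9, hetero: false}
    curve: {shape: non_monotone, effect_at_best: 16.4, proportional: none}
    enrol_rate_per_month: 4
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .ndlm import MCMCSettings, NDLMPriors
from .scenarios import DoseResponseCurve, PopulationModel, ScenarioSpec
from .trial import DesignSpec, TrialResult
from .workbench import GridCell, GridSpec

__all__ = [
    "load_design",
    "load_scenario",
    "load_grid",
    "result_to_dict",
    "save_result",
]


def _read(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    text = Path(source).read_text()
    return yaml.safe_load(text) or {}


def load_design(source) -> DesignSpec:
    """Build a DesignSpec from a YAML/JSON file path or a dict."""
    cfg = _read(source)
    if "mcmc" in cfg:
        cfg["mcmc"] = MCMCSettings(**cfg["mcmc"])
    if "priors" in cfg:
        pr = dict(cfg["priors"])
        if "w_bounds" in pr:
            pr["w_bounds"] = tuple(pr["w_bounds"])
        cfg["priors"] = NDLMPriors(**pr)
    if "dose_grid" in cfg:
        cfg["dose_grid"] = tuple(cfg["dose_grid"])
    if "schedule" in cfg:
        cfg["schedule"] = tuple(cfg["schedule"])
    return DesignSpec(**cfg)


def load_scenario(source) -> ScenarioSpec:
    """Build a ScenarioSpec from a YAML/JSON file path or a dict."""
    cfg = _read(source)
    if "population" in cfg:
        cfg["population"] = PopulationModel(**cfg["population"])
    if "curve" in cfg:
        cv = dict(cfg["curve"])
        if "dose_grid" in cv:
            cv["dose_grid"] = tuple(cv["dose_grid"])
        cfg["curve"] = DoseResponseCurve(**cv)
    return ScenarioSpec(**cfg)


def load_grid(source) -> GridSpec:
    """Build a GridSpec from a YAML/JSON file path or a dict.

    Expected keys: ``replicates``, ``base_seed`` and ``cells``, each cell a
    mapping with ``design``, ``scenario`` and optional ``factors``.
    """
    cfg = _read(source)
    cells = tuple(
        GridCell(
            design=load_design(c["design"]),
            scenario=load_scenario(c["scenario"]),
            factors=dict(c.get("factors", {})),
        )
        for c in cfg["cells"]
    )
    return GridSpec(
        cells,
        replicates=int(cfg.get("replicates", 200)),
        base_seed=int(cfg.get("base_seed", 1)),
    )


def result_to_dict(result: TrialResult) -> dict:
    """JSON-serialisable view of a TrialResult."""
    return {
        "success": bool(result.success),
        "p_efficacy": [float(p) for p in result.p_efficacy],
        "ed95_arm": int(result.ed95_arm),
        "ed95_mg": float(result.ed95_mg),
        "gamma_mean": [float(g) for g in result.gamma_mean],
        "arm_counts": [int(c) for c in result.arm_counts],
        "stage_counts": np.asarray(result.stage_counts).astype(int).tolist(),
        "allocation_history": [
            [float(p) for p in pi] for pi in result.allocation_history
        ],
        "interim_n_complete": [int(n) for n in result.interim_n_complete],
        "warnings": list(result.warnings),
    }


def save_result(result: TrialResult, path) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result), indent=2))
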