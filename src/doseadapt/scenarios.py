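"""Virtual-participant simulation for menstrual-blood-loss dose-finding trials.

The data-generating model mirrors the structure of a heavy-menstrual-bleeding
(HMB) trial: each woman has a latent mean menstrual blood loss (MBL, mL per
period) ``S`` drawn from a log-normal population distribution, and every
cycle's measurement is ``S`` plus an independent Gaussian within-subject
deviation ``E`` with SD ``sigma_e``.  Sharing ``S`` across repeat measurements
induces compound symmetry and, together with the eligibility screen
(average of two screening cycles >= 50 mL), makes regression to the mean
arise with no extra mechanism.

Treatment is applied as a *reduction* of the latent mean at follow-up: a
subject on arm ``j`` with true effect ``D`` (mL) has follow-up measurements
``S - D + E``.  The analysed response is the reduction

    Y = Ybl - Yfu,   Ybl = (Y1 + Y2)/2,   Yfu = (Y3 + Y4)/2,

so efficacious doses give positive expected responses and positive
dose-vs-placebo contrasts downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PopulationModel",
    "DoseResponseCurve",
    "ScenarioSpec",
    "Subject",
    "draw_subject",
    "screen",
    "true_effect",
    "follow_up",
    "simulate_cohort",
    "cohort_to_frame",
]

CurveShape = Literal["flat", "monotone_plateau", "monotone_linear", "non_monotone"]
Proportional = Literal["none", "p10", "p20"]


@dataclass(frozen=True)
class PopulationModel:
    """Population distribution of MBL and the within-subject error model.

    Parameters
    ----------
    meanlog, sdlog
        Log-scale parameters of the log-normal law of the latent subject
        mean ``S`` (mL).  Defaults give a population median of 40 mL with a
        heavy right tail — a calibration choice, not an empirical estimate.
    eligibility_threshold
        Minimum average of the two screening measurements (mL) for trial
        entry; inclusive.
    sigma_e
        SD (mL) of the within-subject cycle-to-cycle deviation ``E``.
    hetero
        If True, follow-up deviations are heteroscedastic with
        ``sigma_e,i = sigma_e * (Ybl_i / hetero_ref)**hetero_kappa`` so that
        variability increases with the subject's baseline MBL.  Screening
        draws stay homoscedastic (the baseline does not exist yet).
    """

    meanlog: float = math.log(40.0)
    sdlog: float = 0.6
    eligibility_threshold: float = 50.0
    sigma_e: float = 17.9
    hetero: bool = False
    hetero_kappa: float = 0.5
    hetero_ref: float = 50.0

    def __post_init__(self) -> None:
        if self.sdlog <= 0:
            raise ValueError(f"sdlog must be > 0, got {self.sdlog}")
        if self.sigma_e < 0:
            raise ValueError(f"sigma_e must be >= 0, got {self.sigma_e}")
        if self.eligibility_threshold <= 0:
            raise ValueError(
                f"eligibility_threshold must be > 0, got {self.eligibility_threshold}"
            )

    def followup_sigma(self, ybl: float) -> float:
        """Within-subject SD used at follow-up for a subject with baseline ``ybl``."""
        if not self.hetero:
            return self.sigma_e
        return self.sigma_e * (max(ybl, 0.0) / self.hetero_ref) ** self.hetero_kappa


# Dose (mg) where the saturating shape reaches its plateau, and the dose
# where the non-monotone shape peaks (between 1.0 and 1.2 mg).
_PLATEAU_DOSE = 1.2
_PEAK_DOSE = 1.1
_PEAK_LOGWIDTH = 1.0


@dataclass(frozen=True)
class DoseResponseCurve:
    """True dose-response curve of a simulation scenario.

    ``effect_at_best`` is the reduction in MBL (mL) at the most effective
    dose; other doses are scaled by the shape's relative profile.  Under
    ``proportional='p10'``/``'p20'`` the best dose's effect is instead 10%/20%
    of the subject's baseline measurement, with the same relative profile
    across doses.
    """

    shape: CurveShape
    dose_grid: tuple[float, ...] = (0.4, 0.8, 1.0, 1.2, 1.5, 1.8)
    effect_at_best: float = 16.4
    proportional: Proportional = "none"

    def __post_init__(self) -> None:
        grid = tuple(float(d) for d in self.dose_grid)
        object.__setattr__(self, "dose_grid", grid)
        if any(d <= 0 for d in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ValueError("dose_grid must be strictly increasing and positive")
        if self.effect_at_best < 0:
            raise ValueError("effect_at_best must be >= 0")
        if self.shape not in ("flat", "monotone_plateau", "monotone_linear", "non_monotone"):
            raise ValueError(f"unknown curve shape {self.shape!r}")
        if self.proportional not in ("none", "p10", "p20"):
            raise ValueError(f"unknown proportional mode {self.proportional!r}")

    def relative_profile(self) -> np.ndarray:
        """Per-dose effects relative to the best dose (max normalised to 1).

        Flat curves return all zeros.
        """
        d = np.asarray(self.dose_grid, dtype=float)
        if self.shape == "flat":
            return np.zeros_like(d)
        if self.shape == "monotone_linear":
            raw = d
        elif self.shape == "monotone_plateau":
            raw = np.minimum(d, _PLATEAU_DOSE)
        else:  # non_monotone: quadratic in log dose, clipped at zero
            raw = 1.0 - ((np.log(d) - math.log(_PEAK_DOSE)) / _PEAK_LOGWIDTH) ** 2
            raw = np.clip(raw, 0.0, None)
        return raw / raw.max()

    def best_dose_index(self) -> int:
        """1-based arm index of the most effective dose (ties -> smallest dose)."""
        rel = self.relative_profile()
        return int(np.argmax(rel)) + 1

    def effects(self, ybl: float | None = None) -> np.ndarray:
        """Absolute per-dose effects (mL reduction) for a given baseline."""
        rel = self.relative_profile()
        if self.proportional == "none":
            return self.effect_at_best * rel
        if ybl is None:
            raise ValueError("proportional effects require the subject's baseline Ybl")
        frac = 0.10 if self.proportional == "p10" else 0.20
        return frac * ybl * rel


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the scenario space: population, truth, and enrolment rate."""

    population: PopulationModel = field(default_factory=PopulationModel)
    curve: DoseResponseCurve = field(default_factory=lambda: DoseResponseCurve("flat"))
    enrol_rate_per_month: float = 4.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.enrol_rate_per_month <= 0:
            raise ValueError("enrol_rate_per_month must be > 0")

    @property
    def is_null(self) -> bool:
        return self.curve.shape == "flat"

    def with_(self, **kwargs) -> "ScenarioSpec":
        return replace(self, **kwargs)


@dataclass
class Subject:
    """One virtual participant.

    ``arm`` is 0 for placebo and 1..J-1 for active doses (index into the dose
    grid is ``arm - 1``).  Times are calendar days from trial start.
    """

    id: int
    S: float
    Y1: float
    Y2: float
    t_screen: float = 0.0
    arm: int | None = None
    D: float | None = None
    Y3: float | None = None
    Y4: float | None = None
    t_rand: float | None = None
    t_outcome: float | None = None

    @property
    def Ybl(self) -> float:
        return 0.5 * (self.Y1 + self.Y2)

    @property
    def Yfu(self) -> float | None:
        if self.Y3 is None or self.Y4 is None:
            return None
        return 0.5 * (self.Y3 + self.Y4)

    @property
    def Y(self) -> float | None:
        """Analysed response: reduction from baseline to follow-up (mL)."""
        yfu = self.Yfu
        return None if yfu is None else self.Ybl - yfu

    @property
    def randomised(self) -> bool:
        return self.arm is not None

    @property
    def outcome_complete(self) -> bool:
        return self.Y3 is not None


def draw_subject(pop: PopulationModel, rng: np.random.Generator, id: int = 0) -> Subject:
    """Draw a screened, pre-randomisation subject.

    One latent mean ``S`` per subject, a fresh deviation ``E`` per
    measurement: ``Y1, Y2 = S + E``.
    """
    s = float(rng.lognormal(pop.meanlog, pop.sdlog))
    e = rng.normal(0.0, pop.sigma_e, size=2) if pop.sigma_e > 0 else np.zeros(2)
    return Subject(id=id, S=s, Y1=s + float(e[0]), Y2=s + float(e[1]))


def screen(subject: Subject, threshold: float) -> bool:
    """Eligibility: average screening MBL at least ``threshold`` (inclusive)."""
    return subject.Ybl >= threshold


def true_effect(curve: DoseResponseCurve, j: int, ybl: float) -> float:
    """True MBL reduction (mL) for arm ``j`` given the subject's baseline.

    Placebo (j=0) and flat curves return 0.
    """
    if j == 0 or curve.shape == "flat":
        return 0.0
    if not 1 <= j <= len(curve.dose_grid):
        raise IndexError(f"arm index {j} outside 1..{len(curve.dose_grid)}")
    return float(curve.effects(ybl)[j - 1])


def follow_up(subject: Subject, pop: PopulationModel, rng: np.random.Generator) -> Subject:
    """Add the two follow-up measurements ``Y3, Y4 = S - D + E`` in place."""
    if subject.arm is None or subject.D is None:
        raise RuntimeError("follow_up requires a randomised subject (arm and D set)")
    sig = pop.followup_sigma(subject.Ybl)
    e = rng.normal(0.0, sig, size=2) if sig > 0 else np.zeros(2)
    mean = subject.S - subject.D
    subject.Y3 = mean + float(e[0])
    subject.Y4 = mean + float(e[1])
    return subject


def simulate_cohort(
    n: int,
    pop: PopulationModel,
    curve: DoseResponseCurve,
    arms: Sequence[int],
    rng: np.random.Generator,
) -> list[Subject]:
    """Screen until ``n`` eligible subjects are found and follow them up.

    ``arms`` assigns the arm of each eligible subject in order (length >= n).
    Convenience wrapper used by examples and tests; the trial engine drives
    the same primitives in calendar time.
    """
    out: list[Subject] = []
    sid = 0
    while len(out) < n:
        subj = draw_subject(pop, rng, id=sid)
        sid += 1
        if not screen(subj, pop.eligibility_threshold):
            continue
        subj.arm = int(arms[len(out)])
        subj.D = true_effect(curve, subj.arm, subj.Ybl)
        follow_up(subj, pop, rng)
        out.append(subj)
    return out


def cohort_to_frame(subjects: Sequence[Subject]):
    """Cohort as a pandas DataFrame (CSV-exportable)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "S": [s.S for s in subjects],
            "Y1": [s.Y1 for s in subjects],
            "Y2": [s.Y2 for s in subjects],
            "Ybl": [s.Ybl for s in subjects],
            "arm": [s.arm for s in subjects],
            "D": [s.D for s in subjects],
            "Y3": [s.Y3 for s in subjects],
            "Y4": [s.Y4 for s in subjects],
            "Yfu": [s.Yfu for s in subjects],
            "Y": [s.Y for s in subjects],
            "t_rand": [s.t_rand for s in subjects],
            "t_outcome": [s.t_outcome for s in subjects],
        }
    )
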