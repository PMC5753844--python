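"""Calendar-time simulation of one response-adaptive dose-finding trial.

A trial runs as a stream of events: women arrive (Poisson process at the
scenario's monthly enrolment rate), are screened over two menstrual cycles,
and if eligible are randomised with the allocation probabilities current at
that moment.  Outcomes complete three cycles plus a laboratory lag after
randomisation.  When the number randomised reaches a scheduled trigger, the
NDLM is refitted on the subjects whose follow-up has completed by that time
(later enrollees are still in follow-up and cannot contribute — the cost of
fast enrolment relative to follow-up), and the configured rule updates the
allocation probabilities for subsequent randomisations.  After the last of
``n_total`` randomisations a final fit on everyone decides success: the
trial succeeds when the posterior probability of a positive dose-vs-placebo
contrast exceeds the success threshold for at least one active dose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .adaptation import (
    AllocationProbs,
    ed95_precision_utility,
    play_the_winner,
    utilities_to_allocation,
)
from .ndlm import (
    DoseData,
    MCMCSettings,
    NDLMPriors,
    PosteriorFit,
    estimate_ed95,
    fit_ndlm,
    prob_efficacy,
)
from .scenarios import ScenarioSpec, Subject, draw_subject, follow_up, screen, true_effect

__all__ = ["DesignSpec", "TrialState", "TrialResult", "run_trial", "interim_dataset", "declare_success"]

logger = logging.getLogger(__name__)

RULES = ("play_the_winner", "ed95_precision", "none")


@dataclass(frozen=True)
class DesignSpec:
    """The trial design under evaluation.

    ``placebo_rate`` may be a float or a string like ``"2/J"`` which is
    resolved against the number of arms (J = actives + placebo).  The
    adaptation ``schedule`` lists randomisation counts that trigger interims;
    with ``rule="none"`` no interim fits are run (the schedule may still
    delimit phases for bookkeeping).

    Calendar parameters (days): ``screen_days`` from arrival to
    randomisation (two cycles), ``followup_days`` from randomisation to an
    analysable outcome (three treated cycles plus laboratory turnaround) and
    ``month_days`` converting the monthly enrolment rate to arrival times.
    """

    dose_grid: tuple[float, ...] = (0.4, 0.8, 1.0, 1.2, 1.5, 1.8)
    n_total: int = 100
    schedule: tuple[int, ...] = (16, 32, 50, 66, 84)
    placebo_rate: float | str = "2/J"
    rule: str = "ed95_precision"
    success_threshold: float = 0.975
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    priors: NDLMPriors = field(default_factory=NDLMPriors)
    utility_m: int = 100
    screen_days: float = 56.0
    followup_days: float = 91.0
    month_days: float = 28.0
    name: str = ""

    def __post_init__(self) -> None:
        grid = tuple(float(d) for d in self.dose_grid)
        object.__setattr__(self, "dose_grid", grid)
        if any(d <= 0 for d in grid) or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("dose_grid must be strictly increasing and positive")
        sched = tuple(int(k) for k in self.schedule)
        object.__setattr__(self, "schedule", sched)
        if any(b <= a for a, b in zip(sched, sched[1:])) or any(
            not 0 < k < self.n_total for k in sched
        ):
            raise ValueError("schedule must be strictly increasing within (0, n_total)")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}, got {self.rule!r}")
        if not 0 < self.success_threshold < 1:
            raise ValueError("success_threshold must be in (0, 1)")
        pr = self.resolved_placebo_rate()
        if not 0 < pr < 1:
            raise ValueError(f"placebo rate {pr} outside (0, 1)")

    @property
    def n_arms(self) -> int:
        return len(self.dose_grid) + 1

    def resolved_placebo_rate(self) -> float:
        """Placebo probability as a float (``"k/J"`` resolved against n_arms)."""
        if isinstance(self.placebo_rate, str):
            num, _, den = self.placebo_rate.partition("/")
            if den.strip() in ("J", "j"):
                return float(Fraction(int(num), self.n_arms))
            return float(Fraction(self.placebo_rate))
        return float(self.placebo_rate)

    @property
    def n_stages(self) -> int:
        return len(self.schedule) + 1


@dataclass
class TrialState:
    """Mutable in-trial bookkeeping (exposed mainly for interim inspection)."""

    clock: float
    subjects: list[Subject]
    probs: AllocationProbs
    stage: int
    stage_counts: np.ndarray  # (n_stages, n_arms)
    dose_grid: tuple[float, ...]


@dataclass
class TrialResult:
    """Outputs of one simulated trial."""

    success: bool
    p_efficacy: np.ndarray          # per active dose, final fit
    ed95_arm: int                   # 1-based active arm index
    ed95_mg: float
    stage_counts: np.ndarray        # (n_stages, n_arms)
    gamma_mean: np.ndarray          # posterior mean contrast per arm
    allocation_history: list[np.ndarray]
    interim_n_complete: list[int]   # outcome-complete subjects at each interim
    warnings: list[str]
    seed: object
    final_fit: PosteriorFit | None = None

    @property
    def arm_counts(self) -> np.ndarray:
        return self.stage_counts.sum(axis=0)


def interim_dataset(state: TrialState) -> DoseData:
    """Analysable data at an interim: subjects with follow-up complete by the clock.

    Baseline centring is recomputed on exactly this subset.
    """
    done = [
        s
        for s in state.subjects
        if s.t_outcome is not None and s.t_outcome <= state.clock
    ]
    return DoseData(
        y=np.array([s.Y for s in done], dtype=float),
        ybl=np.array([s.Ybl for s in done], dtype=float),
        arm=np.array([s.arm for s in done], dtype=np.int64),
        dose_grid=state.dose_grid,
    )


def declare_success(fit: PosteriorFit, threshold: float = 0.975) -> bool:
    """True iff some active dose has P(gamma_j > 0) strictly above the threshold."""
    probs = [prob_efficacy(fit, j) for j in range(1, fit.n_arms)]
    return max(probs) > threshold


def _adapt(
    design: DesignSpec,
    data: DoseData,
    fit: PosteriorFit,
    placebo_rate: float,
    util_rng: np.random.Generator,
    refit_seed: int,
) -> AllocationProbs:
    if design.rule == "play_the_winner":
        p = np.array([prob_efficacy(fit, j) for j in range(1, fit.n_arms)])
        return play_the_winner(p, placebo_rate)
    u = ed95_precision_utility(
        fit,
        data,
        m_predictions=design.utility_m,
        rng=util_rng,
        refit_priors=design.priors,
        refit_seed=refit_seed,
    )
    return utilities_to_allocation(u, placebo_rate)


def run_trial(
    design: DesignSpec,
    scenario: ScenarioSpec,
    seed: int | np.random.SeedSequence,
    keep_final_fit: bool = False,
) -> TrialResult:
    """Simulate one complete trial; deterministic given (design, scenario, seed).

    Randomness is split into independent streams for the cohort, the MCMC
    fits and the utility predictions, so the cohort realisation does not
    depend on which adaptation rule is being evaluated.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    cohort_ss, mcmc_ss, util_ss = ss.spawn(3)
    rng = np.random.default_rng(cohort_ss)
    util_rng = np.random.default_rng(util_ss)
    n_fits = len(design.schedule) + 1
    fit_seeds = mcmc_ss.spawn(2 * n_fits)  # second half reserved for fallback refits

    pop, curve = scenario.population, scenario.curve
    if tuple(curve.dose_grid) != tuple(design.dose_grid) and not scenario.is_null:
        raise ValueError("scenario curve and design use different dose grids")
    placebo_rate = design.resolved_placebo_rate()
    J = design.n_arms
    state = TrialState(
        clock=0.0,
        subjects=[],
        probs=AllocationProbs.equal_actives(J, placebo_rate),
        stage=0,
        stage_counts=np.zeros((design.n_stages, J)),
        dose_grid=design.dose_grid,
    )
    allocation_history = [state.probs.pi.copy()]
    interim_n_complete: list[int] = []
    warns: list[str] = []

    arrival_scale = design.month_days / scenario.enrol_rate_per_month
    t_arrive = 0.0
    n_rand = 0
    sid = 0
    while n_rand < design.n_total:
        t_arrive += rng.exponential(arrival_scale)
        subj = draw_subject(pop, rng, id=sid)
        subj.t_screen = t_arrive
        sid += 1
        if not screen(subj, pop.eligibility_threshold):
            continue
        t_rand = t_arrive + design.screen_days
        arm = int(rng.choice(J, p=state.probs.pi))
        subj.arm = arm
        subj.D = true_effect(curve, arm, subj.Ybl)
        follow_up(subj, pop, rng)
        subj.t_rand = t_rand
        subj.t_outcome = t_rand + design.followup_days
        state.subjects.append(subj)
        state.stage_counts[state.stage, arm] += 1
        n_rand += 1

        if state.stage < len(design.schedule) and n_rand == design.schedule[state.stage]:
            state.clock = t_rand
            if design.rule != "none":
                data = interim_dataset(state)
                interim_n_complete.append(len(data.y))
                if data.n_levels_observed() < 2:
                    msg = (
                        f"interim at n={n_rand}: {data.n_levels_observed()} dose "
                        "level(s) with outcomes; adaptation skipped"
                    )
                    logger.warning(msg)
                    warns.append(msg)
                else:
                    fit = fit_ndlm(
                        data,
                        priors=design.priors,
                        mcmc=design.mcmc,
                        seed=fit_seeds[state.stage],
                    )
                    refit_seed = int(
                        fit_seeds[n_fits + state.stage].generate_state(1, dtype=np.uint32)[0]
                    )
                    state.probs = _adapt(
                        design, data, fit, placebo_rate, util_rng, refit_seed
                    )
            allocation_history.append(state.probs.pi.copy())
            state.stage += 1

    # final analysis on all randomised subjects (all outcomes complete by then)
    state.clock = max(s.t_outcome for s in state.subjects)
    final_data = interim_dataset(state)
    final_fit = fit_ndlm(
        final_data,
        priors=design.priors,
        mcmc=design.mcmc,
        seed=fit_seeds[n_fits - 1],
    )
    p_eff = np.array([prob_efficacy(final_fit, j) for j in range(1, J)])
    ed95_arm = estimate_ed95(final_fit)
    return TrialResult(
        success=bool(p_eff.max() > design.success_threshold),
        p_efficacy=p_eff,
        ed95_arm=ed95_arm,
        ed95_mg=design.dose_grid[ed95_arm - 1],
        stage_counts=state.stage_counts,
        gamma_mean=final_fit.gamma_mean(),
        allocation_history=allocation_history,
        interim_n_complete=interim_n_complete,
        warnings=warns,
        seed=seed,
        final_fit=final_fit if keep_final_fit else None,
    )
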