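"""Bayesian dose-response estimation with a second-order Normal Dynamic Linear Model.

The treatment effect at arm ``l`` (placebo at ``l = 0``) is a latent level
``theta_l`` whose increments follow a local random walk with slope
``delta_l`` — a piecewise-linear, non-parametric dose-response fit in which
each arm's estimate borrows strength from its neighbours.  The analysed
response of subject ``i`` is modelled as

    y_i = theta_{l(i)} + beta * yblc_i + nu_i,      nu_i ~ N(0, sigma_nu^2)

with ``yblc`` the mean-centred baseline MBL, and the state evolution

    theta_l = theta_{l-1} + delta_{l-1} + omega_l
    delta_l = delta_{l-1} + eps_l,   omega_l, eps_l ~ N(0, W * sigma_nu^2).

Priors: diffuse N(0, 10000) on the pre-placebo state and on beta,
U(0.001, 100) on the variance-ratio W, and a half-normal N(0, 100) on the
observational noise (on the SD scale by default; see ``NDLMPriors``).

Inference is by a blocked Gibbs sampler (forward-filtering backward-sampling
for the states, conjugate beta, slice steps for the variances); draws of the
dose-vs-placebo contrasts ``gamma_l = theta_l - theta_0`` drive efficacy
probabilities, the ED95 and the adaptation utilities downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kernel import gibbs_ndlm

__all__ = [
    "NDLMPriors",
    "MCMCSettings",
    "DoseData",
    "PosteriorFit",
    "fit_ndlm",
    "prob_efficacy",
    "ed95_index",
    "estimate_ed95",
    "response_posterior_at",
    "split_rhat",
]


@dataclass(frozen=True)
class NDLMPriors:
    """Prior hyperparameters.

    ``obs_scale_prior`` is the variance parameter of the half-normal prior on
    the observational noise; with ``prior_on_sd=True`` (default) it is placed
    on the SD ``sigma_nu``, otherwise literally on the variance
    ``sigma_nu^2``.
    """

    var_theta0_delta0_beta: float = 10000.0
    w_bounds: tuple[float, float] = (0.001, 100.0)
    obs_scale_prior: float = 100.0
    prior_on_sd: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.w_bounds
        if not (0 < lo < hi):
            raise ValueError(f"invalid W bounds {self.w_bounds}")
        if self.var_theta0_delta0_beta <= 0 or self.obs_scale_prior <= 0:
            raise ValueError("prior variances must be > 0")


@dataclass(frozen=True)
class MCMCSettings:
    """Chain length: ``n_retained`` kept draws after ``n_burn`` burn-in.

    Defaults are sized for simulation studies; ``MCMCSettings.paper_fidelity()``
    gives the long 10,000/5,000 chains used for a single confirmatory fit.
    """

    n_retained: int = 2000
    n_burn: int = 1000

    def __post_init__(self) -> None:
        if self.n_retained < 1 or self.n_burn < 0:
            raise ValueError("need n_retained >= 1 and n_burn >= 0")

    @staticmethod
    def paper_fidelity() -> "MCMCSettings":
        return MCMCSettings(n_retained=10000, n_burn=5000)


@dataclass
class DoseData:
    """Per-subject analysed responses ready for the NDLM.

    ``arm`` holds 0-based arm indices (0 = placebo, ``l`` = l-th active dose
    of ``dose_grid``).  The baseline covariate is mean-centred on this
    dataset at construction.
    """

    y: np.ndarray
    ybl: np.ndarray
    arm: np.ndarray
    dose_grid: tuple[float, ...]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.ybl = np.asarray(self.ybl, dtype=float)
        self.arm = np.asarray(self.arm, dtype=np.int64)
        self.dose_grid = tuple(float(d) for d in self.dose_grid)
        if not (self.y.shape == self.ybl.shape == self.arm.shape):
            raise ValueError("y, ybl and arm must have identical shapes")
        if self.y.size and not (
            np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.ybl))
        ):
            raise ValueError("non-finite values in dose data")
        if self.y.size and (self.arm.min() < 0 or self.arm.max() > len(self.dose_grid)):
            raise ValueError("arm indices outside 0..J-1")

    @property
    def n_arms(self) -> int:
        return len(self.dose_grid) + 1

    @property
    def ybl_centred(self) -> np.ndarray:
        if self.y.size == 0:
            return self.ybl
        return self.ybl - self.ybl.mean()

    def n_levels_observed(self) -> int:
        return int(np.unique(self.arm).size)


@dataclass
class PosteriorFit:
    """Retained posterior draws and derived contrasts.

    ``gamma[:, l] = theta[:, l] - theta[:, 0]`` (identically 0 at placebo).
    """

    theta: np.ndarray       # (n_draws, J)
    delta: np.ndarray       # (n_draws, J)
    beta: np.ndarray        # (n_draws,)
    sigma2_nu: np.ndarray   # (n_draws,)
    W: np.ndarray           # (n_draws,)
    dose_grid: tuple[float, ...]
    rhat: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0]

    @property
    def n_arms(self) -> int:
        return self.theta.shape[1]

    @property
    def gamma(self) -> np.ndarray:
        return self.theta - self.theta[:, [0]]

    def gamma_mean(self) -> np.ndarray:
        return self.gamma.mean(axis=0)

    def diagnostics_report(self) -> dict:
        return {"n_draws": self.n_draws, "rhat": dict(self.rhat)}


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential-scale-reduction factor for a single chain.

    The chain is split in half and the usual between/within variance ratio
    computed; values near 1 indicate the two halves explore the same
    distribution.
    """
    x = np.asarray(draws, dtype=float)
    n = x.size // 2
    halves = np.stack([x[:n], x[n : 2 * n]])
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within <= 0:
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def fit_ndlm(
    data: DoseData,
    priors: NDLMPriors | None = None,
    mcmc: MCMCSettings | None = None,
    seed: int | np.random.SeedSequence = 0,
    fix_sigma_nu: float | None = None,
    fix_w: float | None = None,
    fix_beta: float | None = None,
) -> PosteriorFit:
    """Draw from the joint NDLM posterior.

    ``fix_sigma_nu`` / ``fix_w`` / ``fix_beta`` pin the respective parameter
    instead of sampling it — with all three fixed the remaining state block
    is exactly Gaussian, which the tests exploit against closed-form linear
    algebra.

    Raises ``ValueError`` if fewer than two dose levels carry observations
    (the evolution structure is then unidentifiable).
    """
    priors = priors or NDLMPriors()
    mcmc = mcmc or MCMCSettings()
    if data.n_levels_observed() < 2:
        raise ValueError(
            "NDLM needs observations at >= 2 distinct dose levels "
            f"(got {data.n_levels_observed()})"
        )
    J = data.n_arms
    x = data.ybl_centred
    arm = data.arm
    n_arm = np.bincount(arm, minlength=J).astype(np.float64)
    sum_y = np.bincount(arm, weights=data.y, minlength=J)
    sum_x = np.bincount(arm, weights=x, minlength=J)
    sum_y2 = np.bincount(arm, weights=data.y**2, minlength=J)
    sum_x2 = np.bincount(arm, weights=x**2, minlength=J)
    sum_xy = np.bincount(arm, weights=x * data.y, minlength=J)

    if isinstance(seed, np.random.SeedSequence):
        kernel_seed = int(seed.generate_state(1, dtype=np.uint32)[0])
    else:
        kernel_seed = int(seed) % (2**32)

    theta, delta, beta, sig2, w = gibbs_ndlm(
        n_arm,
        sum_y,
        sum_x,
        sum_y2,
        sum_x2,
        sum_xy,
        mcmc.n_retained,
        mcmc.n_burn,
        priors.var_theta0_delta0_beta,
        priors.w_bounds[0],
        priors.w_bounds[1],
        float(np.sqrt(priors.obs_scale_prior)),
        priors.prior_on_sd,
        -1.0 if fix_sigma_nu is None else float(fix_sigma_nu),
        -1.0 if fix_w is None else float(fix_w),
        fix_beta is not None,
        0.0 if fix_beta is None else float(fix_beta),
        kernel_seed,
    )
    rhat = {f"theta_{l}": split_rhat(theta[:, l]) for l in range(J)}
    rhat["beta"] = split_rhat(beta)
    return PosteriorFit(
        theta=theta,
        delta=delta,
        beta=beta,
        sigma2_nu=sig2,
        W=w,
        dose_grid=data.dose_grid,
        rhat=rhat,
    )


def prob_efficacy(fit: PosteriorFit, j: int) -> float:
    """Posterior probability that active arm ``j`` beats placebo, P(gamma_j > 0).

    Strict inequality: draws exactly at 0 do not count.
    """
    if not 1 <= j < fit.n_arms:
        raise ValueError(f"j must index an active arm (1..{fit.n_arms - 1}), got {j}")
    return float(np.mean(fit.gamma[:, j] > 0))


def ed95_index(effects: Sequence[float]) -> int:
    """ED95 from per-active-dose effects: smallest dose reaching 95% of the max.

    ``effects`` has one entry per active dose (placebo excluded); returns a
    0-based index into the dose grid.  If no effect is positive the curve has
    no meaningful ED95 and the max-effect dose is returned (ties to the
    smallest dose) so adaptation stays defined under the null.
    """
    eff = np.asarray(effects, dtype=float)
    if eff.size == 0:
        raise ValueError("need at least one active dose")
    best = eff.max()
    if best <= 0:
        return int(np.argmax(eff))
    return int(np.argmax(eff >= 0.95 * best))


def estimate_ed95(fit: PosteriorFit, per_draw: bool = False):
    """ED95 arm index (1-based, i.e. into ``theta``'s columns) from a fit.

    Default applies the ED95 rule to the posterior-mean contrast curve (the
    stable choice for allocation); ``per_draw=True`` instead returns the
    array of per-draw ED95 arm indices.
    """
    if per_draw:
        g = fit.gamma[:, 1:]
        best = g.max(axis=1)
        thresh = np.where(best > 0, 0.95 * best, np.inf)
        hit = g >= thresh[:, None]
        idx = np.where(hit.any(axis=1), hit.argmax(axis=1), g.argmax(axis=1))
        return idx + 1
    return ed95_index(fit.gamma_mean()[1:]) + 1


def response_posterior_at(fit: PosteriorFit, j: int):
    """Posterior (mean, variance, draws) of the contrast at arm ``j``.

    Placebo returns (0, 0, zeros) since ``gamma_0`` is identically zero.
    """
    if not 0 <= j < fit.n_arms:
        raise ValueError(f"arm index {j} outside 0..{fit.n_arms - 1}")
    draws = fit.gamma[:, j]
    return float(draws.mean()), float(draws.var()), draws
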