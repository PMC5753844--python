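import numpy as np
import pytest

from doseadapt import (
    DoseData,
    DoseResponseCurve,
    MCMCSettings,
    PopulationModel,
    fit_ndlm,
    simulate_cohort,
)

TINY_MCMC = MCMCSettings(n_retained=300, n_burn=150)
SHORT_MCMC = MCMCSettings(n_retained=1000, n_burn=500)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


def make_dose_data(
    n_per_arm: int,
    theta: np.ndarray,
    beta: float = 0.0,
    sigma: float = 17.9,
    dose_grid=(0.4, 0.8, 1.2),
    seed: int = 0,
) -> DoseData:
    """Data simulated straight from the NDLM observation equation."""
    g = np.random.default_rng(seed)
    J = len(dose_grid) + 1
    arm = np.repeat(np.arange(J), n_per_arm)
    ybl = g.normal(80.0, 20.0, size=arm.size)
    y = theta[arm] + beta * (ybl - ybl.mean()) + g.normal(0, sigma, size=arm.size)
    return DoseData(y=y, ybl=ybl, arm=arm, dose_grid=dose_grid)


@pytest.fixture(scope="session")
def small_fit():
    """A short but well-mixed fit on observation-equation data (4 arms)."""
    data = make_dose_data(
        12, theta=np.array([0.0, 5.0, 10.0, 12.0]), beta=0.4, seed=3
    )
    return fit_ndlm(data, mcmc=SHORT_MCMC, seed=11), data


@pytest.fixture(scope="session")
def eligible_cohort(rng):
    """1000 eligible completers on placebo under the base population model."""
    pop = PopulationModel()
    curve = DoseResponseCurve("flat")
    return simulate_cohort(1000, pop, curve, np.zeros(1000, dtype=int), rng)
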