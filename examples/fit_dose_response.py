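"""Fit the NDLM dose-response model to one simulated cohort.

Builds 100 virtual participants under a non-monotone true curve (best dose
between 1.0 and 1.2 mg, 16.4 mL reduction at the best dose), fits the
second-order Normal Dynamic Linear Model, and prints per-dose contrasts
versus placebo, efficacy probabilities and the ED95.
"""

import numpy as np

from doseadapt import (
    DoseData,
    DoseResponseCurve,
    PopulationModel,
    estimate_ed95,
    fit_ndlm,
    prob_efficacy,
    simulate_cohort,
)

rng = np.random.default_rng(2026)
pop = PopulationModel(sigma_e=17.9)
curve = DoseResponseCurve("non_monotone", effect_at_best=16.4)

# equal allocation: placebo (arm 0) and six active doses
arms = rng.integers(0, 7, size=100)
cohort = simulate_cohort(100, pop, curve, arms, rng)
data = DoseData(
    y=[s.Y for s in cohort],
    ybl=[s.Ybl for s in cohort],
    arm=[s.arm for s in cohort],
    dose_grid=curve.dose_grid,
)

fit = fit_ndlm(data, seed=1)
true_eff = curve.effects()

print("dose (mg)  n   true effect  post. mean gamma  P(gamma>0)")
for j in range(1, 7):
    n_j = int(np.sum(data.arm == j))
    print(
        f"{curve.dose_grid[j-1]:8.1f} {n_j:3d} {true_eff[j-1]:12.1f} "
        f"{fit.gamma_mean()[j]:17.1f} {prob_efficacy(fit, j):11.3f}"
    )
ed95 = estimate_ed95(fit)
print(f"\nED95 estimate: {curve.dose_grid[ed95-1]} mg (arm {ed95})")
print(f"posterior sigma_nu: {np.sqrt(fit.sigma2_nu.mean()):.1f} mL (truth ~17.9)")
print("\nThe contrasts gamma_j are the modelled MBL reductions versus placebo;")
print("each dose's estimate borrows strength from its neighbours through the")
print("random-walk prior, so sparsely populated arms stay well-behaved.")
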