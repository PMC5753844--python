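"""Why measure two menstrual cycles at baseline and follow-up?

Monte-Carlo demonstration that averaging two cycles at each end roughly
halves the conditional variance of the analysed response Var(Y | Ybl)
compared with a single cycle at each end - the justification for keeping
four measured cycles per participant.
"""

import numpy as np

from doseadapt import DoseResponseCurve, PopulationModel, simulate_cohort

n = 50_000
rng = np.random.default_rng(11)
pop = PopulationModel(sigma_e=17.9)
cohort = simulate_cohort(n, pop, DoseResponseCurve("flat"), np.zeros(n, int), rng)


def resid_var(x, y):
    slope = np.cov(x, y)[0, 1] / np.var(x)
    return np.var(y - slope * x)


two = resid_var(
    np.array([s.Ybl for s in cohort]), np.array([s.Y for s in cohort])
)
one = resid_var(
    np.array([s.Y1 for s in cohort]), np.array([s.Y1 - s.Y3 for s in cohort])
)
print(f"Var(Y|Ybl), single cycle at each end: {one:7.1f} mL^2")
print(f"Var(Y|Ybl), two-cycle averages:       {two:7.1f} mL^2")
print(f"reduction: {100*(1-two/one):.1f}%")
print("\nEach extra averaged cycle halves the measurement-noise contribution")
print("(sigma_e^2 vs 2*sigma_e^2 after baseline adjustment), which feeds")
print("directly into the power of every design built on this outcome.")
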