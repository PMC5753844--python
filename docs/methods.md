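# Methods

This note documents the statistical model, the synthetic-cohort generator,
the adaptation machinery and the numerical choices behind `doseadapt`, in
enough detail to judge what a passing simulation does and does not show.

## The virtual cohort

A participant's menstrual blood loss (MBL) is modelled in two stages: a
latent subject mean `S ~ LogNormal(meanlog, sdlog)` and, for every measured
cycle, an independent deviation `E ~ N(0, σ_e²)`, so repeated measurements
share `S` (compound symmetry, intraclass correlation
`Var(S)/(Var(S)+σ_e²)`).  Screening records two cycles; eligibility requires
their average to be at least 50 mL.  Because selection acts on `S + noise`,
eligible participants have positively biased screening noise and their
follow-up regresses toward `S`: regression to the mean is a *consequence* of
the generator, not an added mechanism, and the analysis model absorbs it
through the baseline regression term.  For the same reason the unconditional
mean response of screened subjects is positive (≈ +5 mL under defaults) even
with no treatment effect; "no effect leakage" is the statement
`E[Yfu − S] = 0`, which the tests check.

Treatment reduces the latent mean at follow-up by `D_j`, determined by a
dose-response curve shape, its best-dose magnitude, and optionally a
baseline-proportional mode in which the best dose removes 10% or 20% of the
subject's own baseline.  The analysed response is the reduction
`Y = Ybl − Yfu` of two-cycle averages, so `Var(Y | Ybl) ≈ σ_e²`; with single
cycles at each end it would be `≈ 2σ_e²` — the twin-measurement design
halves the modelled noise, which the acceptance run verifies by Monte Carlo.

**Parameters and defaults.** `meanlog = log 40`, `sdlog = 0.6` (population
median 40 mL with a heavy right tail — a calibration to the qualitative
description of population MBL, not a fitted value); `σ_e = 17.9` mL (within-
subject SD, with 22 and 26 as stress scenarios); eligibility threshold
50 mL.  Heteroscedastic scenarios use `σ_e,i = σ_e (Ybl_i/50)^κ`, `κ = 0.5`,
at follow-up only: the functional form is a re-parameterisation chosen for
its single qualitative property — variability grows with baseline MBL — and
is deliberately *not* modelled in the analysis, so those scenarios probe
robustness to misspecification.  The curve shapes are parametric stand-ins:
linear in dose; linear rise saturating at 1.2 mg; a log-dose quadratic
peaking at 1.1 mg (between the 1.0 and 1.2 mg grid points); flat ≡ 0.  The
"large" best-dose effect is 16.4 mL and the "small" one half that.

**What the generator does not emulate.** Cycle-length variability, dropout
(completers are simulated directly), measurement floor/ceiling effects,
non-normal within-subject error, and time trends in recruitment.  Passing
operating characteristics therefore speak to the design logic under this
stylised population, not to robustness against those features.

## The dose-response model

Second-order Normal Dynamic Linear Model over arm index (placebo first):
level `θ_j` and local slope `δ_j` evolve as a random walk with innovation
variance `W σ_ν²` shared between level and slope; the observation equation
regresses the response on the arm level plus mean-centred baseline.  The
model yields piecewise-linear, non-monotone-capable fits where sparsely
populated arms borrow strength from neighbours.  Evolution steps are per arm
*index*, not per mg of dose spacing — the natural reading of a model indexed
by level.

Priors: `N(0, 10⁴)` on the pre-placebo state and on β; `U(0.001, 100)` on W;
half-normal `N(0, 100)` on the observational noise.  The half-normal is
placed on the **SD** `σ_ν` by default (`prior_on_sd=True`): placing it
literally on the variance concentrates `σ_ν` below ~10 mL a priori, and in
simulation that forces the posterior noise down to ≈10 mL and the null
success rate to ≈28% — behaviour incompatible with any sensible operating
characteristic, so the SD placement is treated as the intended
specification.  The switch is kept for sensitivity analyses.

**Sampler.** Blocked Gibbs: the full state vector is drawn jointly by
forward-filtering backward-sampling (exact, verified against closed-form
Gaussian posteriors with fixed variances); β has a conjugate Gaussian
conditional; `σ_ν` and `W` are drawn by univariate slice sampling on the log
scale, W within its bounds.  Per-iteration cost is O(J) after reducing the
data to per-arm sufficient statistics, and the kernel is numba-compiled, so
chain length drives runtime.  Defaults for simulation studies are 2,000
retained draws after 1,000 burn-in; `MCMCSettings.paper_fidelity()` gives
10,000/5,000 for confirmatory single fits.  A split-chain R̂ per parameter
is attached to every fit; on well-conditioned data it sits below 1.1.

**Derived quantities.** Contrasts `γ_j = θ_j − θ_0`; efficacy probability
P(γ_j > 0) as the Monte-Carlo fraction of positive draws (strict
inequality); ED95 as the smallest dose reaching 95% of the maximal effect,
computed on the posterior-mean contrast curve for allocation (stable), with
the per-draw ED95 distribution exposed as well.  When no effect is positive
the ED95 is undefined; the argmax dose (ties to the smallest) keeps
adaptation well-defined under the null.

## Adaptation

Play-the-winner allocates the non-placebo mass in proportion to P(γ_j > 0).
The ED95-precision rule allocates it in proportion to the predicted gain in
precision (reciprocal variance) of `γ` at the current ED95 from one further
randomisation at each dose.  The one-step-ahead update is approximated by
importance sampling: M (default 100) hypothetical responses are drawn from
the posterior predictive at the candidate dose (future baseline covariate at
its centred mean, 0), the retained draws are reweighted by the likelihood of
each hypothetical observation, and the reweighted variances are averaged
before inverting.  Precision gains are clamped at zero and an all-zero
utility vector falls back to equal active allocation, so the output is
always a valid probability vector with the placebo entry pinned — under the
null this fallback is routine, not exceptional.

When the weights collapse (effective sample size below 5% of the draws for
more than half the M predictions — common at early interims where the
posterior is diffuse), the dose's predicted variance is recomputed by a
short augmented-data refit.  The importance-sampling answer is validated in
the tests against brute-force nested refits on a small instance.  Note one
structural fact checked there: utilities are *not* exchangeable across dose
labels even for identical data at every dose — the random walk ties a
dose's informational value to its distance from the current ED95, and the
gain peaks at the ED95 itself.

## The trial engine

Calendar time in days: Poisson arrivals at the scenario's monthly enrolment
rate (month = 28 days, matching the fixed 28-day cycle), screening occupies
two cycles (56 days), and the outcome completes three treated cycles plus a
7-day laboratory lag (91 days) after randomisation; all durations are
configurable, and only the enrolment *rates* (2 or 4 per month) are
empirically anchored.  Interims trigger on the count randomised; the fit
uses exactly the subjects whose follow-up has completed by that moment, so
fast enrolment relative to follow-up genuinely erodes the value of
adaptation (at an infinite rate every interim is empty and adaptation is
skipped with a warning).  Interim computation itself is treated as
instantaneous, its real-world delay folded into the laboratory lag.
Screening failures are generated and discarded; enrolment continues until
`n_total` randomisations.  Success: P(γ_j > 0) strictly above 0.975 for at
least one active dose at the final fit on all subjects.

Randomness is split into independent streams (cohort, MCMC fits, utility
predictions) from one seed, so a trial is bit-reproducible and the cohort
realisation is invariant to the rule being evaluated.

## Operating characteristics

Grids of (design, scenario) cells run replicated trials with seeds bound to
(base seed, cell index, replicate index) — results are independent of
execution order and parallelism.  Family-wise type I error pools success
proportions over flat-curve cells; disjunctive power pools over
effect-bearing cells; both with Wilson 95% intervals.  Factor effects on
power are estimated by least squares on cell proportions (weighted by
replicates by default; an unweighted option exists), with reference levels
at zero by construction and rank-deficiency in fractional grids reported as
aliasing.  A linear probability model is used deliberately — it matches the
normal-linear-model analysis convention for simulation outputs — rather
than logistic regression.

**Problem sizes.** The shipped acceptance run uses desk-scale grids chosen
as the package's own defaults: 8 null cells × 200 replicates for type I
error (spanning both rules, both placebo rates, several schedules, and
homo-/heteroscedastic noise at the three σ_e levels, since the pooled null
rate is a scenario-average quantity and heteroscedastic misspecification
measurably inflates it); 6 effect cells × 100 replicates for each power
estimate (three effect-bearing shapes balanced against
heteroscedasticity and baseline-proportional effects at a 16.4 mL best-dose
effect, σ_e = 17.9, 4 enrolled/month); 100,000 subjects for the variance
Monte Carlo.  Chains are 2,000/1,000 throughout the grids.  At these sizes
the binomial standard error of a pooled power estimate is ≈1%, and of the
pooled type I error ≈0.5%.

The non-adaptive comparator is the *conventional* design: equal fixed
allocation across all seven arms (placebo probability 1/J) with no interims
— the design one would run absent any adaptive machinery.  Giving the
comparator the 2/J placebo share instead would credit it with the single
biggest power-bearing design choice and erase most of the adaptive gain.

## Known limitations

* The NDLM is fit with homoscedastic Gaussian errors even under
  heteroscedastic truth — by design, to measure robustness, but it means
  σ_ν² is then an average noise level, not a parameter of the truth.
* The importance-sampling utility reuses the interim chain; at very small
  interim datasets its refit fallback carries extra Monte-Carlo noise.
* Type I and power estimates inherit the graininess of the success
  criterion: with 2,000 retained draws, P(γ_j > 0) moves in steps of
  1/2000, and trials sitting near the 0.975 threshold can flip with chain
  seed.
* The factor-effect model treats cell proportions as approximately normal;
  with few replicates per cell its CIs are indicative only.
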