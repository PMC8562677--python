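# utilitr

Estimation of composite-outcome utility functions — and of the optimal
individualized treatment rule they imply — from observational data, treating
clinician decisions as noisy signals of patient utility.

## The problem

Many clinical decisions trade off two competing outcomes: in bipolar
disorder, for instance, antidepressants may relieve depression (outcome *Y*)
while raising the risk of mania (outcome *Z*). Standard individualized
treatment rule (ITR) methods optimize one scalar outcome; here the scalar of
interest is an unknown patient utility

u(y, z; x) = ω(x)·y + (1 − ω(x))·z,  ω(x) ∈ [0, 1],

either a shared weight ω or a patient-specific ω(x; θ) = expit(xᵀθ). Rather
than eliciting ω from patients, the package assumes clinicians *approximately*
act in each patient's best interest:

Pr{A = d_opt(X) | X = x} = expit(xᵀβ),

where d_opt(x) = sign{ω(x)·R_Y(x) + (1 − ω(x))·R_Z(x)} is the utility-optimal
rule and R_Y, R_Z are the treatment contrasts Q(x, 1) − Q(x, −1) of linear
outcome regressions (Q-learning with treatment interactions). Observed
treatment choices then carry information about (ω, β), recovered by maximum
**pseudo-likelihood**: plug the estimated rule d̂ into the assignment
likelihood and maximize

ℓ̂ₙ(ω, β) = Σᵢ [ 1{Aᵢ = d̂_ω(Xᵢ)} · XᵢᵀB − log(1 + exp(XᵢᵀB)) ]

profiling β by logistic regression at each candidate utility parameter. The
fixed-ω model is maximized over a grid (the criterion is a step function of
ω); the patient-specific model by a Metropolis random-walk search over θ. A
parametric bootstrap (block square root of the stacked influence-vector
covariance, a kernel-localized boundary map, and an inner argmin) approximates
the sampling law of √n(θ̂ − θ₀, β̂ − β₀) and yields a test for **preference
heterogeneity** H₀: ‖θ₍₁₎‖ = 0 (all patients share one weight).

The package is for biostatisticians and methods researchers working on
precision medicine with observational cohorts: it provides the estimators,
the bootstrap inference, policy-value evaluation (plug-in simulation value
and cross-validated inverse-probability-weighted value), synthetic cohort
generators with known ground truth, and a Monte-Carlo harness.

## Worked example

```python
import numpy as np
from utilitr import CompositeUtilityModel, GenerativeConfig, simulate

# a cohort where the true weight is 0.25 and clinicians pick the optimal
# treatment for 60% of patients
cohort = simulate(GenerativeConfig(n=500, utility=0.25, behavior=0.6, seed=7))

res = CompositeUtilityModel(cohort, utility="fixed").fit()
print(res.summary())
```

```
Composite-outcome utility model (fixed weight)
======================================================
No. observations:        500
Behavior model:          constant
omega grid:              101 points in [0, 1]
------------------------------------------------------
omega_hat                    0.3300
rho_hat                      0.6180
beta_const                   0.4811
------------------------------------------------------
log pseudo-likelihood      -332.517
optimal fraction             0.6180
coin-toss diagnostic         1.0000
separation flag               False
```

`omega_hat` is the estimated utility weight (truth 0.25; across Monte-Carlo
replications the mean is ≈ 0.25 with SD ≈ 0.08 at this sample size),
`rho_hat` the estimated probability that standard care assigns the optimal
treatment (truth 0.60), and the optimal fraction the in-sample concordance
between observed treatments and the fitted rule. `res.treatment_rule()`
returns the fitted rule; `res.plot_profile()` shows the profiled
pseudo-likelihood over the ω grid.

For patient-specific utilities:

```python
cohort = simulate(GenerativeConfig(
    n=500, utility=(1.0, -0.5, 0, 0, 0, 0),      # omega(x) = expit(1 - 0.5 x1)
    behavior=(0.5, 1.0, 0, 0, 0, 0), seed=7))
res = CompositeUtilityModel(cohort, utility="varying").fit(
    chain_length=10_000, seed=1)
test = res.heterogeneity_test(n_boot=1000, seed=2)
print(f"sqrt(n)||theta_(1)|| = {test.statistic:.2f}, p = {test.p_value:.3f}")
```

A small p-value indicates that patient preferences genuinely vary with
covariates. A command-line interface mirrors the library:
`utilitr simulate|fit|bootstrap-test|evaluate|reproduce-tables --help`.

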