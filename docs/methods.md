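# Methods

## Model

Data are n i.i.d. records (X, A, Y, Z): covariates X ∈ ℝᵖ, a binary
treatment A ∈ {−1, +1}, and two outcomes Y, Z for which larger values are
better. Patient utility is a convex combination

u(y, z; x) = w(x)·y + (1 − w(x))·z,

with w either a shared constant ω ∈ [0, 1] or the logistic form
w(x; θ) = expit((1, x)ᵀθ). Under standard causal assumptions (consistency,
positivity, ignorability) the outcome regressions
Q_O(x, a) = E[O | X = x, A = a] identify the contrasts
R_O(x) = Q_O(x, 1) − Q_O(x, −1), and the utility-optimal rule is

d_opt(x) = sign{ D(x) },  D(x) = w(x)·R_Y(x) + (1 − w(x))·R_Z(x),

with the convention sign(0) = +1 (ties are measure-zero under continuous
covariates but must be fixed for determinism). The behavioral premise is
that clinicians approximately follow d_opt:

Pr{A = d_opt(X) | X = x} = expit((1, x)ᵀβ).

Replacing d_opt by its plug-in estimate d̂ (from OLS Q-fits on the saturated
design (1, X, A, A·X)) turns the assignment likelihood into a
pseudo-likelihood for the utility parameter and β. Identifiability requires
more than the likelihood itself supplies; a sufficient condition is that
clinical decisions beat a coin toss, Pr{A = d_opt(X) | X} > 1/2 a.s., and
every fit reports the fraction of subjects whose fitted probability exceeds
1/2 as a diagnostic.

## Estimation

**Q-functions.** Each outcome is regressed by OLS on (1, X, A, A·X)
(statsmodels). The model family is fixed to linear-in-X with full treatment
interactions because the influence expansion used by the bootstrap is exact
for (generalized) linear models; a `features` hook restricts the term list.
Rank-deficient designs raise an error naming the offending columns.

**Fixed weight (grid profile).** The log pseudo-likelihood is a step
function of ω — it changes only when some subject's estimated optimal
treatment flips — so ω̂ is the argmax over a grid (default 101 equispaced
points, step 0.01; the grid resolution is our choice), profiling β at each
point by logistic regression of the optimality indicators 1{Aᵢ = d̂_ω(Xᵢ)}
on (1, X) (or on an intercept alone when the behavior model is constant).
Ties are broken toward the smallest ω, deterministically. Q-fits are done
once on the full sample and reused across the grid. The reported ρ̂ is
expit(β̂₀) for an intercept-only behavior design and the sample mean of
expit((1, x)ᵀβ̂) otherwise.

The inner logistic maximization is a hand-written Newton/IRLS solver with
backtracking: the grid, Metropolis and bootstrap loops perform on the order
of 10⁵ logistic fits per experiment, where per-call overhead of a full
GLM stack dominates. The solver is validated against statsmodels Logit to
10⁻⁷ in the test suite. Complete separation or all-constant indicators
(which occur by construction when the fitted rule matches every observed
treatment) trigger a ridge-stabilized refit with penalty 10⁻⁴·n·‖β‖² and a
separation flag; the reported log pseudo-likelihood is the unpenalized
value at the stabilized β̂.

**Patient-specific weight (Metropolis profile search).** For w(x; θ) the
profiled criterion L̃ₙ(θ) = max_β ℓ̂ₙ(θ, β) is a step function on ℝᵖ⁺¹ and a
grid is infeasible, so the maximizer is sought by a symmetric Gaussian
random walk: propose θ* = θᵇ + N(0, σ²I), accept with probability
min{1, exp(L̃ₙ(θ*) − L̃ₙ(θᵇ))}, and return the visited state with the
largest profiled value (the chain is a search device, not a posterior
sampler; no burn-in is discarded, and the starting point θ = 0 — w ≡ 1/2 —
counts as visited). L̃ₙ values are memoized by θ's byte representation
because rejections re-use the current state. Default chain length 10,000.

σ is chosen by pilot runs over a ladder of scales 4, 2, …, 2⁻⁶, keeping the
*smallest* scale whose acceptance proportion lands in [0.25, 0.5]. The
band-only tuning rule is not well-posed here: acceptance is non-monotone in
σ because far from the origin the weights saturate (w(x; θ) ∈ {0, 1} for
essentially all subjects) and L̃ₙ becomes flat, so arbitrarily large
proposals are accepted at in-band rates. Preferring the most local in-band
scale avoids tuning onto those ridges.

**Compact search region (important).** The identifiability theory for this
model assumes θ ranges over a compact set, and our implementation shows the
assumption is load-bearing rather than technical: on the synthetic designs
at n = 500 the *unconstrained* empirical maximizer does not sit near the
truth. Along directions that saturate the weights, the rule family becomes
a flexible piecewise classifier that can re-classify near-boundary subjects
into indicator patterns that are simultaneously more concordant and more
predictable from x, gaining several nats of pseudo-likelihood that pure
chance supplies at this sample size; an unconstrained chain therefore
drifts outward without bound (‖θ̂‖ of order σ√B). The default search is
accordingly confined to the ball ‖θ − θ_init‖ ≤ 3 / E‖(1, x)‖ — the radius
beyond which the logistic weight saturates for a typical subject, i.e. the
scale past which θ is empirically unidentifiable — with `radius=None`
restoring the unconstrained walk. The instability is confined to the
θ-parameterization: the fitted *decision rules* from constrained and
unconstrained searches are nearly identical (see Limitations).

**Parametric bootstrap.** The sampling law of √n(θ̂ − θ₀, β̂ − β₀) is
non-Gaussian and driven by subjects near the decision boundary D(X) = 0.
One bootstrap draw: (i) stack the per-subject influence vectors — the OLS
influence of each subject on the two interaction-coefficient blocks
(ψ_Y, ψ_Z, with basis φ(x) = 2(1, x)) and the behavior score
ψ_A = [1{A = d̂(X)} − P_β̂(X)]·(1, X) — and form Σ̂, their empirical
second-moment matrix; (ii) draw Z* ~ N(0, I) and map it through the
lower-block-triangular root of Σ̂ (top-left block: symmetric PSD root of
Σ̂₁; lower-left: Σ̂₂₁ᵀΣ̂₁^{−1/2}; lower-right: symmetric root of the Schur
complement; eigenvalues below 10⁻¹⁰ of the largest are clipped at zero and
pseudo-inverted); (iii) form the kernel-localized boundary average
k̃(Z_Y, Z_Z, u) — a ratio of sample means with Gaussian kernel weights
h⁻¹φ₀(D̂/h), bandwidth h = v̂·n^{−1/5} where v̂ is the sample SD of D̂(Xᵢ)
(an error is raised if v̂ = 0 or the kernel mass falls below 10⁻¹²);
(iv) solve Ũ = argmin_u β̂ᵀk̃(Z̃_Y, Z̃_Z, u) by Nelder–Mead from five starts
(origin ± scaled first two coordinate directions; tolerance 10⁻⁶, at most
2000 evaluations per start — the objective is piecewise smooth), and set
B̃ = Iₙ(β̂)^{−1}{Z̃_A − k̃(Ũ)}. Non-convergent draws are flagged and
excluded; more than 5% of them aborts inference.

**Heterogeneity test.** The statistic is T = √n‖θ̂₍₁₎‖ (θ̂ without its
intercept); the p-value is the fraction of bootstrap draws with
‖Ũ₍₁₎‖ ≥ T, rejecting at p ≤ α. The norm-quantile construction is our
choice (the conversion of the bootstrap into a test is otherwise open);
bootstrap standard errors of θ̂ components, sd(Ũ)/√n, are exposed.

## Policy evaluation

On synthetic designs the value of a rule is estimated by simulating a fresh
testing sample (default 500 subjects), assigning treatment by the rule, and
averaging the *true* composite outcome; the standard-of-care value averages
the composite outcome under the generative assignment mechanism; the error
rate is the disagreement of a rule with the true optimal rule on a fresh
covariate sample of 500. On observed cohorts the value is the K-fold
cross-validated inverse-probability-weighted estimate: per fold, rule and
propensity (logistic regression of A on (1, X)) are fit on the training
part and the held-out subjects concordant with the rule contribute with
weight 1/π̂, Hajek-normalized by default (a variance-reducing standard
choice; the unnormalized form is a flag). Propensities are truncated to
[0.01, 0.99] with a count of truncations; folds with no concordant subject
are dropped with a warning.

## Synthetic designs

The generator mirrors the simulation study the estimators target:
X ~ N(0, 0.5²)ᵖ i.i.d. (p = 5 by default, only X₁, X₂ enter the outcomes —
the rest are genuine noise), Y = A(4X₁ − 2X₂ + 2) + ε and
Z = A(2X₁ − 4X₂ − 2) + ε with ε ~ N(0, 0.5²); treatment equals the
utility-optimal choice with probability ρ (constant design),
expit(0.5 + X₁) (covariate-propensity design, β = (0.5, 1, 0, …)), with
true weight ω ∈ {0.25, 0.75} or w(x) = expit(1 − 0.5X₁)
(θ = (1, −0.5, 0, …)); the bootstrap test design uses bivariate X with the
same outcome models, β = (2.5, 1, 0), and null θ = (1, 0, 0). The
bivariate design is assumed to share the univariate designs' noise SDs (the
source of these designs leaves that detail open). One RNG stream per cohort
with a documented draw order (X, assignment noise, ε_Y, ε_Z) makes seeds
portable across simulators and keeps policy-evaluation draws aligned.

What the generator does *not* emulate: confounding beyond the modeled
assignment mechanism, misspecified utility or outcome models, correlated
or non-Gaussian covariates, missing data, more than two outcomes, or
longitudinal treatment. Passing tests therefore certify the estimators
under a correctly specified, well-behaved data-generating process — not
robustness on real cohorts.

## Scales used in tests

Monte-Carlo checks in the test suite run at desk scale as the package's own
choice of problem size: 100 replications for the grid-search and value
summaries (against published means within 3·SD/√reps + 3·SD/√500), and 50
replications with 2,000-step chains and 200 bootstrap draws for the
patient-specific and bootstrap operating characteristics. The acceptance
script uses 100 replications per quantity.

## Known limitations

- **θ-scale instability of the patient-specific search.** As described
  above, the unconstrained profile search drifts along saturation ridges.
  With the default compact search region the estimator is stable but its
  θ-RMSE on the n = 500 synthetic design is ≈ 1.5 — substantially larger
  than the ≈ 0.6 reported for the original implementation of this
  procedure, whose exact search settings are not documented. The same fits
  reproduce the published β̂ accuracy (RMSE ≈ 0.5), decision-rule error
  rate (≈ 0.06) and policy value (≈ 1.67 vs 1.71), so the discrepancy is
  confined to the θ-parameterization, to which the induced rule is nearly
  invariant (saturated and unsaturated θ along the same direction imply
  almost the same sign rule).
- **Heterogeneity-test calibration inherits that instability.** The
  bootstrap approximates the sampling law of the idealized maximizer; the
  search error in θ̂₍₁₎ inflates the statistic under the null, and the
  measured type-I error at α = 0.05 on the bivariate design is ≈ 0.1–0.15
  rather than conservative. p-values near the threshold should be read
  with that in mind; strong heterogeneity (the power settings) is detected
  reliably.
- The bootstrap's B̃ draws are heavy-tailed (the inner argmin occasionally
  lands far out); quantile summaries are preferable to moments for small
  draw counts.
- Only two outcomes, one decision point, binary treatment; nonparametric
  Q-models and doubly-robust value estimators are out of scope.
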