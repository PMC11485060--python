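# Methods

## Model

All procedures work on the combined-level logistic model

    logit P(Y=1 | cell j, z) = θ0 + θ_j + zᵀγ,        θ_(neither) ≡ 0,

where the four cells are the joint levels of two binary exposures
(neither, A-only, B-only, both) and z is an optional vector of
confounders entering linearly. This parameterization is equivalent to the
familiar one with a product term (β1 = θ1, β2 = θ2, β3 = θ3 − θ1 − θ2);
it is preferred because the additive-null constraint involves only
(θ1, θ2, θ3). Log-likelihoods are always per-subject Bernoulli, so the
global deviance GDEV = −2ℓ(θ̂) is comparable across every fit in the
package, including fits scored on held-out data.

Without confounders the model is saturated: the MLE equals the observed
cell log-odds, each θ̂_j is a log cross-product ratio against the
reference cell, and the covariance has the closed form
Var(θ̂_j) = 1/a_j + 1/b_j + 1/a_0 + 1/b_0,
Cov(θ̂_i, θ̂_j) = 1/a_0 + 1/b_0 (a = cases, b = controls). The iterative
fit (`fit_unconstrained`) and the closed form (`saturated_from_counts`)
agree to optimizer tolerance and the closed form is used on hot paths
(bootstrap resamples, simulation replicates).

## Interaction measures and delta-method intervals

RERI = e^θ3 − e^θ1 − e^θ2 + 1, AP = RERI/e^θ3,
S = (e^θ3 − 1)/(e^θ1 + e^θ2 − 2). The delta-method variance is gᵀΣg with
Σ the covariance of (θ̂1, θ̂2, θ̂3) and gradients

* RERI: g = (−e^θ1, −e^θ2, e^θ3)
* AP:   g = (−e^{θ1−θ3}, −e^{θ2−θ3}, (e^θ1+e^θ2−1)e^{−θ3})
* log S: g = (−e^θ1/(e^θ1+e^θ2−2), −e^θ2/(e^θ1+e^θ2−2), e^θ3/(e^θ3−1))

(derived analytically, unit-tested against central finite differences at
relative error < 1e-4). RERI and AP get symmetric normal intervals;
S gets a log-normal interval, which requires S > 0 — when the denominator
of S is ≤ 0 (both exposures null or protective) or S ≤ 0 the estimate is
an explicit *undefined* state, not an exception, and is excluded from
simulation denominators with a logged count. Verdicts use closed
containment: an interval whose endpoint touches the null value (0 for
RERI/AP, 1 for S) counts as "no interaction". Default level 0.95 with the
standard-normal quantile.

The first-order variance is accurate when coefficient standard errors are
small; on sparse tables (e.g. a cell with 3 cases) the exponential
nonlinearity makes the true sampling variance substantially larger than
the delta approximation. This is intrinsic to the method and is one
reason the delta verdicts for the three measures disagree so often — the
motivating defect the IC-based procedures address.

## Constrained maximum likelihood (model M2)

The additive-null manifold {e^θ3 = e^θ1 + e^θ2 − 1} is handled by exact
reparameterization, not by a penalty: with ψ = (θ0, r, θ3), r = θ1 − θ2,

    e^θ1 + e^θ2 = 1 + e^θ3,    e^θ1 / e^θ2 = e^r,

every ψ ∈ R³ maps to a feasible θ and the manifold is covered exactly, so
the quasi-Newton optimizer (BFGS, gradient tolerance 1e-8, ≤ 200
iterations) never meets a boundary. Datasets for which the constrained
model is not estimable (the likelihood pushes the joint-cell odds ratio
to zero, i.e. e^θ1 + e^θ2 → 1⁺) reveal themselves as θ3 → −∞ and raise an
infeasibility error rather than returning a spurious optimum; the
threshold is θ3 < −15, far below any interpretable odds ratio. BFGS
occasionally reports "precision loss" after the gradient is already below
1e-6; convergence is therefore judged by the achieved gradient norm
(1e-5), and genuine non-convergence is flagged, never silent. The
covariance is the inverse numerical Hessian of the reduced problem mapped
through the constraint Jacobian, so Var(IC) at the constrained estimate
is 0 to numerical precision. The constraint never involves γ.

## Penalized estimation

`penalized_fit` minimises −ℓ(θ) + λ·s(IC(θ)) with the smooth absolute
value s(x) = √(x² + ε²), ε = 1e-8. Each fit tries the warm start from the
previous grid point plus both endpoint fits and keeps the best optimum.
When |IC| at the optimum falls below a zero tolerance (1e-4 on the IC
scale) the result is snapped to the exact constrained fit and flagged, so
downstream verdicts do not depend on ε. λ = 0 reproduces the
unconstrained MLE; λ → ∞ reproduces M2 (the Lagrangian and
reparameterized solutions agree in log-likelihood to 1e-4). The default
grid is 41 log-spaced points in [1e-3, 1e3], wide enough to bracket both
regimes for the sample sizes considered; the fitted |IC(θ̂(λ))| is
non-increasing in λ (the constrained-form tuning parameter t(λ)).

λ is tuned by generalization error: one random split (default 2/3 train,
1/3 test, re-drawn up to 10 times if a part lacks an exposure level or an
outcome value), path fitted on the training part, chosen λ minimises the
deviance of the test part at the trained coefficients, ties broken toward
the larger λ. The verdict is "no interaction" iff the chosen fit is the
snapped constrained one. A single split with a one-parameter difference
is intrinsically noisy: under exact additivity an intermediate λ
(shrinkage) often generalizes marginally better than the fully
constrained endpoint, so this verdict has limited specificity; the tests
assert cross-seed discrimination rather than per-dataset correctness.
Selection by an information criterion (`selection="aic"/"bic"/"hq"`,
scoring GDEV + κ·df with df dropping by one only when the constraint is
met) is also provided; it provably coincides with two-model GAIC
selection and is tested for exact agreement. K-fold tuning is
deliberately out of scope: the effective-degrees-of-freedom argument that
justifies criterion-based tuning for coefficient-sparsity penalties fails
here, since df changes only at the constrained endpoint.

## Model selection

M1 and M2 are nested with df difference 1 (one constraint equation).
GAIC(κ) = GDEV + κ·df with κ = 2 (AIC), ln n (BIC), 2 ln(ln n)
(Hannan–Quinn); n is the number of subjects, not cells. A criterion
prefers M1 — declares interaction — exactly when Λ = GDEV₂ − GDEV₁ > κ;
at an exact tie the simpler constrained model wins. For n ≥ 16 the
penalties order 2 < 2 ln(ln n) < ln n, so the datasets declared
interacting nest BIC ⊆ HQ ⊆ AIC (at n = 15, 2 ln(ln 15) = 1.993 is
marginally below 2, a documented edge rather than a corrected one). The
likelihood-ratio test floors Λ at 0 (optimizer noise can produce ≈ −1e-10)
and takes the upper χ²₁ tail.

## Outcome-stratified bootstrap

Case-control designs fix the outcome margins, so resampling is with
replacement *within* cases and *within* controls, preserving both stratum
sizes exactly. For confounder-free data the resampled table is drawn
directly as two multinomials — distributionally identical to row
resampling under the saturated model and orders of magnitude faster —
and each resample is refitted by the closed form; row-level resampling
with a full refit is retained for confounder-adjusted data. Intervals are
percentile intervals (default 300 resamples, level 0.95), one seeded
generator per call with per-replicate substreams. A resample that empties
a cell is, under the default `correct` policy, given the Haldane–Anscombe
0.5 correction (that resample only, counted in the diagnostics); under
`drop` it is discarded and the percentile denominator shrinks — resamples
are never topped up, to keep the count of draws bounded. More than half
unusable resamples is a hard failure. Undefined S values are excluded and
counted. Because the three measures are computed from one shared resample
stream, their percentile verdicts coincide whenever S is defined
throughout — the empirical basis for reporting a single coherent
bootstrap verdict.

## Simulation harness

Datasets are generated from the four-cell model directly: exposure cells
multinomial over the four levels (equal probabilities 1/4 by default),
outcomes Bernoulli at logit θ0 + θ_j, with θ0 = 0 and θ the logs of the
scenario odds ratios. The seven standard scenarios fix OR10 = 4,
OR01 = 5 and sweep OR11 = 20, 16, 12, 8, 6, 4, 2 — strong synergy through
exact additivity (OR11 = 8 = 4 + 5 − 1) to strong antagonism. A master
seed spawns one substream per replicate (and a separate substream for
each replicate's bootstrap), so results are independent of evaluation
order. Per replicate, each requested method issues a verdict; methods
that cannot (undefined measure, infeasible constrained fit) are excluded
from that method's denominator and counted. Default 1000 replicates per
cell; the cost is dominated by the bootstrap cell (300 closed-form
refits per replicate), about 15 s per 1000-replicate scenario on one CPU.

What the generator emulates — and what it does not: it produces cohort
(prospective Bernoulli) data with a common baseline log-odds of 0 and
balanced exposure cells. Real case-control data differ in two ways that
matter for operating characteristics: outcome margins are fixed by
design, and exposure distributions are typically far from balanced. The
no-interaction fractions in the power scenarios are quite sensitive to
this design choice — probing alternatives (outcome-balanced case-control
sampling with uniform or cohort-induced control exposure) shifts the
S2-scenario fractions by 0.2–0.4 — whereas the null-scenario (S4) rates
and the qualitative conclusions (fractions shrink with n and effect size;
AIC most liberal, BIC most conservative; the three bootstrap fractions
mutually equal; Hannan–Quinn tracking the bootstrap within 2%) are robust
across all designs tried. Passing simulation tests therefore validate the
estimators and the comparative behaviour of the methods, not the absolute
power numbers of any particular real design.

## Numerical choices and degenerate inputs

- Fitting never applies continuity corrections silently: an empty cell
  raises an error naming the cell, and the 0.5 correction is an explicit,
  logged `CountTable.corrected()` step (the simulation harness applies it
  automatically to the rare replicate with an empty cell and counts it).
- All-cases or all-controls data raise a degenerate-data error.
- Convergence: gradient norm 1e-8 requested, 200 iteration cap,
  non-convergence flagged on the returned model.
- Constraint satisfaction of M2 is exact by construction (|IC| < 1e-8 in
  tests only guards against regression).
- Reported human-readable tables round to 3 decimals; JSON keeps full
  precision.

## Known limitations

- Logistic (odds-ratio) scale only; Cox or log-binomial variants of the
  measures are out of scope, as are Bayesian intervals and more than two
  interacting factors.
- The delta interval for S requires S > 0; heavily antagonistic data
  yield an undefined S verdict by design.
- Percentile is the only bootstrap flavour (no BCa / bootstrap-t).
- Generalization-error tuning of λ is a weak discriminator at these
  sample sizes (see above); the model-selection route is the recommended
  decision procedure, with HQ as the default criterion.
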