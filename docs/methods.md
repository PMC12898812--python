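# Methods

This note documents the models, estimators and numerical choices behind
`ushape`, the assumptions of the synthetic data generator, and what the
simulation-based tests do and do not establish about real data.

## Model

The observational unit is a single foot; feet are clustered within
participants. For foot *j* of participant *i* with exposure `x_ij` (SSNDT,
mm), weekly training load `L_i` (h/week) and training experience `E_i`
(years — participant attributes shared by both feet), the adjusted quadratic
model is

    logit P(y_ij = 1 | u_i) = β₀ + β₁ x_c + β₂ x_c² + γ_L L_c + γ_E E_c + u_i,
    u_i ~ N(0, σ_u²),

with all continuous predictors mean-centered at their full-sample means
(subscript `_c`); the centering constants are stored in the fit so raw-scale
prediction is exact. Linear (drop x²) and cubic (add x³) forms support
model comparison. β₂ > 0 gives a U-shaped risk curve with a unique interior
minimum; the cubic form has no stable minimum and is excluded from all
threshold machinery.

## Estimation

The marginal likelihood integrates `u_i` out of each cluster's contribution.
The integral is evaluated by **adaptive Gauss–Hermite quadrature** (default
15 nodes): each cluster's integrand is re-centered at its posterior mode and
re-scaled by the mode curvature before applying the Hermite rule, so one
node reproduces the Laplace approximation exactly. Optimization is L-BFGS-B
over (β, log σ_u), log σ_u bounded in [−5, 3]; at the lower bound the model
is numerically an ordinary logistic regression, which is also the exact
σ_u → 0 limit of the implementation. Initialisation is deterministic: a
Newton/IRLS plain-logistic fit for β, then a fast profile stage (below).
Standard errors come from the observed information (central-difference
Hessian of the marginal log-likelihood, inverted, fixed-effect block); when
σ_u is pinned at the boundary the Hessian is taken over β alone.

A **fast profile path** serves bootstrap and simulation workloads: for fixed
σ_u, penalized IRLS (block-Newton in (β, u), u-block solved in closed form
via the Schur complement) maximizes the joint penalized likelihood, and a
bounded 1-D search over log σ_u maximizes the Laplace objective, with warm
starts across evaluations. One fit costs a few milliseconds at n = 274. The
fast path profiles β inside the joint optimization (lme4's "fast" glmer
stage); against the exact AGQ optimum this attenuates σ_u and shifts mainly
the intercept (|Δβ₀| ≈ 0.07 at study size) while the slope and curvature
terms agree to ~3 decimal places — adequate for percentile intervals and
calibrated resampling tests, and the default AGQ path is used everywhere a
point estimate is reported. The AGQ implementation reproduces lme4
`glmer(nAGQ=25)` coefficients, SEs, σ_u and log-likelihood to ≤1e-3 on a
study-sized dataset (tested via Rscript when available).

Model comparison uses AIC = −2ℓ + 2k and BIC = −2ℓ + k·ln n with
k = fixed effects + 1 (the variance parameter) and n = number of feet;
Nagelkerke R² rescales Cox–Snell R² computed from marginal log-likelihoods
against the intercept-plus-random-intercept null. Perfect separation and
one-class outcomes raise explicit errors (no Firth correction — separation
is reported, not repaired).

## Risk-curve geometry

All threshold geometry is closed-form in the fitted quadratic:
`x_min = x̄ − β₁/(2β₂)`; `OR(x) = exp(β₂ (x − x_min)²)` relative to the
minimum (covariates cancel); thresholds at target r are
`x_min ± sqrt(ln r / β₂)`. Although the closed form is exact, every
threshold is cross-validated internally against Brent root-finding on
`OR(x) − r` over brackets `x_min ± 20` mm, with a 1e-6 mm agreement guard —
exactness plus an independent numerical route. The local risk gradient is
reported as the exact 1-mm odds contrast `exp(β₁ + β₂(2x_c + 1))`, with the
instantaneous form `exp(β₁ + 2β₂ x_c)` under a flag, since "odds ratio per
1 mm" is ambiguous between the two; they differ by `exp(β₂)` ≈ 5% here.
Emitted tables round to 2 decimals; JSON keeps full precision.

## Bootstrap

Nonparametric bootstrap at the **participant level**: each replicate draws
n participants with replacement; both feet of a drawn participant enter
together, and repeated draws become distinct clusters. Each replicate
refits the quadratic model (fast path) and recomputes `x_min` and all
threshold pairs. Intervals are percentile (the simplest method consistent
with reporting only "bootstrap 95% CIs"; BCa is not implemented).
Replicates whose fit fails or whose β̂₂ ≤ 0 are dropped and counted in
`n_effective`; fewer than B/2 survivors is an error. Adjacent OR levels are
*redundant* when their CIs overlap on **either** arm, so "distinct" demands
non-overlap of both the lower and the upper threshold interval — the
conservative reading of a two-sided comparison (overlap-on-one-side cases
are classified redundant).

## Segmented model and breakpoint test

The broken-line logit `β₀ + b x_c + Σ_m d_m (x − ψ_m)₊ + covariates + u_i`
is continuous at each breakpoint. ψ is estimated by profile ML over a
candidate grid (default 50 points between the 5th and 95th exposure
percentiles), refined by a bounded scalar search between the best grid
point's neighbours; `se(ψ)` comes from the finite-difference curvature of
the profile log-likelihood. A flat profile — the 1.92-drop (95%)
profile-likelihood region spanning more than half the candidate range, or
non-negative curvature — raises an `unstable` flag instead of an error.
The two-breakpoint fit searches ordered candidate pairs on a coarser grid
(12 points) and flags instability when more than a quarter of all pairs are
within 1.92 log-likelihood units of the maximum; at the study's size and a
smooth quadratic truth this flag fires in most replicates.

The existence test is Davies-type: the statistic is the maximal LRT over
the grid for adding one hinge to the linear adjusted mixed model, and its
null distribution is obtained by **parametric bootstrap** from the fitted
no-breakpoint model (simulate u and y, refit, re-maximize), which accounts
for the search over candidates by construction; p = (1 + #{sim ≥ obs})/(B+1).
The analytic Davies bound is conservative and its exact variant
underdetermined, so the simulation route was chosen; its size is verified
by a 200-run type-I-error simulation (observed rejection 0.06 at nominal
0.05, within binomial error). Calibration of this construction holds for
any grid size and B, so the test suite uses a reduced grid (6–8 candidates)
and B = 99 to keep the double simulation loop at desk scale.

## Zones and screening

Anchor ORs (default 1.2, 1.5, 1.8, 2.0) give nested bands; zones are the
rings between successive bands (Safe innermost, Extreme outside the widest
band). Bands are closed intervals and a boundary-exact value maps to the
inner (safer) zone — the conservative screening default; the original
reporting does not state its tie-break. Zone prevalence is empirical and
*not* expected to be monotone across zones (the model-based odds are, on
each arm separately). An empty zone reports 0.0% prevalence plus an
explicit flag. Screening metrics are exact integer confusion-matrix
arithmetic for the High+Extreme-positive rule; empty margins yield NaN
rather than a silent 0. The planning formula `n = (z/δ)² p(1−p)` is
implemented as printed; note that for p = 0.5, δ = 0.05 it gives 384.2,
commonly rounded to ~380 in planning texts.

## Reliability

ICC(3,1) follows Shrout–Fleiss: two-way ANOVA, single measure,
**consistency** form `(BMS − EMS)/(BMS + (k−1)EMS)`; the label "(3,1)"
denotes consistency even where prose says "absolute agreement", so the
consistency form is primary and the absolute-agreement single-measure
variant is exposed under `absolute_agreement=True`. F = BMS/EMS with
(n−1, (n−1)(k−1)) df gives the test and the standard F-based CI.
Interpretation uses the Koo–Li bands (<0.50 poor, 0.50–0.75 moderate,
0.75–0.90 good, >0.90 excellent; boundary values go to the higher band at
0.75, to "good" at 0.90). Implementation matches `pingouin.intraclass_corr`
to 1e-10.

## Synthetic generator

`GeneratorConfig` defaults encode the study conditions: 137 participants ×
2 feet; SSNDT ~ Normal(7.8, 3.0²) truncated to [0, 25] mm (the simplest
distribution matching the two reported moments; the truncation window
mirrors the data-validation plausibility window); load ~ N(7.7, 3.1²) and
experience ~ N(4.3, 0.6²) truncated at 0, drawn per participant and shared
by both feet; conditional quadratic-logit truth (β₀, β₁, β₂) =
(−1.96, 0.238, 0.051) with covariate effects (0.005, 0.341) on the centered
scale; σ_u = 1.0. The study never reports its fitted random-intercept SD,
so σ_u is a documented free knob; 1.0 is a plausible within-person
clustering level for binary outcomes. With these defaults the *marginal*
injury prevalence is ≈ 23.5%, slightly above the 21% conditional target,
because marginalizing a convex-logit over the random intercept raises the
mean — the conditional coefficients and the marginal prevalence cannot both
be matched exactly once σ_u > 0.

What the generator does **not** emulate: cohort-year heterogeneity in
training exposure, left/right asymmetry, measurement error in SSNDT, or any
non-quadratic true risk shape. Passing recovery/coverage tests therefore
show the estimators work when the model is correctly specified at the
study's size — not that the model is correct for real feet.

## Simulation scales and observed results

Problem sizes in the test suite were chosen to probe each property at the
smallest informative scale: parameter recovery uses 200 replicates at the
study size (mean β̂₂ within 3 Monte-Carlo SEs of 0.051; mean x̂_min within
3 MC SEs of 5.467 — note x̂_min is a ratio estimator whose small-sample
bias at n = 137, ≈ −0.5 mm, is of the same order as that Monte-Carlo band);
bootstrap coverage uses 50 outer replicates × B = 300 (observed ≈ 0.92–0.94
for the OR = 2.0 thresholds, within binomial error of 0.95); the type-I
simulation uses 200 runs at 60 participants. Breakpoint recovery is tested
at a strong kink (slopes ∓0.6 per mm, n = 500 participants), where profile
ML localizes ψ to within 0.5 mm; at a weak kink (∓0.3) the information
bound itself only allows ~0.7 mm precision, so no sub-0.5 mm claim is made
there. Against U-shaped data the single-hinge "breakpoint" sits near the
vertex only when the vertex is near the exposure mean (symmetric case);
with the calibrated asymmetric generator it sits between vertex and mean,
as expected for a two-piece linear approximation weighted by the data
density.

## Known limitations

- Random intercepts only; no random slopes, GEE or Bayesian alternatives.
- Percentile bootstrap intervals (no BCa/studentized); slight undercoverage
  at the study size is visible in the coverage simulation.
- The fast Laplace path is biased for σ_u with 2-observation clusters; it
  is never used for reported point estimates.
- Thresholds are defined only for the quadratic model (β₂ > 0).
- The redundancy rule operationalizes "similar ranges" purely as CI
  overlap.
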