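# ushape

U-shaped exposure–response modelling for clustered binary outcomes, built
around a concrete screening problem in sports medicine: how much sit-to-stand
navicular drop (SSNDT, in mm — a functional measure of foot mobility) is
"safe", and when does a foot become too rigid *or* too mobile?

Both extremes of foot mobility elevate lower-limb injury risk, so the usual
pronated/neutral/supinated cut-points are a poor screening tool. `ushape`
replaces them with a data-driven pipeline:

1. **Mixed-effects quadratic logistic regression.** For foot *j* of
   participant *i*,

   ```
   logit P(y_ij = 1) = β₀ + β₁ x_c + β₂ x_c² + γ_L load_c + γ_E exp_c + u_i,
   u_i ~ N(0, σ_u²),
   ```

   with mean-centered predictors (`x_c`), a participant-level random
   intercept `u_i` (both feet of a person are correlated) and adjustment for
   weekly training load and training experience. Estimation is maximum
   marginal likelihood with adaptive Gauss–Hermite quadrature (1 node =
   Laplace); linear and cubic forms are fitted for comparison via AIC/BIC,
   Nagelkerke R² and likelihood-ratio tests.
2. **Minimum-risk point.** For β₂ > 0 the curve is a U with vertex
   `x_min = x̄ − β₁ / (2β₂)` on the raw mm scale — the OR = 1 reference.
3. **OR-anchored two-sided thresholds.** For each target odds ratio r the
   pair `x_min ± sqrt(ln r / β₂)` (closed form, cross-validated against
   bracketed root-finding) marks where predicted odds reach r times the
   minimum; a grid over r = 1.1 … 2.0 maps the whole risk gradient.
4. **Bootstrap distinguishability.** Participant-level resampling refits the
   whole pipeline; overlapping CIs at adjacent OR levels flag them as
   *redundant* — the signature of a smooth risk gradient rather than discrete
   cut-points.
5. **Segmented check.** A broken-line mixed logit with profile-ML breakpoint
   estimation and a bootstrap-calibrated Davies-type existence test verifies
   there are no additional discrete risk transitions.
6. **Risk zones & screening.** Anchor ORs (1.2/1.5/1.8/2.0) define nested
   bands; the rings between them are the ordered zones Safe → Mild →
   Moderate → High → Extreme, with per-zone prevalence and confusion-matrix
   metrics for the High+Extreme-positive screening rule.
7. **Reliability & planning.** Consistency ICC(3,1) with F-based CI for
   test–retest reliability, and the standard proportion sample-size formula.

Because the study's raw data are available only on request, the package
ships a first-class synthetic generator (`ushape.synthetic`) reproducing the
study's statistical structure — truncated-Normal SSNDT (mean 7.8, SD 3 mm),
two correlated feet per participant, calibrated quadratic risk, ~21%
prevalence — so every stage is testable end to end.

## Worked example

Thresholds and zones need no raw data — the published-scale coefficients
suffice (see `examples/02_thresholds_and_zones.py`):

```python
from ushape import RiskCurve, threshold_grid, build_zone_scheme

curve = RiskCurve(beta1=0.238, beta2=0.051, ssndt_mean=7.8)
print(round(curve.x_min_mm, 2))        # 5.47  -> minimum-risk SSNDT in mm
grid = threshold_grid(curve)
print(grid.to_frame().round(2).tail(1))
#    or_target  lower_mm  upper_mm
# 9        2.0      1.78      9.15
```

A foot at 5.47 mm has the lowest predicted injury odds; below 1.78 mm or
above 9.15 mm the odds are at least twice the minimum. `examples/` contains
one short script per capability (simulate+fit, thresholds+zones, bootstrap,
segmented check, reliability+screening); each prints the numbers it computes
with a line of interpretation. A thin CLI mirrors the library:

```sh
ushape simulate --n-participants 137 --seed 3 --out d.csv
ushape fit --data d.csv --out fit.json
ushape thresholds --fit fit.json --out thresholds.csv
ushape all --data d.csv --out-dir run/   # full pipeline + manifest
```

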