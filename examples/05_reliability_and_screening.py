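"""Measurement reliability (ICC) and zone-based screening performance.

Simulates a small test-retest reliability study (two trials on 18 feet),
computes the consistency ICC(3,1), then evaluates the High+Extreme
positive screening rule on a synthetic cohort.
"""

import numpy as np

from ushape import (
    GeneratorConfig,
    RiskCurve,
    assign_zone,
    build_zone_scheme,
    generate_dataset,
    icc_3_1,
    sample_size_proportion,
    screening_metrics,
    zone_report,
)

rng = np.random.default_rng(3)
true_ssndt = rng.normal(7.8, 3.0, size=18)
ratings = true_ssndt[:, None] + rng.normal(0, 1.3, size=(18, 2))
res = icc_3_1(ratings)
print(f"ICC(3,1) = {res.icc:.2f} (95% CI {res.ci[0]:.2f}-{res.ci[1]:.2f}), "
      f"F({res.df1},{res.df2}) = {res.f_statistic:.2f}, p = {res.p:.2g} "
      f"-> {res.interpretation}")

n = sample_size_proportion(0.25, 0.05)
print(f"\nplanning n for a 25% prevalence at +/-5 points: {n:.1f} "
      f"(~{round(n)} feet)")

curve = RiskCurve(beta1=0.238, beta2=0.051, ssndt_mean=7.8)
scheme = build_zone_scheme(curve)
data = generate_dataset(GeneratorConfig(seed=42))
print("\n" + zone_report(scheme, data).table.round(1).to_string(index=False))

zones = [assign_zone(scheme, r.ssndt_mm) for r in data.records]
m = screening_metrics(zones, [r.injured for r in data.records])
print(f"\nHigh+Extreme positive rule: sensitivity {m.sensitivity:.2f}, "
      f"specificity {m.specificity:.2f}, PPV {m.ppv:.2f}, NPV {m.npv:.2f}, "
      f"accuracy {m.accuracy:.2f}")
print("A high NPV means a foot outside the High/Extreme zones is very "
      "unlikely to be injured.")
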