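"""Minimum-risk point, OR-anchored thresholds and risk zones.

Reconstructs the risk curve directly from published-scale coefficients
(beta1 = 0.238, beta2 = 0.051 on the centered scale, exposure mean
7.8 mm) — no raw data needed — then derives the threshold grid, the four
nested bands and the five ordered zones.
"""

from ushape import (
    RiskCurve,
    assign_zone,
    build_zone_scheme,
    local_or_per_mm,
    threshold_grid,
)

curve = RiskCurve(beta1=0.238, beta2=0.051, ssndt_mean=7.8)
print(f"minimum-risk exposure: {curve.x_min_mm:.2f} mm "
      "(odds-ratio reference, OR = 1)")

grid = threshold_grid(curve)
print("\nOR target  lower (mm)  upper (mm)")
for p in grid.pairs:
    print(f"   {p.or_target:4.1f}     {p.lower_mm:6.2f}     {p.upper_mm:6.2f}")

scheme = build_zone_scheme(curve)
print("\nzones from anchors 1.2 / 1.5 / 1.8 / 2.0:")
for label, (lo, hi) in zip(scheme.zone_labels, scheme.boundaries):
    print(f"  {label:<9} band {lo:5.2f} - {hi:5.2f} mm")
print("  Extreme   outside the widest band")

for x in (5.5, 8.0, 9.5, 1.0):
    print(f"  exposure {x:4.1f} mm -> zone {assign_zone(scheme, x):<8} "
          f"(local OR per +1 mm: {local_or_per_mm(curve, x):.2f})")
print("\nA local OR near 1 means flat risk; values far from 1 mark the "
      "steep arms of the U.")
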