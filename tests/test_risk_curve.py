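"""Geometry of the quadratic risk curve: minimum, thresholds, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ushape import (
    ModelSpec,
    RiskCurve,
    fit_mixed_logistic,
    local_or_per_mm,
    minimum_risk_point,
    odds_ratio_at,
    predict_probability,
    threshold_grid,
    thresholds_for_or,
)
from ushape.errors import CurvatureError
from ushape.risk_curve import _root_bracketed

curves = st.builds(
    RiskCurve,
    beta1=st.floats(-1.0, 1.0),
    beta2=st.floats(0.005, 0.5),
    ssndt_mean=st.floats(3.0, 12.0),
)
or_targets = st.floats(1.0001, 5.0)


class TestMinimumRiskPoint:
    def test_closed_form(self, table3_curve):
        assert table3_curve.x_min_mm == pytest.approx(
            7.8 - 0.238 / (2 * 0.051), abs=1e-12
        )

    def test_symmetric_curve_minimum_at_mean(self):
        c = RiskCurve(beta1=0.0, beta2=0.05, ssndt_mean=7.8)
        assert c.x_min_mm == 7.8

    def test_negative_curvature_raises(self):
        with pytest.raises(CurvatureError):
            RiskCurve(beta1=0.2, beta2=-0.01, ssndt_mean=7.8)

    def test_requires_quadratic_fit(self, calibrated_dataset):
        f3 = fit_mixed_logistic(calibrated_dataset, ModelSpec(3),
                                compute_vcov=False)
        with pytest.raises(ValueError, match="quadratic"):
            minimum_risk_point(f3)

    def test_matches_brute_force_minimum_of_fitted_logit(
        self, calibrated_dataset
    ):
        fit = fit_mixed_logistic(calibrated_dataset, ModelSpec(2),
                                 compute_vcov=False)
        curve = minimum_risk_point(fit)
        xs = np.arange(0.0, 25.0, 1e-4)
        probs = predict_probability(fit, xs)
        assert xs[np.argmin(probs)] == pytest.approx(curve.x_min_mm, abs=1e-3)


class TestOddsRatio:
    def test_reference_point_is_one(self, table3_curve):
        assert odds_ratio_at(table3_curve, table3_curve.x_min_mm) == 1.0

    @given(curve=curves, d=st.floats(0.0, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_exact_symmetry(self, curve, d):
        lo = odds_ratio_at(curve, curve.x_min_mm - d)
        hi = odds_ratio_at(curve, curve.x_min_mm + d)
        assert lo == pytest.approx(hi, rel=1e-12)

    def test_upper_threshold_inverts_to_target(self, table3_curve):
        # the published OR=2.0 upper threshold maps back to OR ~ 2
        assert odds_ratio_at(table3_curve, 9.17) == pytest.approx(2.0,
                                                                  abs=0.02)


class TestThresholds:
    @given(curve=curves, target=or_targets)
    @settings(max_examples=200, deadline=None)
    def test_closed_form_equals_root_finder(self, curve, target):
        pair = thresholds_for_or(curve, target, crosscheck=False)
        lo, hi = _root_bracketed(curve, target)
        assert pair.lower_mm == pytest.approx(lo, abs=1e-6)
        assert pair.upper_mm == pytest.approx(hi, abs=1e-6)

    @given(curve=curves, target=or_targets)
    @settings(max_examples=100, deadline=None)
    def test_reconstruction_round_trip(self, curve, target):
        pair = thresholds_for_or(curve, target, crosscheck=False)
        assert odds_ratio_at(curve, pair.lower_mm) == pytest.approx(
            target, rel=1e-9
        )
        assert odds_ratio_at(curve, pair.upper_mm) == pytest.approx(
            target, rel=1e-9
        )

    @given(curve=curves, target=or_targets)
    @settings(max_examples=100, deadline=None)
    def test_pair_equidistant_from_minimum(self, curve, target):
        pair = thresholds_for_or(curve, target, crosscheck=False)
        assert (curve.x_min_mm - pair.lower_mm) == pytest.approx(
            pair.upper_mm - curve.x_min_mm, rel=1e-9
        )

    def test_limit_to_minimum(self, table3_curve):
        pair = thresholds_for_or(table3_curve, 1.0 + 1e-12)
        assert pair.lower_mm == pytest.approx(table3_curve.x_min_mm, abs=1e-4)
        assert pair.upper_mm == pytest.approx(table3_curve.x_min_mm, abs=1e-4)

    def test_bad_target_raises(self, table3_curve):
        with pytest.raises(ValueError):
            thresholds_for_or(table3_curve, 1.0)


class TestThresholdGrid:
    def test_singleton(self, table3_curve):
        grid = threshold_grid(table3_curve, [1.5])
        assert len(grid.pairs) == 1
        assert grid.pairs[0].or_target == 1.5

    @given(curve=curves)
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_widths_increasing(self, curve):
        grid = threshold_grid(curve, crosscheck=False)
        lowers = [p.lower_mm for p in grid.pairs]
        uppers = [p.upper_mm for p in grid.pairs]
        widths = [u - l for l, u in zip(lowers, uppers)]
        assert all(a > b for a, b in zip(lowers, lowers[1:]))
        assert all(a < b for a, b in zip(uppers, uppers[1:]))
        assert all(a < b for a, b in zip(widths, widths[1:]))


class TestLocalGradient:
    def test_unit_step_across_minimum_is_neutral(self, table3_curve):
        # stepping from x_min - 0.5 to x_min + 0.5 leaves the odds unchanged
        assert local_or_per_mm(
            table3_curve, table3_curve.x_min_mm - 0.5
        ) == pytest.approx(1.0, rel=1e-12)

    def test_strictly_increasing(self, table3_curve):
        xs = np.linspace(0, 15, 50)
        vals = local_or_per_mm(table3_curve, xs)
        assert (np.diff(vals) > 0).all()

    @given(curve=curves, x=st.floats(0.0, 20.0))
    @settings(max_examples=100, deadline=None)
    def test_matches_eta_difference(self, curve, x):
        def eta(v):
            vc = v - curve.ssndt_mean
            return curve.beta1 * vc + curve.beta2 * vc**2

        assert local_or_per_mm(curve, x) == pytest.approx(
            np.exp(eta(x + 1) - eta(x)), rel=1e-9
        )
        assert local_or_per_mm(curve, x, instantaneous=True) == pytest.approx(
            np.exp(curve.beta1 + 2 * curve.beta2 * (x - curve.ssndt_mean)),
            rel=1e-9,
        )
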