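"""Closed-form geometry of the fitted quadratic logit.

With centered exposure x_c = x - x_bar the fitted quadratic logit is
eta(x) = beta0 + beta1 x_c + beta2 x_c^2 (+ covariates, which cancel in
every odds ratio below).  For beta2 > 0 the curve is a U with a unique
minimum at

    x_min = x_bar - beta1 / (2 beta2)          (raw mm scale)

and the odds ratio of any exposure relative to that minimum is

    OR(x) = exp(eta(x) - eta(x_min)) = exp(beta2 (x - x_min)^2),

so the two exposures at a target odds ratio r > 1 are the symmetric pair
x_min +/- sqrt(ln r / beta2).  The closed forms are primary; a bracketed
root-finder cross-validates every threshold internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import CurvatureError
from .melogit import MixedLogisticFit

__all__ = [
    "RiskCurve",
    "ThresholdPair",
    "ThresholdGrid",
    "DEFAULT_OR_GRID",
    "minimum_risk_point",
    "odds_ratio_at",
    "thresholds_for_or",
    "threshold_grid",
    "local_or_per_mm",
]

#: Odds-ratio targets 1.1 to 2.0 in 0.1 steps.
DEFAULT_OR_GRID: tuple[float, ...] = tuple(
    round(1.0 + 0.1 * k, 1) for k in range(1, 11)
)

_CROSSCHECK_TOL_MM = 1e-6
_BRACKET_HALFWIDTH_MM = 20.0


@dataclass(frozen=True)
class RiskCurve:
    """The quadratic logit as a function of raw exposure (mm)."""

    beta1: float
    beta2: float
    ssndt_mean: float
    x_min_mm: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.beta2 > 0:
            raise CurvatureError(
                f"beta2 = {self.beta2}: no interior minimum (need beta2 > 0)"
            )
        object.__setattr__(
            self,
            "x_min_mm",
            self.ssndt_mean - self.beta1 / (2.0 * self.beta2),
        )


@dataclass(frozen=True)
class ThresholdPair:
    or_target: float
    lower_mm: float
    upper_mm: float


@dataclass
class ThresholdGrid:
    pairs: list[ThresholdPair]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "or_target": [p.or_target for p in self.pairs],
                "lower_mm": [p.lower_mm for p in self.pairs],
                "upper_mm": [p.upper_mm for p in self.pairs],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ThresholdGrid":
        return cls(
            [
                ThresholdPair(float(r.or_target), float(r.lower_mm),
                              float(r.upper_mm))
                for r in df.itertuples(index=False)
            ]
        )


def minimum_risk_point(fit: MixedLogisticFit) -> RiskCurve:
    """Extract the U-shaped risk curve and its minimum from a quadratic fit."""
    if fit.spec.degree != 2:
        raise ValueError(
            f"minimum-risk point requires a quadratic fit, got degree "
            f"{fit.spec.degree}"
        )
    return RiskCurve(
        beta1=fit.coef("ssndt"),
        beta2=fit.coef("ssndt2"),
        ssndt_mean=fit.centering["ssndt_mean"],
    )


def odds_ratio_at(curve: RiskCurve, ssndt_mm: float | np.ndarray):
    """Odds of injury at x relative to the minimum-risk point (OR >= 1)."""
    x = np.asarray(ssndt_mm, float)
    out = np.exp(curve.beta2 * (x - curve.x_min_mm) ** 2)
    return float(out) if np.isscalar(ssndt_mm) else out


def _root_bracketed(curve: RiskCurve, or_target: float) -> tuple[float, float]:
    """Independent bracketed root-finding on OR(x) - target, both arms."""

    def f(x):
        return odds_ratio_at(curve, x) - or_target

    lo = optimize.brentq(
        f, curve.x_min_mm - _BRACKET_HALFWIDTH_MM, curve.x_min_mm,
        xtol=1e-12,
    )
    hi = optimize.brentq(
        f, curve.x_min_mm, curve.x_min_mm + _BRACKET_HALFWIDTH_MM,
        xtol=1e-12,
    )
    return lo, hi


def thresholds_for_or(
    curve: RiskCurve, or_target: float, crosscheck: bool = True
) -> ThresholdPair:
    """Two-sided exposure thresholds at a target odds ratio (> 1).

    Closed form x_min +/- sqrt(ln r / beta2); with ``crosscheck`` the pair
    is verified against bracketed root-finding to 1e-6 mm.
    """
    if not or_target > 1.0:
        raise ValueError(f"or_target must exceed 1, got {or_target}")
    half = float(np.sqrt(np.log(or_target) / curve.beta2))
    lower, upper = curve.x_min_mm - half, curve.x_min_mm + half
    if crosscheck:
        lo_rf, hi_rf = _root_bracketed(curve, or_target)
        if (
            abs(lo_rf - lower) > _CROSSCHECK_TOL_MM
            or abs(hi_rf - upper) > _CROSSCHECK_TOL_MM
        ):  # pragma: no cover - internal consistency guard
            raise RuntimeError(
                "closed-form and root-finding thresholds disagree: "
                f"{(lower, upper)} vs {(lo_rf, hi_rf)}"
            )
    return ThresholdPair(or_target, lower, upper)


def threshold_grid(
    curve: RiskCurve,
    targets: Sequence[float] = DEFAULT_OR_GRID,
    crosscheck: bool = True,
) -> ThresholdGrid:
    """One threshold pair per target; lower strictly decreasing and upper
    strictly increasing in the target (wider bands at higher odds)."""
    pairs = [thresholds_for_or(curve, t, crosscheck) for t in sorted(targets)]
    lowers = [p.lower_mm for p in pairs]
    uppers = [p.upper_mm for p in pairs]
    if not (
        all(a > b for a, b in zip(lowers, lowers[1:]))
        and all(a < b for a, b in zip(uppers, uppers[1:]))
    ):  # pragma: no cover - guaranteed for beta2 > 0 and distinct targets
        raise RuntimeError("threshold grid lost monotone ordering")
    return ThresholdGrid(pairs)


def local_or_per_mm(
    curve: RiskCurve, ssndt_mm: float | np.ndarray, instantaneous: bool = False
):
    """Local odds ratio for a 1-mm increase in exposure.

    Default is the exact finite contrast exp(eta(x+1) - eta(x)) =
    exp(beta1 + beta2 (2 x_c + 1)); ``instantaneous=True`` returns the
    derivative form exp(eta'(x)) = exp(beta1 + 2 beta2 x_c) instead.
    """
    x = np.asarray(ssndt_mm, float)
    xc = x - curve.ssndt_mean
    if instantaneous:
        out = np.exp(curve.beta1 + 2.0 * curve.beta2 * xc)
    else:
        out = np.exp(curve.beta1 + curve.beta2 * (2.0 * xc + 1.0))
    return float(out) if np.isscalar(ssndt_mm) else out
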