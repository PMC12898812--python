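"""Intra-rater test-retest reliability via the intraclass correlation.

ICC(3,1) in the Shrout-Fleiss convention: a two-way mixed-effects model
with raters (trials) fixed, single-measure, consistency form,

    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) EMS),

where BMS is the between-subjects mean square and EMS the residual mean
square of the two-way ANOVA.  The F statistic BMS/EMS with
(n-1, (n-1)(k-1)) degrees of freedom yields the significance test and
the standard F-based confidence interval.  The absolute-agreement
single-measure variant (which additionally charges the rater variance to
disagreement) is available under a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ICCResult", "icc_3_1", "interpret_icc"]

def interpret_icc(icc: float) -> str:
    """Koo & Li interpretation: <0.50 poor, 0.50-0.75 moderate,
    0.75-0.90 good, >0.90 excellent."""
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci: tuple[float, float]
    f_statistic: float
    df1: int
    df2: int
    p: float
    interpretation: str


def icc_3_1(
    ratings: np.ndarray,
    ci_level: float = 0.95,
    absolute_agreement: bool = False,
) -> ICCResult:
    """Single-measure ICC from an (n subjects x k trials) ratings matrix.

    Default is the consistency form ICC(3,1), which is invariant to a
    fixed shift between trials; ``absolute_agreement=True`` computes the
    two-way mixed absolute-agreement single-measure coefficient instead.
    """
    R = np.asarray(ratings, float)
    if R.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x trials matrix")
    n, k = R.shape
    if k < 2:
        raise ValueError("need at least 2 trials per subject")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.isnan(R).any():
        raise ValueError("ratings must have no missing cells")

    grand = R.mean()
    subj_means = R.mean(axis=1)
    trial_means = R.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_trial = n * np.sum((trial_means - grand) ** 2)
    ss_total = np.sum((R - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_trial
    bms = ss_subj / (n - 1)
    jms = ss_trial / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if bms == 0 and ems == 0:
        raise ValueError("zero variance everywhere: ICC undefined")

    if absolute_agreement:
        icc = (bms - ems) / (bms + (k - 1) * ems + k * (jms - ems) / n)
    else:
        icc = (bms - ems) / (bms + (k - 1) * ems) if ems > 0 else 1.0

    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = bms / ems if ems > 0 else np.inf
    p = float(stats.f.sf(f_obs, df1, df2)) if np.isfinite(f_obs) else 0.0

    # F-based interval for the consistency form (Shrout & Fleiss)
    alpha = 1.0 - ci_level
    if np.isfinite(f_obs):
        fl = f_obs / stats.f.isf(alpha / 2.0, df1, df2)
        fu = f_obs * stats.f.isf(alpha / 2.0, df2, df1)
        ci = (
            float((fl - 1.0) / (fl + k - 1.0)),
            float((fu - 1.0) / (fu + k - 1.0)),
        )
    else:
        ci = (1.0, 1.0)

    return ICCResult(
        icc=float(icc),
        ci=ci,
        f_statistic=float(f_obs),
        df1=df1,
        df2=df2,
        p=p,
        interpretation=interpret_icc(float(icc)),
    )
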