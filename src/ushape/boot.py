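"""Participant-level bootstrap of the threshold pipeline.

Each replicate resamples participants (clusters) with replacement — both
feet of a sampled participant enter together — refits the quadratic
random-intercept model, and recomputes the minimum-risk point and every
two-sided threshold.  Percentile confidence intervals summarise the
replicates; adjacent odds-ratio levels whose intervals overlap on both
sides are flagged redundant, the signature of a smooth continuous risk
gradient rather than discrete breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import Dataset
from .errors import ReliabilityError
from .melogit import ModelSpec, fit_mixed_logistic
from .risk_curve import DEFAULT_OR_GRID, minimum_risk_point, thresholds_for_or

__all__ = [
    "BootstrapThresholds",
    "RedundancyRow",
    "bootstrap_thresholds",
    "classify_redundancy",
    "bootstrap_table",
]


@dataclass(frozen=True)
class BootstrapThresholds:
    or_target: float
    lower_point: float
    lower_ci: tuple[float, float]
    upper_point: float
    upper_ci: tuple[float, float]
    n_effective: int


@dataclass(frozen=True)
class RedundancyRow:
    or_target: float
    redundant_vs_previous: bool | None  # None for the first grid level


def bootstrap_thresholds(
    data: Dataset,
    spec: ModelSpec | None = None,
    targets: Sequence[float] = DEFAULT_OR_GRID,
    B: int = 1000,
    ci_level: float = 0.95,
    seed: int | None = None,
    x_min_track: list | None = None,
    use_agq: bool = False,
) -> list[BootstrapThresholds]:
    """Percentile bootstrap CIs for every threshold on the OR grid.

    Replicate refits use the fast Laplace path by default (``use_agq=True``
    switches to full adaptive quadrature).  Replicates whose fit fails or
    whose quadratic term is non-positive (no interior minimum) are dropped
    and reflected in ``n_effective``; fewer than B/2 survivors raises
    :class:`ReliabilityError`.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if seed is None:
        raise ValueError("seed is mandatory for reproducible bootstrap CIs")
    spec = spec or ModelSpec(degree=2)
    if spec.degree != 2:
        raise ValueError("threshold bootstrap requires the quadratic model")
    targets = sorted(targets)
    rng = np.random.default_rng(seed)

    base_fit = fit_mixed_logistic(data, spec, fast=not use_agq,
                                  compute_vcov=False)
    base_curve = minimum_risk_point(base_fit)
    base_pairs = {
        t: thresholds_for_or(base_curve, t, crosscheck=False) for t in targets
    }

    pids = sorted({r.participant_id for r in data.records})
    n_p = len(pids)
    lowers = {t: [] for t in targets}
    uppers = {t: [] for t in targets}
    for _ in range(B):
        draw = [pids[i] for i in rng.integers(0, n_p, size=n_p)]
        rep = data.subset_participants(draw)
        try:
            fit = fit_mixed_logistic(rep, spec, fast=not use_agq,
                                     compute_vcov=False)
            curve = minimum_risk_point(fit)  # raises if beta2 <= 0
        except Exception:
            continue
        if x_min_track is not None:
            x_min_track.append(curve.x_min_mm)
        for t in targets:
            pair = thresholds_for_or(curve, t, crosscheck=False)
            lowers[t].append(pair.lower_mm)
            uppers[t].append(pair.upper_mm)

    n_eff = len(lowers[targets[0]])
    if n_eff < 0.5 * B:
        raise ReliabilityError(
            f"only {n_eff}/{B} bootstrap replicates produced a valid "
            "U-shaped fit"
        )
    alpha = 100.0 * (1.0 - ci_level) / 2.0
    out = []
    for t in targets:
        lo = np.asarray(lowers[t])
        hi = np.asarray(uppers[t])
        out.append(
            BootstrapThresholds(
                or_target=t,
                lower_point=base_pairs[t].lower_mm,
                lower_ci=(
                    float(np.percentile(lo, alpha)),
                    float(np.percentile(lo, 100.0 - alpha)),
                ),
                upper_point=base_pairs[t].upper_mm,
                upper_ci=(
                    float(np.percentile(hi, alpha)),
                    float(np.percentile(hi, 100.0 - alpha)),
                ),
                n_effective=n_eff,
            )
        )
    return out


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return max(a[0], b[0]) <= min(a[1], b[1])


def classify_redundancy(
    rows: Sequence[BootstrapThresholds],
) -> list[RedundancyRow]:
    """Mark adjacent OR levels redundant when CIs overlap on both sides.

    Non-redundant (statistically distinct) requires non-overlapping
    intervals for BOTH the lower and the upper threshold.  The first grid
    level has no predecessor and is marked not-applicable.
    """
    ts = [r.or_target for r in rows]
    if ts != sorted(ts):
        raise ValueError("rows must be sorted by or_target")
    out: list[RedundancyRow] = []
    for k, row in enumerate(rows):
        if k == 0:
            out.append(RedundancyRow(row.or_target, None))
            continue
        prev = rows[k - 1]
        redundant = _overlap(row.lower_ci, prev.lower_ci) or _overlap(
            row.upper_ci, prev.upper_ci
        )
        out.append(RedundancyRow(row.or_target, redundant))
    return out


def bootstrap_table(
    rows: Sequence[BootstrapThresholds],
    redundancy: Sequence[RedundancyRow] | None = None,
) -> pd.DataFrame:
    """Tabulate bootstrap thresholds, CIs and the redundancy flag."""
    redundancy = redundancy or classify_redundancy(rows)
    flags = {r.or_target: r.redundant_vs_previous for r in redundancy}
    return pd.DataFrame(
        {
            "or_target": [r.or_target for r in rows],
            "lower_mm": [r.lower_point for r in rows],
            "lower_ci_lo": [r.lower_ci[0] for r in rows],
            "lower_ci_hi": [r.lower_ci[1] for r in rows],
            "upper_mm": [r.upper_point for r in rows],
            "upper_ci_lo": [r.upper_ci[0] for r in rows],
            "upper_ci_hi": [r.upper_ci[1] for r in rows],
            "redundant_vs_previous": [
                "-" if flags[r.or_target] is None
                else ("Yes" if flags[r.or_target] else "No")
                for r in rows
            ],
            "n_effective": [r.n_effective for r in rows],
        }
    )
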