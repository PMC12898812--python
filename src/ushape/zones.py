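"""Odds-ratio-anchored risk zones, prevalence tables and screening metrics.

Anchor OR levels (default 1.2, 1.5, 1.8, 2.0) define nested two-sided
exposure bands around the minimum-risk point.  The ordered zones are the
rings between successive bands: Safe is the innermost band, each next
zone is the next band minus the previous, and Extreme is everything
outside the widest band.  Band intervals are closed on both ends, so an
exposure exactly on a boundary maps to the safer (inner) zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import Dataset
from .errors import ValidationError
from .risk_curve import RiskCurve, thresholds_for_or

__all__ = [
    "ZoneScheme",
    "ZoneReport",
    "ScreeningMetrics",
    "DEFAULT_ANCHORS",
    "ZONE_LABELS",
    "build_zone_scheme",
    "assign_zone",
    "zone_report",
    "screening_metrics",
    "sample_size_proportion",
]

DEFAULT_ANCHORS: tuple[float, ...] = (1.2, 1.5, 1.8, 2.0)
ZONE_LABELS: tuple[str, ...] = ("Safe", "Mild", "Moderate", "High", "Extreme")


@dataclass(frozen=True)
class ZoneScheme:
    """Nested band boundaries and the ordered zone labels they induce."""

    anchor_ors: tuple[float, ...]
    boundaries: tuple[tuple[float, float], ...]  # (lower, upper) per anchor
    zone_labels: tuple[str, ...]
    x_min_mm: float

    def __post_init__(self) -> None:
        for (lo1, hi1), (lo2, hi2) in zip(self.boundaries,
                                          self.boundaries[1:]):
            if not (lo2 < lo1 and hi1 < hi2):
                raise ValueError("bands must be strictly nested")


@dataclass
class ZoneReport:
    table: pd.DataFrame  # zone, n_feet, n_injured, prevalence_pct
    empty_zones: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ZoneReport":
        body = df[df["zone"] != "Total"]
        empty = tuple(body.loc[body["n_feet"] == 0, "zone"])
        return cls(df.copy(), empty)


@dataclass(frozen=True)
class ScreeningMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def build_zone_scheme(
    curve: RiskCurve, anchor_ors: Sequence[float] = DEFAULT_ANCHORS
) -> ZoneScheme:
    """Zone scheme from a fitted curve; one more label than anchors."""
    anchors = tuple(float(a) for a in anchor_ors)
    if any(b <= a for a, b in zip(anchors, anchors[1:])) or not anchors:
        raise ValueError("anchor ORs must be non-empty, strictly increasing")
    if anchors[0] <= 1.0:
        raise ValueError("anchor ORs must exceed 1")
    bounds = tuple(
        (p.lower_mm, p.upper_mm)
        for p in (thresholds_for_or(curve, a) for a in anchors)
    )
    labels = ZONE_LABELS if len(anchors) == 4 else tuple(
        [ZONE_LABELS[0]]
        + [f"Zone{k}" for k in range(1, len(anchors))]
        + [ZONE_LABELS[-1]]
    )
    if len(anchors) == 1:
        labels = (ZONE_LABELS[0], ZONE_LABELS[-1])
    return ZoneScheme(anchors, bounds, labels, curve.x_min_mm)


def assign_zone(scheme: ZoneScheme, ssndt_mm: float) -> str:
    """Innermost zone whose band contains the value (closed boundaries)."""
    if not math.isfinite(ssndt_mm):
        raise ValidationError(f"non-finite exposure value: {ssndt_mm!r}")
    for label, (lo, hi) in zip(scheme.zone_labels, scheme.boundaries):
        if lo <= ssndt_mm <= hi:
            return label
    return scheme.zone_labels[-1]


def zone_report(scheme: ZoneScheme, data: Dataset) -> ZoneReport:
    """Per-zone foot counts, injury counts and empirical prevalence (%)."""
    zones = [assign_zone(scheme, r.ssndt_mm) for r in data.records]
    y = np.array([r.injured for r in data.records])
    rows = []
    empty = []
    for label in scheme.zone_labels:
        mask = np.array([z == label for z in zones])
        n = int(mask.sum())
        inj = int(y[mask].sum())
        if n == 0:
            empty.append(label)
        rows.append(
            {
                "zone": label,
                "n_feet": n,
                "n_injured": inj,
                "prevalence_pct": 100.0 * inj / n if n else 0.0,
            }
        )
    rows.append(
        {
            "zone": "Total",
            "n_feet": data.n_feet,
            "n_injured": int(y.sum()),
            "prevalence_pct": 100.0 * y.sum() / data.n_feet
            if data.n_feet
            else 0.0,
        }
    )
    table = pd.DataFrame(rows)
    body = table[table["zone"] != "Total"]
    assert body["n_feet"].sum() == data.n_feet
    assert body["n_injured"].sum() == int(y.sum())
    return ZoneReport(table, tuple(empty))


def screening_metrics(
    zones: Iterable[str],
    outcomes: Iterable[int],
    positive_zones: Sequence[str] = ("High", "Extreme"),
) -> ScreeningMetrics:
    """Confusion matrix and screening metrics for a zone-positive rule.

    A foot is test-positive when its zone is in ``positive_zones``
    (default: the High and Extreme rings combined) and disease-positive
    when injured.  Metrics with an empty margin are returned as NaN.
    """
    pos = set(positive_zones)
    tp = fp = tn = fn = 0
    for z, y in zip(zones, outcomes):
        if y not in (0, 1):
            raise ValidationError(f"outcome {y!r} not in {{0,1}}")
        if z in pos:
            tp, fp = tp + (y == 1), fp + (y == 0)
        else:
            fn, tn = fn + (y == 1), tn + (y == 0)
    n = tp + fp + tn + fn
    if n == 0:
        raise ValidationError("no observations")

    def _ratio(a: int, b: int) -> float:
        return a / b if b else float("nan")

    return ScreeningMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=(tp + tn) / n,
    )


def sample_size_proportion(
    p: float, delta: float, z: float = 1.96, ceiling: bool = False
) -> float | int:
    """Sample size for estimating a proportion to margin ``delta``.

    n = (z / delta)^2 * p * (1 - p); ``ceiling=True`` rounds up to the
    next integer.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if delta <= 0:
        raise ValueError("delta must be positive")
    n = (z / delta) ** 2 * p * (1.0 - p)
    return math.ceil(n) if ceiling else n
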