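"""Risk zones, prevalence tables, screening metrics, sample size."""

import math

import numpy as np
import pandas as pd
import pytest

from ushape import (
    Dataset,
    FootRecord,
    FootSide,
    ZoneReport,
    assign_zone,
    build_zone_scheme,
    odds_ratio_at,
    sample_size_proportion,
    screening_metrics,
    write_table,
    zone_report,
)
from ushape.errors import ValidationError

# Published zone occupancy: (n feet, n injured) per zone, 274 feet total
PUB_ZONE_COUNTS = {
    "Safe": (118, 5),
    "Mild": (50, 8),
    "Moderate": (16, 0),
    "High": (8, 2),
    "Extreme": (82, 43),
}


def dataset_with_zone_counts(scheme, counts=PUB_ZONE_COUNTS) -> Dataset:
    """Synthetic dataset hitting exact per-zone counts (zone midpoints)."""
    reps = {
        "Safe": scheme.x_min_mm,
        "Mild": 0.5 * (scheme.boundaries[0][1] + scheme.boundaries[1][1]),
        "Moderate": 0.5 * (scheme.boundaries[1][1] + scheme.boundaries[2][1]),
        "High": 0.5 * (scheme.boundaries[2][1] + scheme.boundaries[3][1]),
        "Extreme": scheme.boundaries[3][1] + 1.0,
    }
    recs = []
    i = 0
    for zone, (n, injured) in counts.items():
        for k in range(n):
            recs.append(
                FootRecord(
                    f"Z{i // 2:04d}",
                    FootSide.LEFT if i % 2 == 0 else FootSide.RIGHT,
                    reps[zone],
                    1 if k < injured else 0,
                    7.7,
                    4.3,
                )
            )
            i += 1
    return Dataset(recs)


class TestZoneScheme:
    def test_bands_nested(self, table3_curve):
        scheme = build_zone_scheme(table3_curve)
        for (lo1, hi1), (lo2, hi2) in zip(scheme.boundaries,
                                          scheme.boundaries[1:]):
            assert lo2 < lo1 < hi1 < hi2

    def test_single_anchor_two_zones(self, table3_curve):
        scheme = build_zone_scheme(table3_curve, [1.5])
        assert scheme.zone_labels == ("Safe", "Extreme")

    def test_non_increasing_anchors_rejected(self, table3_curve):
        with pytest.raises(ValueError):
            build_zone_scheme(table3_curve, [1.2, 1.2])


class TestAssignZone:
    def test_minimum_is_safe(self, table3_curve):
        scheme = build_zone_scheme(table3_curve)
        assert assign_zone(scheme, table3_curve.x_min_mm) == "Safe"

    def test_beyond_widest_band_is_extreme(self, table3_curve):
        scheme = build_zone_scheme(table3_curve)
        assert assign_zone(scheme, 9.5) == "Extreme"
        assert assign_zone(scheme, 0.1) == "Extreme"

    def test_boundary_maps_to_inner_zone(self, table3_curve):
        scheme = build_zone_scheme(table3_curve)
        inner_upper = scheme.boundaries[0][1]
        assert assign_zone(scheme, inner_upper) == "Safe"

    def test_partition_of_the_line(self, table3_curve):
        scheme = build_zone_scheme(table3_curve)
        xs = np.linspace(-2.0, 30.0, 2001)
        labels = {assign_zone(scheme, float(x)) for x in xs}
        assert labels <= set(scheme.zone_labels)
        for x in xs:
            assert assign_zone(scheme, float(x)) in scheme.zone_labels

    def test_non_finite_rejected(self, table3_curve):
        scheme = build_zone_scheme(table3_curve)
        with pytest.raises(ValidationError):
            assign_zone(scheme, float("nan"))

    def test_model_risk_monotone_across_zones_on_one_side(self, table3_curve):
        # any point of an outer zone carries higher model odds than any
        # point of an inner zone on the same arm of the U
        scheme = build_zone_scheme(table3_curve)
        uppers = [hi for _, hi in scheme.boundaries]
        samples = [
            0.5 * (scheme.x_min_mm + uppers[0]),
            0.5 * (uppers[0] + uppers[1]),
            0.5 * (uppers[1] + uppers[2]),
            0.5 * (uppers[2] + uppers[3]),
            uppers[3] + 0.5,
        ]
        ors = [odds_ratio_at(table3_curve, x) for x in samples]
        assert all(a < b for a, b in zip(ors, ors[1:]))


class TestZoneReport:
    def test_published_counts_reproduce_published_prevalences(
        self, table3_curve
    ):
        scheme = build_zone_scheme(table3_curve)
        ds = dataset_with_zone_counts(scheme)
        report = zone_report(scheme, ds)
        body = report.table.set_index("zone")
        assert round(body.loc["Safe", "prevalence_pct"], 1) == 4.2
        assert round(body.loc["Mild", "prevalence_pct"], 1) == 16.0
        assert body.loc["Moderate", "prevalence_pct"] == 0.0
        assert round(body.loc["High", "prevalence_pct"], 1) == 25.0
        assert round(body.loc["Extreme", "prevalence_pct"], 1) == 52.4
        assert body.loc["Total", "n_feet"] == 274

    def test_empty_zone_flagged(self, table3_curve):
        scheme = build_zone_scheme(table3_curve)
        recs = [
            FootRecord(f"p{i}", s, scheme.x_min_mm, 0, 7.7, 4.3)
            for i in range(5)
            for s in (FootSide.LEFT, FootSide.RIGHT)
        ]
        report = zone_report(scheme, Dataset(recs))
        assert set(report.empty_zones) == {"Mild", "Moderate", "High",
                                           "Extreme"}
        body = report.table.set_index("zone")
        assert body.loc["Mild", "prevalence_pct"] == 0.0

    def test_round_trip(self, tmp_path, table3_curve):
        scheme = build_zone_scheme(table3_curve)
        report = zone_report(scheme, dataset_with_zone_counts(scheme))
        path = tmp_path / "zones.csv"
        write_table(report, path)
        back = ZoneReport.from_frame(pd.read_csv(path))
        pd.testing.assert_frame_equal(report.table, back.table)


class TestScreeningMetrics:
    def test_brute_force_confusion_recount(self):
        rng = np.random.default_rng(4)
        zones = rng.choice(["Safe", "Mild", "High", "Extreme"], size=200)
        ys = rng.integers(0, 2, size=200)
        m = screening_metrics(zones, ys)
        pos = np.isin(zones, ["High", "Extreme"])
        assert m.tp == int((pos & (ys == 1)).sum())
        assert m.tn == int((~pos & (ys == 0)).sum())
        assert m.sensitivity == pytest.approx(m.tp / (m.tp + m.fn))
        assert m.accuracy == pytest.approx((m.tp + m.tn) / 200)

    def test_all_positive_degenerate(self):
        m = screening_metrics(["Extreme"] * 10, [1, 0] * 5)
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0
        assert math.isnan(m.npv)


class TestSampleSize:
    def test_planning_values(self):
        assert sample_size_proportion(0.25, 0.05) == pytest.approx(288.12)
        assert sample_size_proportion(0.50, 0.05) == pytest.approx(384.16)
        assert sample_size_proportion(0.25, 0.05, ceiling=True) == 289

    def test_small_p_boundary(self):
        assert sample_size_proportion(1e-9, 0.05) < 1e-5

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sample_size_proportion(0.0, 0.05)
        with pytest.raises(ValueError):
            sample_size_proportion(0.25, 0.0)
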