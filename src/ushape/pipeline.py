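"""End-to-end stepwise analysis: model comparison, quadratic fit,
minimum-risk point, threshold grid, bootstrap, segmented check, zones and
screening metrics — one table per stage plus a run manifest."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .boot import bootstrap_table, bootstrap_thresholds, classify_redundancy
from .datamodel import Dataset, write_table
from .melogit import (
    ModelSpec,
    fit_indices,
    fit_mixed_logistic,
    fit_null_model,
    likelihood_ratio_test,
)
from .risk_curve import DEFAULT_OR_GRID, minimum_risk_point, threshold_grid
from .segmented import breakpoint_test, fit_segmented
from .zones import (
    DEFAULT_ANCHORS,
    build_zone_scheme,
    screening_metrics,
    zone_report,
    assign_zone,
)

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a full pipeline run; one global seed drives every
    stochastic stage through deterministically derived child seeds."""

    out_dir: str | Path = "ushape_run"
    seed: int = 0
    or_grid: tuple[float, ...] = DEFAULT_OR_GRID
    anchors: tuple[float, ...] = DEFAULT_ANCHORS
    positive_zones: tuple[str, ...] = ("High", "Extreme")
    bootstrap_B: int = 1000
    skip_bootstrap: bool = False
    skip_segmented: bool = False
    segmented_test_B: int = 199
    quad_points: int = 15


def _child_seeds(seed: int, n: int) -> list[int]:
    # counter-based derivation: stage k reruns identically in isolation
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) >> 1]


def run_full_analysis(data: Dataset, cfg: RunConfig) -> dict:
    """Run every stage on a dataset, writing one CSV/JSON per table.

    Returns a dict with the in-memory results and the paths written.
    Any stage failure propagates with the stage name attached; tables
    written before the failure remain on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(cfg.seed, 4)
    t0 = time.time()
    bundle: dict = {"paths": {}}
    stage = "model-comparison"
    try:
        fits = {
            d: fit_mixed_logistic(
                data, ModelSpec(degree=d), quad_points=cfg.quad_points
            )
            for d in (1, 2, 3)
        }
        null = fit_null_model(data, quad_points=cfg.quad_points)
        comp_rows = []
        for d, label in [(1, "Linear"), (2, "Quadratic"), (3, "Cubic")]:
            idx = fit_indices(fits[d], null)
            comp_rows.append(
                {
                    "model": label,
                    "aic": idx.aic,
                    "bic": idx.bic,
                    "nagelkerke_r2": idx.nagelkerke_r2,
                    "loglik": fits[d].loglik,
                }
            )
        comparison = pd.DataFrame(comp_rows)
        lrt12 = likelihood_ratio_test(fits[1], fits[2])
        lrt23 = likelihood_ratio_test(fits[2], fits[3])
        comparison["lrt_vs_simpler_p"] = [np.nan, lrt12[2], lrt23[2]]
        write_table(comparison, out / "model_comparison.csv")
        bundle["model_comparison"] = comparison
        bundle["paths"]["model_comparison"] = str(out / "model_comparison.csv")

        stage = "quadratic-fit"
        fit2 = fits[2]
        write_table(fit2.summary(), out / "quadratic_fit.csv")
        (out / "quadratic_fit.json").write_text(
            json.dumps(fit2.to_dict(), indent=2)
        )
        bundle["quadratic_fit"] = fit2
        bundle["paths"]["quadratic_fit"] = str(out / "quadratic_fit.csv")

        stage = "minimum-risk-point"
        curve = minimum_risk_point(fit2)
        bundle["curve"] = curve

        stage = "threshold-grid"
        grid = threshold_grid(curve, cfg.or_grid)
        write_table(grid, out / "thresholds.csv")
        bundle["thresholds"] = grid
        bundle["paths"]["thresholds"] = str(out / "thresholds.csv")

        if not cfg.skip_bootstrap:
            stage = "bootstrap"
            rows = bootstrap_thresholds(
                data, ModelSpec(degree=2), cfg.or_grid, B=cfg.bootstrap_B,
                seed=seeds[0],
            )
            table = bootstrap_table(rows, classify_redundancy(rows))
            write_table(table, out / "bootstrap_thresholds.csv")
            bundle["bootstrap"] = table
            bundle["paths"]["bootstrap"] = str(
                out / "bootstrap_thresholds.csv"
            )

        if not cfg.skip_segmented:
            stage = "segmented"
            seg = fit_segmented(data, n_breakpoints=1)
            stat, p = breakpoint_test(
                data, B=cfg.segmented_test_B, seed=seeds[1]
            )
            seg_out = {
                "psi_mm": seg.psi.tolist(),
                "psi_se_mm": [
                    None if not np.isfinite(s) else float(s)
                    for s in seg.psi_se
                ],
                "slopes": seg.slopes.tolist(),
                "loglik": seg.loglik,
                "aic": seg.aic,
                "bic": seg.bic,
                "unstable": seg.unstable,
                "davies_statistic": stat,
                "davies_p": p,
            }
            (out / "segmented.json").write_text(json.dumps(seg_out, indent=2))
            bundle["segmented"] = seg_out
            bundle["paths"]["segmented"] = str(out / "segmented.json")

        stage = "zones"
        scheme = build_zone_scheme(curve, cfg.anchors)
        report = zone_report(scheme, data)
        write_table(report, out / "zones.csv")
        zones = [assign_zone(scheme, r.ssndt_mm) for r in data.records]
        metrics = screening_metrics(
            zones, [r.injured for r in data.records], cfg.positive_zones
        )
        (out / "screening.json").write_text(
            json.dumps(metrics.to_dict(), indent=2)
        )
        bundle["zones"] = report
        bundle["screening"] = metrics
        bundle["paths"]["zones"] = str(out / "zones.csv")
        bundle["paths"]["screening"] = str(out / "screening.json")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "child_seeds": seeds,
        "n_feet": data.n_feet,
        "n_participants": data.n_participants,
        "or_grid": list(cfg.or_grid),
        "anchors": list(cfg.anchors),
        "positive_zones": list(cfg.positive_zones),
        "bootstrap_B": cfg.bootstrap_B,
        "skip_bootstrap": cfg.skip_bootstrap,
        "skip_segmented": cfg.skip_segmented,
        "quad_points": cfg.quad_points,
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    bundle["paths"]["manifest"] = str(out / "manifest.json")
    return bundle


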