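#!/usr/bin/env python
"""Statistical calibration of the estimator and tests, by simulation.

Measures, at fixed seed:
  - estimator consistency: max relative error of K-hat against the known
    target over the 0.05 <= f <= 0.95 window, 10,000 droplets;
  - empirical coverage of the 95% Clopper-Pearson interval on K (500 assays)
    against the exactly computed coverage;
  - bootstrap null calibration: rejection rate at alpha=0.05 over 200
    same-scenario assay pairs.

Output: results/calibration.json
"""

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
from scipy import stats

from dropfreeze import (
    INClass,
    Scenario,
    assay_spectrum,
    build_curve,
    compare_t50,
    confidence_interval,
    cumulative_spectrum,
    expected_cumulative_concentration,
    expected_frozen_fraction,
    preset,
    simulate_assay,
)

SEED = 13
RESULTS = Path(__file__).resolve().parent.parent / "results"


def estimator_consistency() -> dict:
    scen = Scenario(
        classes=[
            INClass("steep_warm", 65.0, -4.95, 0.1),
            INClass("steep_mid", 85.0, -6.95, 0.1),
            INClass("steep_cold", 100.0, -8.95, 0.1),
        ],
        n_droplets=10000, n_plates=5,
    )
    curve = build_curve(simulate_assay(scen, seed=SEED))
    spec = cumulative_spectrum(curve, scen.droplet_volume)
    f = expected_frozen_fraction(scen, curve.grid)
    k_true = expected_cumulative_concentration(scen, curve.grid)
    w = (f >= 0.05) & (f <= 0.95) & spec.defined()
    rel = np.abs(spec.K[w] - k_true[w]) / k_true[w]
    return {"max_rel_error_pct": round(100 * float(rel.max()), 2), "n_droplets": 10000}


def ci_coverage() -> dict:
    scen = Scenario(classes=[INClass("mode", 70.0, -7.0, 1.0)], n_droplets=235, n_plates=5)
    k_true = float(expected_cumulative_concentration(scen, -7.0))
    counts = np.arange(scen.n_droplets + 1)
    lo, hi = confidence_interval(counts, scen.n_droplets, scen.droplet_volume)
    covers = (lo <= k_true) & (k_true <= hi)
    p = math.exp(-scen.droplet_volume * k_true)
    exact = float(stats.binom.pmf(counts, scen.n_droplets, p)[covers].sum())
    hits = 0
    for run in range(500):
        spec = assay_spectrum(simulate_assay(scen, seed=SEED * 1000 + run))
        j = int(np.argmin(np.abs(spec.grid + 7.0)))
        hits += bool(spec.ci_low[j] <= k_true <= spec.ci_high[j])
    return {
        "exact_coverage_pct": round(100 * exact, 2),
        "empirical_coverage_pct": round(100 * hits / 500, 1),
        "n_simulations": 500,
    }


def bootstrap_null() -> dict:
    scen = preset("paper_like_rain")
    rejections = 0
    n_pairs = 200
    for run in range(n_pairs):
        a = simulate_assay(scen, seed=800_000 + 2 * run)
        b = simulate_assay(scen, seed=800_001 + 2 * run)
        rejections += compare_t50(a, b, n_resamples=2000, seed=run).boot_p < 0.05
    return {"rejection_rate_pct": round(100 * rejections / n_pairs, 1), "n_pairs": n_pairs}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    report = {
        "estimator_consistency": estimator_consistency(),
        "ci_coverage": ci_coverage(),
        "bootstrap_null_calibration": bootstrap_null(),
    }
    (RESULTS / "calibration.json").write_text(json.dumps(report, indent=2) + "\n")
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
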