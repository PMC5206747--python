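"""Paired control-vs-treated comparison of drop-freezing assays.

Quantifies what a treatment (heating, filtration) removed from a sample's
ice-nucleus population: the decrease in onset freezing temperature, the shift
in median freezing temperature (Delta T50), and the percent of cumulative IN
concentration lost at reference temperatures (default -6, -8, -10 degC),

    pct_sensitive(T*) = 100 * (K_control(T*) - K_treated(T*)) / K_control(T*).

Significance of the T50 shift is assessed two ways and both are reported: a
Welch two-sample test on the per-droplet freezing temperatures, and a seeded
percentile bootstrap of Delta T50 (droplets resampled with replacement within
each group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .assay import (
    DEFAULT_GRID_STEP,
    DropletAssay,
    assay_spectrum,
    build_curve,
    median_freezing_temperature,
    onset_temperature,
    spectrum_at,
)

__all__ = [
    "SensitivityPoint",
    "T50Test",
    "TreatmentComparison",
    "DEFAULT_REF_TEMPS",
    "DEFAULT_N_RESAMPLES",
    "onset_decrease",
    "percent_sensitive",
    "compare_t50",
    "build_comparison_table",
    "comparison_frame",
    "holm_adjust",
    "t50_of_events",
]

DEFAULT_REF_TEMPS = (-6.0, -8.0, -10.0)
DEFAULT_N_RESAMPLES = 2000


@dataclass(frozen=True)
class SensitivityPoint:
    """Treatment-sensitive IN share at one reference temperature."""

    ref_temp: float
    k_control: float
    k_treated: float
    pct_raw: float  # may be negative or >100 by sampling noise
    pct_clamped: float  # clipped into [0, 100] for headline tables
    treated_censored: bool = False  # K_treated undefined (all droplets frozen)


@dataclass(frozen=True)
class T50Test:
    delta_t50: float
    welch_stat: float
    welch_p: float
    boot_p: float
    method: str
    n_resamples: int
    seed: int


@dataclass
class TreatmentComparison:
    """One control/treated pair of assays, summarised."""

    sample_id: str
    control_label: str
    treated_label: str
    onset_control: float | None = None
    onset_treated: float | None = None
    onset_decrease: float | None = None
    t50_control: float | None = None
    t50_treated: float | None = None
    delta_t50: float | None = None
    sensitivity: list[SensitivityPoint] = field(default_factory=list)
    test: T50Test | None = None


def onset_decrease(onset_control: float | None, onset_treated: float | None) -> float | None:
    """Onset lowering by the treatment: onset_control - onset_treated.

    Positive when the treatment removed the warmest-active nuclei. None when
    either onset is undefined.
    """
    if onset_control is None or onset_treated is None:
        return None
    return round(onset_control - onset_treated, 6)


def percent_sensitive(k_control: float, k_treated: float) -> tuple[float, float]:
    """Share of cumulative IN concentration removed by a treatment, percent.

    Returns ``(raw, clamped)``: the raw value can leave [0, 100] through
    sampling noise; the clamped copy is clipped for headline tables.
    Raises ValueError when the control concentration is not positive.
    """
    if not (k_control > 0) or math.isnan(k_control):
        raise ValueError("percent_sensitive undefined for k_control <= 0")
    raw = 100.0 * (k_control - k_treated) / k_control
    return raw, min(100.0, max(0.0, raw))


# ---------------------------------------------------------------------------
# T50 testing
# ---------------------------------------------------------------------------


def t50_of_events(temps: np.ndarray, grid_step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Vectorised grid-interpolated T50 for rows of freezing temperatures.

    ``temps`` is (B, n); censored droplets are encoded as -inf. Reproduces the
    curve-based :func:`dropfreeze.assay.median_freezing_temperature` exactly
    (same grid, same closed-above counting, same interpolation). Rows where
    fewer than half the droplets froze give NaN.
    """
    temps = np.atleast_2d(np.asarray(temps, dtype=float))
    B, n = temps.shape
    m = int(math.ceil(n / 2))  # frozen count needed for f >= 0.5
    # m-th largest temperature per row: the warmest T at which f first reaches 0.5
    kth = np.partition(temps, n - m, axis=1)[:, n - m]
    out = np.full(B, np.nan)
    ok = np.isfinite(kth)
    if not ok.any():
        return out if B > 1 else out
    t_m = kth[ok]
    # warmest grid point g with g <= t_m (+tol): first point where f >= 0.5
    g1 = -grid_step * np.ceil(np.round(-(t_m + 1e-9) / grid_step, 9))
    g1 = np.minimum(g1, 0.0)
    g0 = g1 + grid_step  # previous (warmer) grid point, f < 0.5 there
    rows = temps[ok]
    f1 = (rows >= g1[:, None] - 1e-9).sum(axis=1) / n
    f0 = (rows >= g0[:, None] - 1e-9).sum(axis=1) / n
    t50 = np.where(
        np.isclose(f1, 0.5, atol=1e-12) | (g0 > 1e-12),
        g1,
        g0 + (0.5 - f0) * (-grid_step) / (f1 - f0),
    )
    out[ok] = t50
    return out


def _event_matrix(assay: DropletAssay) -> np.ndarray:
    return assay.event_temperatures(censored_as=-np.inf)


def compare_t50(
    assay_control: DropletAssay,
    assay_treated: DropletAssay,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
) -> T50Test:
    """Welch test plus percentile bootstrap on the T50 shift.

    ``delta_t50 = t50_control - t50_treated`` (positive when the treatment
    pushed the median colder). The bootstrap resamples droplets with
    replacement within each group, recomputes Delta T50 on each resample, and
    reports the two-sided percentile p-value with add-one correction,
    ``p = 2 * min((1+#{d* <= 0}), (1+#{d* >= 0})) / (B+1)`` capped at 1.
    The Welch test uses the non-censored per-droplet freezing temperatures.
    """
    if seed is None:
        raise ValueError("compare_t50 requires an explicit seed")
    a = _event_matrix(assay_control)
    b = _event_matrix(assay_treated)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each assay needs at least 2 droplets")
    t50_a = float(t50_of_events(a[None, :], grid_step)[0])
    t50_b = float(t50_of_events(b[None, :], grid_step)[0])
    if math.isnan(t50_a) or math.isnan(t50_b):
        raise ValueError("T50 undefined for at least one assay (censored)")
    delta = t50_a - t50_b

    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, len(a), size=(n_resamples, len(a)))
    idx_b = rng.integers(0, len(b), size=(n_resamples, len(b)))
    d_star = t50_of_events(a[idx_a], grid_step) - t50_of_events(b[idx_b], grid_step)
    d_star = d_star[~np.isnan(d_star)]
    B = len(d_star)
    n_le = int((d_star <= 0).sum())
    n_ge = int((d_star >= 0).sum())
    boot_p = min(1.0, 2.0 * min(n_le + 1, n_ge + 1) / (B + 1))

    fa = a[np.isfinite(a)]
    fb = b[np.isfinite(b)]
    welch = stats.ttest_ind(fa, fb, equal_var=False)
    return T50Test(
        delta_t50=delta,
        welch_stat=float(welch.statistic),
        welch_p=float(welch.pvalue),
        boot_p=boot_p,
        method="welch+percentile-bootstrap",
        n_resamples=n_resamples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# comparison tables
# ---------------------------------------------------------------------------


def _compare_pair(
    control: DropletAssay,
    treated: DropletAssay,
    ref_temps,
    grid_step: float,
    ci_level: float,
    n_resamples: int,
    seed: int,
) -> TreatmentComparison:
    curve_c = build_curve(control, grid_step)
    curve_t = build_curve(treated, grid_step)
    spec_c = assay_spectrum(control, grid_step, ci_level)
    spec_t = assay_spectrum(treated, grid_step, ci_level)
    cmp = TreatmentComparison(
        sample_id=control.sample_id,
        control_label=control.treatment,
        treated_label=treated.treatment,
        onset_control=onset_temperature(curve_c),
        onset_treated=onset_temperature(curve_t),
        t50_control=median_freezing_temperature(curve_c),
        t50_treated=median_freezing_temperature(curve_t),
    )
    cmp.onset_decrease = onset_decrease(cmp.onset_control, cmp.onset_treated)
    if cmp.t50_control is not None and cmp.t50_treated is not None:
        cmp.delta_t50 = cmp.t50_control - cmp.t50_treated
        cmp.test = compare_t50(control, treated, n_resamples, seed, grid_step)
    for rt in ref_temps:
        kc = spectrum_at(spec_c, rt)
        kt = spectrum_at(spec_t, rt)
        treated_censored = (
            spec_t.censored_below is not None and rt < spec_t.censored_below + 1e-9
        )
        if math.isnan(kc) or kc <= 0:
            continue  # sensitivity undefined (no control freezing yet, or censored)
        kt_eff = 0.0 if math.isnan(kt) and not treated_censored else kt
        if math.isnan(kt_eff):
            raw, clamped = float("nan"), float("nan")
        else:
            raw, clamped = percent_sensitive(kc, kt_eff)
        cmp.sensitivity.append(
            SensitivityPoint(
                ref_temp=rt,
                k_control=kc,
                k_treated=kt,
                pct_raw=raw,
                pct_clamped=clamped,
                treated_censored=treated_censored,
            )
        )
    return cmp


def build_comparison_table(
    assays: list[DropletAssay],
    control_label: str = "crude",
    ref_temps=DEFAULT_REF_TEMPS,
    grid_step: float = DEFAULT_GRID_STEP,
    ci_level: float = 0.95,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int | None = None,
) -> list[TreatmentComparison]:
    """One comparison per sample x non-control treatment.

    Samples lacking a ``control_label`` assay are skipped (the caller decides
    whether to warn). Bootstrap seeds are derived per pair from ``seed``.
    """
    if seed is None:
        raise ValueError("build_comparison_table requires a seed")
    by_sample: dict[str, dict[str, DropletAssay]] = {}
    for a in assays:
        by_sample.setdefault(a.sample_id, {})[a.treatment] = a
    out: list[TreatmentComparison] = []
    pair_idx = 0
    for sample_id in by_sample:
        group = by_sample[sample_id]
        if control_label not in group:
            continue
        control = group[control_label]
        for trt, treated in group.items():
            if trt == control_label:
                continue
            pair_seed = int(
                np.random.SeedSequence([seed, pair_idx]).generate_state(1)[0] % (2**31)
            )
            out.append(
                _compare_pair(
                    control, treated, ref_temps, grid_step, ci_level, n_resamples, pair_seed
                )
            )
            pair_idx += 1
    return out


def comparison_frame(comparisons: list[TreatmentComparison], ref_temps=DEFAULT_REF_TEMPS) -> pd.DataFrame:
    """Flatten comparisons into the tabular output layout."""

    def _col(t: float) -> str:
        mag = abs(t)
        return f"m{int(mag)}" if float(mag).is_integer() else f"m{mag}".replace(".", "p")

    rows = []
    for c in comparisons:
        row: dict[str, object] = {
            "sample_id": c.sample_id,
            "treatment": c.treated_label,
            "onset_c": c.onset_treated,
            "onset_decrease_c": c.onset_decrease,
            "t50_c": c.t50_treated,
            "delta_t50_c": c.delta_t50,
        }
        sens = {s.ref_temp: s for s in c.sensitivity}
        for rt in ref_temps:
            s = sens.get(rt)
            row[f"k_{_col(rt)}"] = s.k_control if s else float("nan")
            row[f"pct_{_col(rt)}"] = s.pct_clamped if s else float("nan")
        row["p_welch"] = c.test.welch_p if c.test else float("nan")
        row["p_boot"] = c.test.boot_p if c.test else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment for a family of pairwise tests."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]
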