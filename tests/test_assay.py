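"""Unit tests for curve building, the K(T) spectrum, onset and T50."""

import math

import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from dropfreeze import (
    DropletAssay,
    DropletRecord,
    FreezingCurve,
    build_curve,
    confidence_interval,
    cumulative_spectrum,
    median_freezing_temperature,
    onset_temperature,
    spectrum_at,
    summarize_assay,
)
from .conftest import make_assay


def _grid_value(curve, temp):
    j = np.argmin(np.abs(curve.grid - temp))
    assert abs(curve.grid[j] - temp) < 1e-9
    return j


class TestBuildCurve:
    def test_two_droplet_counts(self, two_droplet_assay):
        # events at -3.0 and -5.0: both unfrozen above -3.0, one unfrozen on
        # [-3.0, -4.8], none at -5.0 and below (closed-above convention)
        curve = build_curve(two_droplet_assay, grid_step=0.2)
        assert curve.n_total == 2
        assert curve.grid[0] == 0.0 and curve.grid[-1] == pytest.approx(-5.0)
        assert curve.n_unfrozen[_grid_value(curve, -2.8)] == 2
        assert curve.n_unfrozen[_grid_value(curve, -3.0)] == 1
        assert curve.n_unfrozen[_grid_value(curve, -4.8)] == 1
        assert curve.n_unfrozen[_grid_value(curve, -5.0)] == 0

    def test_all_censored_droplets_stay_unfrozen(self):
        assay = make_assay([-12.0] * 235, censored=[True] * 235)
        curve = build_curve(assay)
        assert np.all(curve.n_unfrozen == 235)
        assert onset_temperature(curve) is None

    def test_empty_assay_rejected(self):
        assay = DropletAssay(sample_id="x", treatment="crude", records=[])
        with pytest.raises(ValueError, match="no droplets"):
            build_curve(assay)

    def test_brute_force_recount(self, rng):
        # 47 droplets uniform on [-8, -4]: counts at every grid point must
        # equal a direct recount of the event list, and f reaches 1 at the end
        temps = rng.uniform(-8.0, -4.0, size=47)
        curve = build_curve(make_assay(temps), grid_step=0.2)
        for j, g in enumerate(curve.grid):
            assert curve.n_unfrozen[j] == int((temps < g - 1e-9).sum())
        assert np.all(np.diff(curve.n_unfrozen) <= 0)
        assert curve.frozen_fraction[-1] == 1.0

    def test_positive_freezing_temperature_rejected(self):
        with pytest.raises(ValueError, match="above 0"):
            DropletRecord(plate_id="p", droplet_id="d", freeze_temp=3.0)

    def test_duplicate_droplet_id_rejected(self):
        recs = [
            DropletRecord("p1", "d1", -4.0),
            DropletRecord("p1", "d1", -5.0),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            DropletAssay(sample_id="x", treatment="crude", records=recs)


class TestSpectrum:
    def test_no_freezing_gives_zero(self):
        curve = FreezingCurve(grid=[0.0, -0.2], n_total=235, n_unfrozen=[235, 235])
        spec = cumulative_spectrum(curve, volume=0.01)
        assert spec.K == pytest.approx([0.0, 0.0])

    def test_printed_formula_evaluation(self):
        # K = ln(235/9)/0.01 for a 10-uL assay with 9 droplets left unfrozen
        curve = FreezingCurve(grid=[0.0, -6.0], n_total=235, n_unfrozen=[235, 9])
        spec = cumulative_spectrum(curve, volume=0.01)
        assert spec.K[1] == pytest.approx(math.log(235 / 9) / 0.01)
        assert spec.K[1] == pytest.approx(326.2, abs=0.05)

    def test_half_frozen_closed_form(self):
        curve = FreezingCurve(grid=[0.0, -8.0], n_total=100, n_unfrozen=[100, 50])
        spec = cumulative_spectrum(curve, volume=0.01)
        assert spec.K[1] == pytest.approx(100 * math.log(2))

    def test_censored_below_marks_exhaustion(self):
        curve = FreezingCurve(grid=[0.0, -4.0, -6.0], n_total=10, n_unfrozen=[10, 2, 0])
        spec = cumulative_spectrum(curve, volume=0.01)
        assert math.isnan(spec.K[2]) and math.isnan(spec.ci_high[2])
        assert spec.censored_below == pytest.approx(-6.0)
        assert spec.defined().tolist() == [True, True, False]

    def test_spectrum_identity_against_frozen_fraction(self, rng):
        # K(T) = -ln(1 - f(T))/V via an independent code path
        temps = rng.uniform(-12, -3, size=200)
        curve = build_curve(make_assay(temps))
        spec = cumulative_spectrum(curve, volume=0.01)
        f = curve.frozen_fraction
        ok = spec.defined()
        alt = -np.log(1.0 - f[ok]) / 0.01
        np.testing.assert_allclose(spec.K[ok], alt, rtol=1e-9, atol=1e-9)


class TestConfidenceInterval:
    def test_no_events_lower_bound_zero(self):
        low, high = confidence_interval(100, 100, volume=0.01)
        assert low == 0.0 and high > 0

    def test_brackets_point_estimate(self):
        low, high = confidence_interval(50, 100, volume=0.01, level=0.95)
        k = 100 * math.log(2)
        assert low < k < high

    def test_matches_independent_binomial_interval(self):
        # beta-quantile interval on the unfrozen proportion, pushed through
        # K = -ln(p)/V, must match statsmodels' Clopper-Pearson bounds
        for n_unfrozen, n_total in [(9, 235), (50, 100), (1, 47), (234, 235)]:
            low, high = confidence_interval(n_unfrozen, n_total, volume=0.01)
            p_lo, p_hi = proportion_confint(n_unfrozen, n_total, alpha=0.05, method="beta")
            assert low == pytest.approx(-math.log(p_hi) / 0.01, rel=1e-12, abs=1e-9)
            assert high == pytest.approx(-math.log(p_lo) / 0.01, rel=1e-12)

    def test_exhausted_assay_upper_bound_infinite(self):
        low, high = confidence_interval(0, 47, volume=0.01)
        assert math.isinf(high) and 0 < low < math.inf

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            confidence_interval(5, 4, volume=0.01)
        with pytest.raises(ValueError):
            confidence_interval(1, 4, volume=0.01, level=1.5)


class TestOnsetAndT50:
    def test_onset_is_warmest_event(self, two_droplet_assay):
        assert onset_temperature(build_curve(two_droplet_assay)) == pytest.approx(-3.0)

    def test_t50_exact_grid_crossing(self):
        curve = FreezingCurve(grid=[0.0, -8.0], n_total=2, n_unfrozen=[2, 1])
        assert median_freezing_temperature(curve) == pytest.approx(-8.0)

    def test_t50_linear_interpolation(self):
        curve = FreezingCurve(
            grid=[0.0, -8.0, -8.2], n_total=10, n_unfrozen=[10, 6, 4]
        )
        # f goes 0.4 -> 0.6 across [-8.0, -8.2]; the 0.5 crossing is -8.1
        assert median_freezing_temperature(curve) == pytest.approx(-8.1)

    def test_t50_undefined_when_half_never_freeze(self):
        curve = FreezingCurve(grid=[0.0, -10.0], n_total=10, n_unfrozen=[10, 6])
        assert median_freezing_temperature(curve) is None

    def test_t50_close_to_event_median(self, rng):
        # uniform events on [-10, -6]: T50 within one grid step of the
        # brute-force sample median
        temps = rng.uniform(-10.0, -6.0, size=471)
        curve = build_curve(make_assay(temps))
        t50 = median_freezing_temperature(curve)
        assert t50 == pytest.approx(float(np.median(temps)), abs=0.2)

    def test_onset_not_colder_than_t50(self, rng):
        temps = rng.uniform(-12.0, -2.0, size=100)
        curve = build_curve(make_assay(temps))
        assert onset_temperature(curve) >= median_freezing_temperature(curve)


class TestSmallSampleOracle:
    """Hand-enumerated values for assays of <= 5 droplets."""

    def test_two_droplets(self, two_droplet_assay):
        curve = build_curve(two_droplet_assay)
        spec = cumulative_spectrum(curve, volume=0.01)
        assert onset_temperature(curve) == pytest.approx(-3.0)
        # at -3.0 one of two droplets is frozen: K = ln(2)/V, and f = 0.5
        assert spectrum_at(spec, -3.0) == pytest.approx(math.log(2) / 0.01)
        assert median_freezing_temperature(curve) == pytest.approx(-3.0)

    def test_five_droplets(self):
        temps = [-2.0, -4.0, -6.0, -8.0, -10.0]
        curve = build_curve(make_assay(temps))
        spec = cumulative_spectrum(curve, volume=0.01)
        assert onset_temperature(curve) == pytest.approx(-2.0)
        # third of five frozen at -6.0: f = 0.6 crosses 0.5 between -4.0
        # (f=0.4) and -4.2 (still 0.4) ... first f >= 0.5 at -6.0; the
        # interpolation runs between -5.8 (f=0.4) and -6.0 (f=0.6) -> -5.9
        assert median_freezing_temperature(curve) == pytest.approx(-5.9)
        for temp, n_unfrozen in [(-2.0, 4), (-4.0, 3), (-6.0, 2), (-8.0, 1)]:
            assert spectrum_at(spec, temp) == pytest.approx(math.log(5 / n_unfrozen) / 0.01)
        assert spec.censored_below == pytest.approx(-10.0)


def test_summary_reports_per_plate_values(rng):
    temps = rng.uniform(-9.0, -5.0, size=94)
    assay = make_assay(temps, plates=2)
    summary = summarize_assay(assay)
    assert summary.n_total == 94
    assert set(summary.plate_onsets) == {"plate1", "plate2"}
    assert summary.onset_temp == max(
        v for v in summary.plate_onsets.values() if v is not None
    )


def test_spectrum_at_interpolates_and_masks():
    curve = FreezingCurve(grid=[0.0, -2.0, -4.0], n_total=10, n_unfrozen=[10, 8, 4])
    spec = cumulative_spectrum(curve, volume=0.01)
    k2 = math.log(10 / 8) / 0.01
    k4 = math.log(10 / 4) / 0.01
    assert spectrum_at(spec, -3.0) == pytest.approx((k2 + k4) / 2)
    assert math.isnan(spectrum_at(spec, -5.0))
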