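"""Indicator engineering: sine interpolation, deficit transform, windows,
histogram accumulation, percentile thresholds and extreme-day counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropclimex import indicators as ind

from conftest import brute_force_counts


class TestSineInterpolation:
    def test_zero_amplitude_constant(self):
        samples = ind.interpolate_daily_temperature(20.0, 20.0, 24)
        assert np.allclose(samples, 20.0)

    def test_four_sample_closed_form(self):
        """Phases {0, pi/2, pi, 3pi/2} give {mean, mean+amp, mean, mean-amp}."""
        samples = ind.interpolate_daily_temperature(0.0, 10.0, 4)
        assert np.allclose(np.sort(samples.ravel()), [0.0, 5.0, 5.0, 10.0])
        assert np.allclose(samples.ravel(), [5.0, 10.0, 5.0, 0.0])

    def test_sample_mean_and_bounds(self):
        samples = ind.interpolate_daily_temperature(10.0, 30.0, 24)
        assert abs(samples.mean() - 20.0) < 1e-9
        assert samples.min() >= 10.0 - 1e-12 and samples.max() <= 30.0 + 1e-12

    def test_bounds_never_violated_bulk(self):
        rng = np.random.default_rng(0)
        tmin = rng.uniform(-40, 40, size=100_000)
        tmax = tmin + rng.uniform(0, 30, size=100_000)
        samples = ind.interpolate_daily_temperature(tmin, tmax, 8)
        assert (samples >= tmin[:, None] - 1e-9).all()
        assert (samples <= tmax[:, None] + 1e-9).all()

    def test_rejects_inverted_range(self):
        with pytest.raises(ValueError):
            ind.interpolate_daily_temperature(5.0, 4.0, 24)


class TestDeficit:
    @pytest.mark.parametrize(
        "sm,expected", [(0.4, 0.0), (0.1, 1.0), (0.25, 0.5)]
    )
    def test_linear_endpoints_and_midpoint(self, sm, expected):
        assert ind.soil_moisture_to_deficit(sm, 0.1, 0.4) == pytest.approx(expected)

    def test_monotone_decreasing_in_sm(self):
        sm = np.linspace(0.1, 0.4, 50)
        d = ind.soil_moisture_to_deficit(sm, 0.1, 0.4)
        assert (np.diff(d) < 0).all()

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            ind.soil_moisture_to_deficit(0.3, 0.3, 0.3)


class TestSeasonWindow:
    def test_same_year_window(self):
        win = ind.extract_season_window(200, year=1, window_days=90)
        assert win[0] == 365 + 110 and win[-1] == 365 + 199
        assert len(win) == 90

    def test_wraparound_window(self):
        """Harvest DOY 30: the 90-day window spans prior-year days 306-365
        plus days 1-30 of the harvest year."""
        win = ind.extract_season_window(30, year=1, window_days=90)
        assert win[0] == 305  # absolute index of prior-year DOY 306
        assert win[-1] == 365 + 29
        assert len(win) == 90

    def test_single_day_window(self):
        win = ind.extract_season_window(120, year=0, window_days=1)
        assert list(win) == [119]

    def test_window_before_record_rejected(self):
        with pytest.raises(ValueError):
            ind.extract_season_window(30, year=0, window_days=90)


class TestHistograms:
    def test_constant_temperature_single_bin(self):
        t = np.full(90, 20.0)
        h = ind.accumulate_histograms(t, t, np.full(90, 0.3), samples_per_day=24)
        assert h.temp_counts.sum() == pytest.approx(90.0)
        assert (h.temp_counts > 0).sum() == 1
        assert h.temp_counts.max() == pytest.approx(90.0)

    def test_deficit_bin_edge_assignment(self):
        """Deficit 0.5005 falls in half-open bin [0.500, 0.501) = index 500."""
        t = np.full(90, 20.0)
        h = ind.accumulate_histograms(t, t, np.full(90, 0.5005))
        assert h.deficit_counts[500] == pytest.approx(90.0)
        assert h.deficit_counts.sum() == pytest.approx(90.0)

    def test_pathological_temperature_clamped(self):
        t = np.full(10, 75.0)  # beyond the 60 degC bin range
        h = ind.accumulate_histograms(t, t, np.full(10, 0.5))
        assert h.temp_counts[-1] == pytest.approx(10.0)

    def test_mass_conservation(self, small_world):
        _, weather, calendar, *_ = small_world
        win = ind.extract_season_window(200, 2, 90)
        h = ind.accumulate_histograms(
            weather["tmin"].values[0, win],
            weather["tmax"].values[0, win],
            np.clip(weather["sm"].values[0, win], 0, 1),
        )
        assert h.temp_counts.sum() == pytest.approx(90.0)
        assert h.deficit_counts.sum() == pytest.approx(90.0)


class TestMergeRegimes:
    def _pair(self):
        t1 = np.full(90, 20.0)
        t2 = np.full(90, 25.0)
        h1 = ind.accumulate_histograms(t1, t1, np.full(90, 0.2))
        h2 = ind.accumulate_histograms(t2, t2, np.full(90, 0.8))
        return h1, h2

    def test_degenerate_weight_keeps_first(self):
        h1, h2 = self._pair()
        m = ind.merge_regimes(h1, h2, 1.0, 0.0)
        assert np.allclose(m.temp_counts, h1.temp_counts)

    def test_linearity_binwise(self):
        h1, h2 = self._pair()
        m = ind.merge_regimes(h1, h2, 0.3, 0.7)
        assert np.allclose(m.temp_counts, 0.3 * h1.temp_counts + 0.7 * h2.temp_counts)
        assert m.temp_counts.sum() == pytest.approx(90.0)

    def test_bad_weights_rejected(self):
        h1, h2 = self._pair()
        with pytest.raises(ValueError):
            ind.merge_regimes(h1, h2, 0.3, 0.6)


class TestPercentilesAndCounts:
    def test_uniform_pool_q90(self):
        pooled = np.zeros(800)
        pooled[1:101] = 1.0
        assert ind.percentile_threshold(pooled, 90) == 90

    def test_single_bin_pool_any_q(self):
        pooled = np.zeros(800)
        pooled[300] = 42.0
        for q in (5, 50, 95):
            assert ind.percentile_threshold(pooled, q) == 300

    def test_threshold_monotone_in_q(self):
        rng = np.random.default_rng(1)
        pooled = rng.random(800)
        assert ind.percentile_threshold(pooled, 90) >= ind.percentile_threshold(
            pooled, 10
        )

    def test_order_invariance_of_pooling(self, small_world):
        _, weather, *_ = small_world
        hists = []
        for year in range(1, 6):
            win = ind.extract_season_window(200, year, 90)
            hists.append(
                ind.accumulate_histograms(
                    weather["tmin"].values[0, win],
                    weather["tmax"].values[0, win],
                    np.clip(weather["sm"].values[0, win], 0, 1),
                )
            )
        t1 = ind.percentile_threshold(hists, 90, "temp")
        t2 = ind.percentile_threshold(list(reversed(hists)), 90, "temp")
        assert t1 == t2

    def test_counts_beyond_occupied_range_are_zero(self):
        pooled = np.zeros(800)
        pooled[100:200] = 1.0
        assert ind.count_extreme_days(pooled, 400, "above") == 0.0
        assert ind.count_extreme_days(pooled, 50, "below") == 0.0

    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            ind.count_extreme_days(np.ones(800), 10, "sideways")


class TestSeasonAggregates:
    def test_constant_precip_totals(self):
        mt, msm, gsp, anp = ind.season_means_and_totals(
            np.full(90, 21.0), np.full(90, 0.3), np.full(90, 2.0), np.full(365, 2.0)
        )
        assert gsp == pytest.approx(180.0)
        assert anp == pytest.approx(730.0)
        assert mt == pytest.approx(21.0)
        assert msm == pytest.approx(0.3)

    def test_season_precip_bounded_by_annual(self, small_world):
        _, weather, calendar, *_ = small_world
        table = ind.compute_indicators(weather, calendar)
        assert (table["gs_precip"] <= table["annual_precip"] + 1e-9).all()


class TestIndicatorTable:
    def test_extreme_counts_within_season_length(self, small_features):
        table, _ = small_features
        for col in ("hot_days", "dry_days", "cold_days", "wet_days"):
            assert table[col].between(0, 90).all()

    def test_mean_extreme_count_near_ten_percent(self, small_features):
        """Per-cell long-run mean of each extreme count ~ 10% of the season."""
        table, _ = small_features
        means = table.groupby("cell")[
            ["hot_days", "dry_days", "cold_days", "wet_days"]
        ].mean()
        assert ((means - 9.0).abs() < 1.5).all().all()

    def test_histogram_counts_match_brute_force(self, small_world):
        """Oracle equivalence: histogram-derived counts match counts on the
        raw un-binned series within binning granularity."""
        _, weather, calendar, *_ = small_world
        sub = weather.isel(cell=slice(0, 6))
        table = ind.compute_indicators(sub, calendar[calendar.cell < 6])
        oracle = brute_force_counts(sub, calendar[calendar.cell < 6])
        m = table.merge(oracle, on=["cell", "year"], suffixes=("", "_bf"))
        assert len(m) == len(table)
        for col in ("hot_days", "dry_days", "cold_days", "wet_days"):
            assert (m[col] - m[f"{col}_bf"]).abs().max() < 1.5


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    tmin=st.floats(-30, 40),
    spread=st.floats(0, 25),
    k=st.integers(2, 48),
)
def test_sine_samples_average_to_daily_mean(tmin, spread, k):
    """Equispaced samples over a full sine period average to (tmin+tmax)/2."""
    tmax = tmin + spread
    samples = ind.interpolate_daily_temperature(tmin, tmax, k)
    assert samples.mean() == pytest.approx((tmin + tmax) / 2, abs=1e-9)
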