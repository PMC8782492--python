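import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from springpulse.exceptions import (
    IncompleteYearError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from springpulse.hydro_phenology import (
    AnnualPulseFeature,
    annual_mean_flow,
    dsm_covariate,
    lagged_pulse_features,
    pulse_correlation,
    spring_pulse_day,
)
from springpulse.io_formats import DailySeries
from springpulse.synthetic_data import SyntheticScenario, gen_hydrograph


def brute_force_pulse_day(flows, ref):
    """Independent oracle: scan every day's cumulative departure."""
    best_day, best = None, np.inf
    total = 0.0
    for i, q in enumerate(flows, start=1):
        total += q - ref
        if total < best:
            best, best_day = total, i
    return best_day


class TestAnnualMeanFlow:
    def test_constant_year(self):
        assert annual_mean_flow(np.full(365, 5.0)) == 5.0

    def test_short_gap_interpolates(self):
        flows = np.full(365, 5.0)
        flows[100] = np.nan
        assert annual_mean_flow(flows, gap_policy=1) == 5.0

    def test_long_gap_marks_year_incomplete(self):
        flows = np.full(365, 5.0)
        flows[100:140] = np.nan
        with pytest.raises(IncompleteYearError):
            annual_mean_flow(flows, gap_policy=10)


class TestSpringPulseDay:
    def test_step_hydrograph_minimum_before_rise(self):
        flows = np.r_[np.full(99, 1.0), np.full(266, 11.0)]
        ref = flows.mean()
        assert spring_pulse_day(flows, ref) == 99
        assert brute_force_pulse_day(flows, ref) == 99

    def test_recession_only_hydrograph_matches_oracle(self):
        flows = np.linspace(100.0, 1.0, 365)
        ref = flows.mean()
        assert spring_pulse_day(flows, ref) == brute_force_pulse_day(flows, ref)

    def test_constant_flow_ties_resolve_to_day_one(self):
        flows = np.full(365, 3.0)
        assert spring_pulse_day(flows, 3.0) == 1

    def test_min_plus_one_convention(self):
        flows = np.r_[np.full(99, 1.0), np.full(266, 11.0)]
        assert spring_pulse_day(flows, flows.mean(), convention="min_plus_one") == 100

    @given(st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=30, max_size=366))
    @settings(max_examples=100, derandomize=True)
    def test_equals_brute_force_oracle_on_random_hydrographs(self, values):
        flows = np.asarray(values)
        ref = float(flows.mean())
        assert spring_pulse_day(flows, ref) == brute_force_pulse_day(flows, ref)

    def test_shift_invariance_with_same_year_reference(self, rng):
        flows = rng.gamma(2.0, 5.0, 365)
        day = spring_pulse_day(flows, flows.mean())
        shifted = flows + 42.0
        assert spring_pulse_day(shifted, shifted.mean()) == day

    @pytest.mark.parametrize("noise_fraction", [0.0, 0.05, 0.10])
    def test_detection_window_on_synthetic_pulses(self, noise_fraction):
        sc = SyntheticScenario(seed=5, noise_fraction=noise_fraction)
        for year in sc.years:
            series, onset = gen_hydrograph(sc, year)
            flows = series.year_values(year)
            day = spring_pulse_day(flows, flows.mean())
            assert onset - 2 <= day <= onset


class TestDsmCovariate:
    @pytest.mark.parametrize("j,pulse,expected", [(119, 119, 0), (130, 119, 11), (100, 119, -19)])
    def test_difference(self, j, pulse, expected):
        assert dsm_covariate(j, pulse) == expected


def _series_from_years(values_by_year):
    import datetime as dt

    dates, values = [], []
    for year, vals in sorted(values_by_year.items()):
        start = dt.date(year, 1, 1)
        dates.extend(start + dt.timedelta(days=i) for i in range(len(vals)))
        values.extend(vals)
    return DailySeries("g", "discharge", "m3/s", dates, values)


class TestLaggedPulseFeatures:
    def test_identical_years_agree_with_current_reference(self):
        year = np.r_[np.full(99, 1.0), np.full(266, 11.0)]
        series = _series_from_years({2001: year, 2002: year})
        feats = lagged_pulse_features(series)
        assert len(feats) == 1
        assert feats[0].year == 2002
        assert feats[0].pulse_day == spring_pulse_day(year, year.mean())

    def test_lower_previous_mean_never_delays_pulse(self):
        rise = np.r_[np.full(99, 1.0), np.full(266, 11.0)]
        prev = 0.8 * rise
        series = _series_from_years({2001: prev, 2002: rise})
        lagged = lagged_pulse_features(series)[0]
        current = spring_pulse_day(rise, rise.mean())
        oracle = brute_force_pulse_day(rise, prev.mean())
        assert lagged.pulse_day == oracle
        assert lagged.pulse_day <= current

    def test_single_year_yields_no_lagged_feature(self):
        series = _series_from_years({2001: np.full(365, 5.0)})
        assert lagged_pulse_features(series) == []


class TestPulseCorrelation:
    def _feats(self, days, reference):
        return [AnnualPulseFeature("g", 2000 + i, 5.0, d, reference)
                for i, d in enumerate(days)]

    def test_identical_series_correlate_perfectly(self):
        cur = self._feats([100, 110, 120], "current_year_mean")
        lag = self._feats([100, 110, 120], "previous_year_mean")
        assert pulse_correlation(cur, lag) == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        cur = self._feats([1, 2, 3], "current_year_mean")
        lag = self._feats([2, 1, 3], "previous_year_mean")
        assert pulse_correlation(cur, lag) == pytest.approx(0.5)

    def test_too_few_pairs(self):
        cur = self._feats([1, 2], "current_year_mean")
        lag = self._feats([2, 1], "previous_year_mean")
        with pytest.raises(InsufficientDataError):
            pulse_correlation(cur, lag)

    def test_constant_series_is_undefined(self):
        cur = self._feats([1, 2, 3], "current_year_mean")
        lag = self._feats([5, 5, 5], "previous_year_mean")
        with pytest.raises(UndefinedStatisticError):
            pulse_correlation(cur, lag)
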