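"""Spoilage-indicator rules: limit crossings, amine quality classes, and
correlation with the sensory quality index."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import qimshelf as q
from qimshelf.indicators import Direction, IndicatorError

# Reference ice-storage putrescine series (mg/kg)
PUTRESCINE = q.IndicatorSeries(
    "putrescine", "mg/kg",
    ((1, 3.28), (4, 13.74), (8, 24.41), (11, 65.84), (14, 409.97)),
)

# Psychrotrophic plate counts: trend-line values with the observed day-14
# count of 7.02 log CFU/g
_PSY_LINE = lambda d: 0.1593 * d + 4.5679
PSYCHRO = q.IndicatorSeries(
    "psychrotrophic", "log CFU/g",
    tuple((d, 7.02 if d == 14 else _PSY_LINE(d)) for d in (1, 4, 8, 11, 14, 18)),
)


class TestIndicatorSeries:
    def test_invariants_enforced(self):
        with pytest.raises(IndicatorError):
            q.IndicatorSeries("x", "", ((1, 1.0),))
        with pytest.raises(IndicatorError):
            q.IndicatorSeries("x", "u", ((4, 1.0), (1, 2.0)))
        with pytest.raises(IndicatorError):
            q.IndicatorSeries("x", "u", ((1, float("nan")),))


class TestFirstCrossingDay:
    def test_psychrotrophic_limit_reached_day14(self):
        rule = q.LimitRule("psychrotrophic", 7.0, Direction.AT_OR_ABOVE)
        assert q.first_crossing_day(PSYCHRO, rule) == 14

    def test_mesophilic_never_reaches_limit(self, noiseless_cfg):
        series = {s.name: s for s in q.simulate_indicators(noiseless_cfg)}
        rule = q.LimitRule("mesophilic", 7.0, Direction.AT_OR_ABOVE)
        assert q.first_crossing_day(series["mesophilic"], rule) is None

    def test_putrescine_low_quality_from_day8(self):
        rule = q.LimitRule("putrescine", 20.0, Direction.ABOVE)
        assert q.first_crossing_day(PUTRESCINE, rule) == 8

    def test_units_mismatch_rejected(self):
        rule = q.LimitRule("psychrotrophic", 7.0, units="CFU/g")
        with pytest.raises(IndicatorError, match="units"):
            q.first_crossing_day(PSYCHRO, rule)

    @given(st.floats(0, 500), st.floats(0, 500))
    def test_raising_threshold_never_fires_earlier(self, t1, t2):
        lo, hi = sorted([t1, t2])
        day_lo = q.first_crossing_day(PUTRESCINE, q.LimitRule("putrescine", lo))
        day_hi = q.first_crossing_day(PUTRESCINE, q.LimitRule("putrescine", hi))
        if day_hi is not None:
            assert day_lo is not None and day_lo <= day_hi


class TestCrossingDayContinuous:
    def test_identity_slope(self):
        fit = q.LinearFit(1.0, 0.0, 1.0, 0.0, 6)
        assert q.crossing_day_continuous(fit, q.LimitRule("x", 7.0)) == 7.0

    def test_psychrotrophic_fitted_line(self):
        fit = q.LinearFit(0.1593, 4.5679, 0.9747, 0.0, 6)
        day = q.crossing_day_continuous(fit, q.LimitRule("psychrotrophic", 7.0))
        assert day == pytest.approx(15.27, abs=0.01)

    def test_already_violated_at_day_zero(self):
        falling = q.LinearFit(-0.5, 9.0, 1.0, 0.0, 6)
        assert q.crossing_day_continuous(falling, q.LimitRule("x", 7.0)) == 0.0

    def test_trend_moving_away_never_crosses(self):
        falling = q.LinearFit(-0.5, 5.0, 1.0, 0.0, 6)
        assert q.crossing_day_continuous(falling, q.LimitRule("x", 7.0)) is None

    def test_flat_line_below_threshold(self):
        flat = q.LinearFit(0.0, 5.0, 1.0, 0.0, 6)
        assert q.crossing_day_continuous(flat, q.LimitRule("x", 7.0)) is None

    def test_agrees_with_discrete_within_one_interval(self, noiseless_cfg):
        for s in q.simulate_indicators(noiseless_cfg):
            if s.name == "putrescine":
                continue  # exponential trend; the straight-line fit is biased
            rule = q.LimitRule(s.name, s.values[-1])  # threshold = last value
            discrete = q.first_crossing_day(s, rule)
            continuous = q.crossing_day_continuous(s.fit(), rule)
            assert discrete is not None and continuous is not None
            gaps = max(b - a for a, b in zip(s.days, s.days[1:]))
            assert abs(discrete - continuous) <= gaps


class TestClassifyAmine:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (3.28, q.AmineQuality.FRESH),
            (9.999, q.AmineQuality.FRESH),
            (10.0, q.AmineQuality.INTERMEDIATE),
            (13.74, q.AmineQuality.INTERMEDIATE),
            (20.0, q.AmineQuality.INTERMEDIATE),
            (24.41, q.AmineQuality.LOW_QUALITY),
            (409.97, q.AmineQuality.LOW_QUALITY),
        ],
    )
    def test_quality_bands(self, value, expected):
        assert q.classify_amine(value) is expected

    def test_negative_rejected(self):
        with pytest.raises(IndicatorError):
            q.classify_amine(-1.0)

    @given(st.floats(0, 1000, allow_nan=False))
    def test_total_ordered_partition(self, value):
        order = [q.AmineQuality.FRESH, q.AmineQuality.INTERMEDIATE,
                 q.AmineQuality.LOW_QUALITY]
        cls = q.classify_amine(value)
        assert cls in order
        # monotone: a larger value never maps to a fresher class
        bigger = q.classify_amine(value + 5.0)
        assert order.index(bigger) >= order.index(cls)


class TestPearson:
    def test_perfect_positive_and_negative(self):
        assert q.pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert q.pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_two_noiseless_lines_correlate_perfectly(self, noiseless_cfg):
        days = noiseless_cfg.sampling_days
        qi = [noiseless_cfg.qi_line(d) for d in days]
        psy = [_PSY_LINE(d) for d in days]
        assert q.pearson(qi, psy) == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(IndicatorError, match="constant"):
            q.pearson([1, 1, 1], [1, 2, 3])

    @given(
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_affine_invariance(self, scale, shift):
        a = [1.0, 2.5, 3.0, 5.5]
        b = [0.5, 1.0, 3.0, 4.0]
        rescaled = [scale * v + shift for v in a]
        assert q.pearson(rescaled, b) == pytest.approx(q.pearson(a, b), abs=1e-9)


class TestCorrelationMatrix:
    def _panel(self, days, qis):
        return [
            q.PanelQi(storage_day=d, qi_mean=v, qi_sd=0.0, n_assessments=1,
                      per_parameter_mean={})
            for d, v in zip(days, qis)
        ]

    def test_indicator_identical_to_qi(self):
        days, qis = (1, 4, 8), (2.0, 5.0, 9.0)
        series = q.IndicatorSeries("twin", "u", tuple(zip(days, qis)))
        mat = q.correlation_matrix(self._panel(days, qis), [series])
        assert mat.loc["qi", "twin"] == pytest.approx(1.0)

    def test_symmetric_with_unit_diagonal(self, protocol, study):
        panel = q.aggregate_panel(study.assessments, protocol)
        mat = q.correlation_matrix(panel, study.indicator_series)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 1.0)

    def test_too_few_common_days_rejected(self):
        series = q.IndicatorSeries("x", "u", ((1, 1.0), (2, 2.0)))
        with pytest.raises(IndicatorError, match="common days"):
            q.correlation_matrix(self._panel((1, 2), (1.0, 2.0)), [series])


def test_indicator_csv_round_trip(study, tmp_path):
    path = tmp_path / "ind.csv"
    q.write_indicator_csv(study.indicator_series, path)
    back = {s.name: s for s in q.read_indicator_csv(path)}
    for s in study.indicator_series:
        got = back[s.name]
        assert got.units == s.units
        assert got.days == s.days
        assert got.values == pytest.approx(s.values)
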