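"""Unit and property tests for the three criteria and the interval check."""

import itertools
import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as scipy_stats

from sgtools import (
    ConfigError,
    CriteriaConfig,
    MeasurementSeries,
    TriState,
    check_interval,
    crit1_met,
    crit2_met,
    critical_value,
    pattern_evaluable,
)
from sgtools.criteria import crit3_met


class TestCrit1:
    @pytest.mark.parametrize(
        "x_n, x_n1, cutoff, direction, expected",
        [
            (30, 23, 7, "gain", TriState.MET),        # drop of exactly 7 counts
            (30, 24, 7, "gain", TriState.NOT_MET),    # 6 < 7
            (None, 24, 7, "gain", TriState.INDETERMINATE),
            (30, None, 7, "gain", TriState.INDETERMINATE),
            (23, 30, 7, "loss", TriState.MET),
            (30, 23, 7, "loss", TriState.NOT_MET),
            (20.0, 13.0, 7.0, "gain", TriState.MET),
        ],
    )
    def test_examples(self, x_n, x_n1, cutoff, direction, expected):
        assert crit1_met(x_n, x_n1, cutoff, direction) is expected

    @pytest.mark.parametrize("bad", [0, -3])
    def test_nonpositive_cutoff_rejected(self, bad):
        with pytest.raises(ConfigError):
            crit1_met(30, 20, bad)


class TestCrit2:
    @pytest.mark.parametrize(
        "x_n, x_n1, pct, direction, expected",
        [
            (40, 30, 0.25, "gain", TriState.MET),      # 10 is exactly 25% of 40
            (40, 31, 0.25, "gain", TriState.NOT_MET),  # 9 < 10
            (0, 0, 0.25, "gain", TriState.NOT_MET),    # no positive score to drop from
            (-2, -10, 0.25, "gain", TriState.NOT_MET),
            (None, 30, 0.25, "gain", TriState.INDETERMINATE),
            (40, float("nan"), 0.25, "gain", TriState.INDETERMINATE),
            (30, 40, 0.25, "loss", TriState.MET),      # rise of 10 >= 25% of 30
            (40, 30, 0.25, "loss", TriState.NOT_MET),
        ],
    )
    def test_examples(self, x_n, x_n1, pct, direction, expected):
        assert crit2_met(x_n, x_n1, pct, direction) is expected


class TestCriticalValue:
    @pytest.mark.parametrize(
        "n_pre, n_post, expected",
        [(3, 3, 2.776), (3, 2, 3.182), (2, 3, 3.182), (2, 2, 4.303)],
    )
    def test_missing_data_quantiles(self, n_pre, n_post, expected):
        assert critical_value(n_pre, n_post, 0.05) == pytest.approx(expected, abs=5e-4)

    @given(alpha=st.floats(0.001, 0.499))
    def test_monotone_in_df(self, alpha):
        full = critical_value(3, 3, alpha)
        one_missing = critical_value(3, 2, alpha)
        two_missing = critical_value(2, 2, alpha)
        assert full < one_missing < two_missing

    def test_df_below_one_rejected(self):
        with pytest.raises(ConfigError):
            critical_value(1, 1, 0.05)


def eq1_oracle(pre, post, alpha=0.05, direction="gain", fixed_c=None):
    """Brute-force evaluation of the stability criterion, independent path.

    Uses the statistics module for the moments and evaluates the
    mean-difference vs critical-multiple-of-pooled-SD inequality directly.
    """
    if len(pre) < 2 or len(post) < 2:
        return None
    m_pre, m_post = statistics.fmean(pre), statistics.fmean(post)
    sd_pre, sd_post = statistics.stdev(pre), statistics.stdev(post)
    pooled = math.sqrt(
        ((len(pre) - 1) * sd_pre**2 + (len(post) - 1) * sd_post**2)
        / (len(pre) + len(post) - 2)
    )
    c = fixed_c if fixed_c is not None else float(
        scipy_stats.t.ppf(1 - alpha / 2, len(pre) + len(post) - 2)
    )
    diff = (m_pre - m_post) if direction == "gain" else (m_post - m_pre)
    return diff > c * pooled


class TestCrit3:
    config = CriteriaConfig(crit1_cutoff=7)

    def test_clean_windows_met(self):
        res = crit3_met((30, 29, 28), (18, 17, 16), self.config)
        assert res.verdict is TriState.MET
        ws = res.window_stats
        assert (ws.mean_pre, ws.mean_post) == (29, 17)
        assert ws.pooled_sd == pytest.approx(1.0)
        assert res.critical_value_used == pytest.approx(2.776, abs=5e-4)

    def test_constant_windows_not_met(self):
        # zero pooled SD reduces the test to a strict mean comparison
        res = crit3_met((20, 20, 20), (20, 20, 20), self.config)
        assert res.verdict is TriState.NOT_MET

    def test_missing_points_adjust_critical_value(self):
        # one point missing on each side: df = 2, critical value 4.303
        res = crit3_met((30, None, 28), (18, 17, None), self.config)
        assert res.verdict is TriState.MET
        ws = res.window_stats
        assert (ws.n_pre, ws.n_post) == (2, 2)
        assert (ws.mean_pre, ws.mean_post) == (29, 17.5)
        assert ws.pooled_sd == pytest.approx(math.sqrt(1.25))
        assert res.critical_value_used == pytest.approx(4.303, abs=5e-4)
        # 11.5 > 4.303 * 1.118 = 4.811, with room to spare
        assert ws.mean_pre - ws.mean_post > 4.81

    def test_single_sided_window_indeterminate(self):
        res = crit3_met((30, None, None), (18, 17, 16), self.config)
        assert res.verdict is TriState.INDETERMINATE
        assert res.window_stats is None

    def test_fixed_critical_value_mode(self):
        cfg = CriteriaConfig(crit1_cutoff=7, crit3_adjust=False,
                             crit3_critical_value=2.776)
        res = crit3_met((30, None, 28), (18, 17, None), cfg)
        assert res.critical_value_used == 2.776
        assert res.verdict is TriState.MET
        assert eq1_oracle([30, 28], [18, 17], fixed_c=2.776) is True

    @given(
        pre=st.lists(st.integers(0, 63), min_size=2, max_size=3),
        post=st.lists(st.integers(0, 63), min_size=2, max_size=3),
        direction=st.sampled_from(["gain", "loss"]),
    )
    @settings(max_examples=300)
    def test_agrees_with_brute_force_oracle(self, pre, post, direction):
        cfg = CriteriaConfig(crit1_cutoff=7, direction=direction)
        res = crit3_met(pre, post, cfg)
        expected = eq1_oracle(pre, post, direction=direction)
        assert (res.verdict is TriState.MET) == expected

    @given(
        pre=st.lists(st.integers(0, 63), min_size=2, max_size=3),
        post=st.lists(st.integers(0, 63), min_size=2, max_size=3),
    )
    @settings(max_examples=300)
    def test_relation_to_classical_two_sample_t(self, pre, post):
        """The criterion is the classical pooled t test with a rescaled bound.

        t = (M_pre - M_post) / (s_p * sqrt(1/n1 + 1/n2)), so the criterion
        M_pre - M_post > c * s_p is t > c / sqrt(1/n1 + 1/n2) whenever the
        pooled SD is positive.
        """
        cfg = CriteriaConfig(crit1_cutoff=7)
        res = crit3_met(pre, post, cfg)
        if res.window_stats.pooled_sd == 0:
            return
        t_stat = scipy_stats.ttest_ind(pre, post, equal_var=True).statistic
        bound = res.critical_value_used / math.sqrt(1 / len(pre) + 1 / len(post))
        assert (res.verdict is TriState.MET) == (t_stat > bound)


TABLE_PATTERNS = [
    (0, 1, 1, 1, 1, 0),
    (0, 1, 1, 1, 0, 1),
    (1, 0, 1, 1, 1, 0),
    (1, 0, 1, 1, 0, 1),
]


class TestPatternEvaluable:
    def test_exhaustive_against_pattern_superset_rule(self):
        """Evaluable iff the availability covers one of the four minimum patterns."""
        for avail in itertools.product((0, 1), repeat=6):
            expected = any(
                all(a >= p for a, p in zip(avail, pat)) for pat in TABLE_PATTERNS
            )
            assert pattern_evaluable(avail) == expected, avail

    def test_minimum_four_points(self):
        counts = [
            sum(avail)
            for avail in itertools.product((0, 1), repeat=6)
            if pattern_evaluable(avail)
        ]
        assert min(counts) == 4

    @pytest.mark.parametrize(
        "avail, expected",
        [
            ((0, 1, 1, 1, 1, 0), True),
            ((1, 0, 1, 1, 0, 1), True),
            ((1, 1, 0, 1, 1, 1), False),  # pregain point missing
            ((1, 1, 1, 0, 1, 1), False),  # postgain point missing
        ],
    )
    def test_examples(self, avail, expected):
        assert pattern_evaluable(avail) is expected


class TestCheckInterval:
    def test_planted_interval_is_gain(self, default_config):
        series = MeasurementSeries(1, (32, 30, 29, 28, 18, 17, 16, 12))
        ev = check_interval(series, 4, default_config)
        assert ev.is_gain is TriState.MET
        assert (ev.crit1, ev.crit2, ev.crit3) == (TriState.MET,) * 3
        assert (ev.n_pre_available, ev.n_post_available) == (3, 3)
        assert ev.critical_value_used == pytest.approx(2.776, abs=5e-4)

    def test_fully_missing_series_indeterminate(self, default_config):
        series = MeasurementSeries(1, (None,) * 8)
        for n in range(1, 8):
            assert check_interval(series, n, default_config).is_gain \
                is TriState.INDETERMINATE

    def test_constant_series_not_met(self, default_config):
        series = MeasurementSeries(1, (20,) * 8)
        for n in range(2, 7):
            assert check_interval(series, n, default_config).is_gain \
                is TriState.NOT_MET

    def test_out_of_range_session_names_valid_range(self, default_config):
        series = MeasurementSeries(1, (20,) * 8)
        with pytest.raises(ValueError, match="1 <= n <= 7"):
            check_interval(series, 8, default_config)
        with pytest.raises(ValueError):
            check_interval(series, 0, default_config)

    def test_unevaluable_pattern_overrides_definite_failures(self, default_config):
        """A not-met criterion 1 still yields an NA combined flag when the
        window cannot support criterion 3 (only the pregain pair present)."""
        series = MeasurementSeries(1, (None, None, 20, 19, None, None, None, None))
        ev = check_interval(series, 3, default_config)
        assert ev.crit1 is TriState.NOT_MET
        assert ev.crit3 is TriState.INDETERMINATE
        assert ev.is_gain is TriState.INDETERMINATE

    def test_definite_failure_with_full_window_is_not_met(self, default_config):
        # criteria 1+2 fail, criterion 3 met: combined is 0, not NA
        series = MeasurementSeries(1, (30, 29, 28, 24, 23, 22, 21, 20))
        ev = check_interval(series, 3, default_config)
        assert ev.crit1 is TriState.NOT_MET
        assert ev.crit3 is TriState.MET
        assert ev.is_gain is TriState.NOT_MET

    def test_crit3_disabled_drops_pattern_gate(self):
        cfg = CriteriaConfig(crit1_cutoff=7, crit3=False)
        series = MeasurementSeries(1, (None, None, 30, 20, None, None, None, None))
        ev = check_interval(series, 3, cfg)
        assert ev.is_gain is TriState.MET

    def test_pure_function(self, default_config):
        series = MeasurementSeries(1, (32, 30, 29, 28, 18, 17, 16, 12))
        assert check_interval(series, 4, default_config) \
            == check_interval(series, 4, default_config)

    @given(
        values=st.lists(
            st.one_of(st.none(), st.integers(0, 63)), min_size=6, max_size=10
        ),
        n_offset=st.integers(0, 8),
    )
    @settings(max_examples=200)
    def test_loss_direction_mirrors_gain_on_negated_series(self, values, n_offset):
        """crit1/crit3 verdicts for losses on x equal those for gains on -x
        (criterion 2 is scale-anchored and excluded from the symmetry)."""
        n = 1 + (n_offset % (len(values) - 1))
        gain_cfg = CriteriaConfig(crit1_cutoff=7, crit2=False, direction="gain")
        loss_cfg = CriteriaConfig(crit1_cutoff=7, crit2=False, direction="loss")
        neg = tuple(None if v is None else -v for v in values)
        ev_gain = check_interval(MeasurementSeries(1, neg), n, gain_cfg)
        ev_loss = check_interval(MeasurementSeries(1, tuple(values)), n, loss_cfg)
        assert ev_gain.crit1 is ev_loss.crit1
        assert ev_gain.crit3 is ev_loss.crit3
        assert ev_gain.is_gain is ev_loss.is_gain
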