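"""Transition counting, the frequency statistic, and the dual-threshold rule."""

import numpy as np
import pytest

from farrowwatch import (
    PostureTimeline,
    WarningConfig,
    count_transitions,
    evaluate_warnings,
    frequency_series,
    transition_frequency,
    warning_error,
)
from farrowwatch.warning import FrequencySeries

from conftest import LL, SD, SI, ST

HOUR = 3600.0

STRICT = WarningConfig(hysteresis=0.0, grace_hours=0.0)


def tl(labels, dt=60.0):
    return PostureTimeline.from_pairs([(i * dt, l) for i, l in enumerate(labels)])


class TestCountTransitions:
    def test_constant_labels_give_zero(self):
        assert count_transitions(tl([LL] * 6), 0, 1e9) == 0

    def test_hand_counted_changes(self):
        assert count_transitions(tl([LL, LL, ST, SI, SI, LL]), 0, 1e9) == 3

    def test_missing_samples_bridge_gaps(self):
        assert count_transitions(tl([LL, None, ST]), 0, 1e9) == 1
        assert count_transitions(tl([LL, None, LL]), 0, 1e9) == 0

    def test_window_is_half_open(self):
        t = tl([LL, ST, SD], dt=60.0)  # changes at t=60 and t=120
        assert count_transitions(t, 0, 121) == 2
        assert count_transitions(t, 0, 120) == 1  # pair ending at 120 excluded
        with pytest.raises(ValueError):
            count_transitions(t, 10, 10)


class TestTransitionFrequency:
    @pytest.mark.parametrize("n,t,f", [(0, 1, 0.0), (35, 2, 17.5), (12, 0.5, 24.0)])
    def test_frequency_is_count_over_hours(self, n, t, f):
        assert transition_frequency(n, t) == pytest.approx(f)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            transition_frequency(3, 0)


class TestFrequencySeries:
    def test_constant_timeline_is_all_zero(self):
        series = frequency_series(tl([LL] * 200))
        assert len(series) > 0
        assert np.all(series.f == 0)

    def test_changes_inside_one_window_are_counted(self):
        # 3 changes in the first hour of a 2 h timeline, constant afterwards
        labels = [LL] * 20 + [ST] * 11 + [SD] + [SI] * 88
        series = frequency_series(tl(labels, dt=60.0))
        assert series.f[0] == 3.0

    def test_short_timeline_yields_empty_series(self):
        series = frequency_series(tl([LL, ST], dt=60.0))
        assert len(series) == 0

    def test_matches_per_window_recount_exactly(self, make_random_timeline):
        cfg = WarningConfig()
        for _ in range(100):
            timeline = make_random_timeline()
            series = frequency_series(timeline, cfg)
            for t_end, f in zip(series.t_end, series.f):
                n = count_transitions(timeline, t_end - cfg.window_hours * HOUR, t_end)
                assert f == transition_frequency(n, cfg.window_hours)


def series_from_hours(f_by_hour, step=0.25, start=1.0):
    t = np.arange(start, start + step * len(f_by_hour), step)[: len(f_by_hour)]
    return FrequencySeries(1.0, t * HOUR, np.asarray(f_by_hour, dtype=float))


def flat(value, hours, step=0.25):
    return [value] * int(hours / step)


class TestEvaluateWarnings:
    def test_midband_series_fires_nothing(self):
        series = series_from_hours(flat(12.0, 40))
        assert evaluate_warnings(series) == []

    def test_sustained_excess_fires_after_persistence(self):
        # 12/h until t=10 h, 20/h afterwards: condition starts at 10 h and the
        # warning goes out once it has held for the 5 h persistence
        f = flat(12.0, 9.0) + flat(20.0, 21.0)
        series = series_from_hours(f, start=1.0)
        events = evaluate_warnings(series)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "upper"
        assert ev.condition_onset == pytest.approx(10.0 * HOUR)
        assert ev.emitted_at == pytest.approx(15.0 * HOUR)
        assert ev.emitted_at - ev.condition_onset == pytest.approx(5.0 * HOUR)

    def test_three_hour_excess_is_not_enough(self):
        f = flat(12.0, 5) + flat(20.0, 3) + flat(12.0, 20)
        assert evaluate_warnings(series_from_hours(f)) == []

    def test_single_point_dip_does_not_cancel_an_episode(self):
        # one window estimate inside the hysteresis band does not reset
        f = flat(12.0, 4) + flat(20.0, 3) + [16.0] + flat(20.0, 10)
        events = evaluate_warnings(series_from_hours(f, start=1.0))
        assert len(events) == 1
        assert events[0].condition_onset == pytest.approx(5.0 * HOUR)

    def test_long_contrary_dip_resets_the_episode(self):
        # 3 h above, 2 h clearly below, 4 h above: neither stretch reaches 5 h
        f = flat(12.0, 3) + flat(20.0, 3) + flat(10.0, 2) + flat(20.0, 4) + flat(12.0, 10)
        assert evaluate_warnings(series_from_hours(f)) == []

    def test_magnitude_cannot_buy_persistence(self):
        # a huge 3 h burst fails the span requirement even though its
        # trailing 5 h mean would clear the threshold
        f = flat(8.0, 5) + flat(40.0, 3) + flat(8.0, 20)
        assert evaluate_warnings(series_from_hours(f)) == []

    def test_lower_warning_only_after_upper(self):
        quiet = flat(2.0, 30)  # rests below the lower threshold the whole time
        assert evaluate_warnings(series_from_hours(quiet)) == []
        # full perinatal shape: calm, surge, collapse -> upper then lower
        f = flat(12.0, 4) + flat(20.0, 8) + flat(2.0, 12)
        events = evaluate_warnings(series_from_hours(f, start=1.0))
        kinds = [e.kind for e in events]
        assert kinds == ["upper", "lower"]
        assert events[1].emitted_at > events[0].emitted_at

    def test_strict_mode_resets_on_any_subthreshold_point(self):
        base = flat(20.0, 4.75) + [12.0] + flat(20.0, 4.75) + flat(12.0, 10)
        assert evaluate_warnings(series_from_hours(base), STRICT) == []
        ok = flat(12.0, 2) + flat(20.0, 5.25) + flat(12.0, 10)
        events = evaluate_warnings(series_from_hours(ok, start=1.0), STRICT)
        assert len(events) == 1 and events[0].kind == "upper"

    def test_strict_boundary_run_lengths(self):
        # a run spanning exactly the persistence fires; one step shorter does not
        just_under = flat(12.0, 2) + flat(20.0, 5.0) + flat(12.0, 10)
        # 5.0 h of points spans 4.75 h between first and last -> no event
        assert evaluate_warnings(series_from_hours(just_under), STRICT) == []
        at_boundary = flat(12.0, 2) + flat(20.0, 5.0) + [20.0] + flat(12.0, 10)
        events = evaluate_warnings(series_from_hours(at_boundary), STRICT)
        assert len(events) == 1

    def test_increasing_persistence_never_adds_events(self, rng):
        # provable for the strict every-point reading: a run sustaining the
        # longer persistence also sustains the shorter one
        short = WarningConfig(persistence_hours=3.0, hysteresis=0.0, grace_hours=0.0)
        long = WarningConfig(persistence_hours=6.0, hysteresis=0.0, grace_hours=0.0)
        for _ in range(25):
            f = rng.choice([5.0, 12.0, 16.0, 19.0, 22.0], size=160)
            series = series_from_hours(list(f))
            n_short = len(evaluate_warnings(series, short))
            n_long = len(evaluate_warnings(series, long))
            assert n_long <= n_short

    def test_empty_series_fires_nothing(self):
        assert evaluate_warnings(FrequencySeries(1.0, np.empty(0), np.empty(0))) == []


class TestWarningError:
    def test_exact_target_lead_has_zero_error(self):
        a = warning_error(emitted_at=0.0, true_farrow_onset=5 * HOUR)
        assert a.error_hours == pytest.approx(0.0)
        assert a.lead_hours == pytest.approx(5.0)
        assert not a.late

    def test_early_warning_error_is_excess_lead(self):
        a = warning_error(emitted_at=0.0, true_farrow_onset=6.5 * HOUR)
        assert a.error_hours == pytest.approx(1.5)

    def test_late_warning_is_flagged(self):
        a = warning_error(emitted_at=10 * HOUR, true_farrow_onset=9 * HOUR)
        assert a.lead_hours == pytest.approx(-1.0)
        assert a.error_hours == pytest.approx(6.0)
        assert a.late


def test_config_validation():
    with pytest.raises(ValueError):
        WarningConfig(upper_threshold=5.0, lower_threshold=10.0)
    with pytest.raises(ValueError):
        WarningConfig(persistence_hours=0)
    with pytest.raises(ValueError):
        WarningConfig(grace_hours=6.0)  # must stay below persistence
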