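import numpy as np
import pytest

from nemasleep import synthetic
from nemasleep.stimulus import (StimulusTrial, acceleration, classify_trial,
                                percent_change, response_summary,
                                round_half_up_pct, tally)


def _trial(sleep_pre_frac=0.0, pre_s=210.0, stim_s=180.0, post_s=60.0,
           dt=0.5, baseline_s=None, v=None, mixed_pattern=None):
    """Hand-built trial; sleep_pre_frac sets the asleep share of the
    classification pre-window (contiguous block at the end unless a
    pattern is given)."""
    pre = baseline_s if baseline_s is not None else pre_s
    n_pre = int(pre / dt)
    n = n_pre + int((stim_s + post_s) / dt)
    t = np.arange(n) * dt
    sleep = np.zeros(n, bool)
    if mixed_pattern is not None:
        sleep[:n_pre] = mixed_pattern
    elif sleep_pre_frac > 0:
        k = int(round(sleep_pre_frac * n_pre))
        sleep[n_pre - k:n_pre] = True
    return StimulusTrial(
        worm_id="w0", trial_id=0, condition="ATR+", t=t,
        v=np.zeros(n) if v is None else v, dff=np.zeros(n), sleep=sleep,
        stim_onset_s=pre, stim_end_s=pre + stim_s, dt=dt)


class TestClassifyTrial:
    def test_fully_awake_pre_window_is_wake(self):
        assert classify_trial(_trial(0.0), "responsiveness") == "wake"

    def test_fully_asleep_pre_window_is_sleep(self):
        assert classify_trial(_trial(1.0), "responsiveness") == "sleep"

    def test_mixed_pre_window_excluded(self):
        assert classify_trial(_trial(0.6), "responsiveness") == "excluded"

    def test_short_pre_window_excluded(self):
        tr = _trial(0.0, pre_s=100.0)
        assert classify_trial(tr, "responsiveness") == "excluded"

    def test_reversibility_sleep_takes_precedence(self):
        # asleep 96% of the final 3.5 min AND only 22% of the 15-min
        # baseline: the sleep criterion wins
        dt = 0.5
        n_base = int(900.0 / dt)
        pattern = np.zeros(n_base, bool)
        n_pre = int(210.0 / dt)
        k_sleep = int(round(0.96 * n_pre))
        pattern[n_base - k_sleep:] = True
        assert pattern.mean() < 0.25
        tr = _trial(baseline_s=900.0, mixed_pattern=pattern)
        assert classify_trial(tr, "reversibility") == "sleep"

    def test_reversibility_low_baseline_sleep_is_wake(self):
        tr = _trial(0.0, baseline_s=900.0)
        assert classify_trial(tr, "reversibility") == "wake"

    def test_reversibility_intermediate_excluded(self):
        # 50% asleep everywhere: fails both criteria
        dt = 0.5
        n_base = int(900.0 / dt)
        pattern = np.arange(n_base) % 2 == 0
        tr = _trial(baseline_s=900.0, mixed_pattern=pattern)
        assert classify_trial(tr, "reversibility") == "excluded"


class TestTally:
    @pytest.mark.parametrize("counts,expect", [
        ((446, 98, 56), (74.3, 16.3, 9.3)),     # 600 blue-light trials
        ((70, 19, 36), (56.0, 15.2, 28.8)),     # 125 ATR+ trials
        ((101, 42, 24), (60.5, 25.1, 14.4)),    # 167 ATR+ trials
        ((69, 85, 143), (23.2, 28.6, 48.1)),    # 297 ATR- trials
        ((350, 186, 326), (40.6, 21.6, 37.8)),  # 862 pooled trials
        ((80, 38, 62), (44.4, 21.1, 34.4)),     # 180 stimulated trials
        ((32, 71, 28), (24.4, 54.2, 21.4)),     # 131 unstimulated trials
    ])
    def test_printed_bookkeeping_reproduced(self, counts, expect):
        nw, ns, ne = counts
        labels = ["wake"] * nw + ["sleep"] * ns + ["excluded"] * ne
        t = tally(labels)
        assert (t.pct_wake, t.pct_sleep, t.pct_excluded) == expect

    def test_all_wake(self):
        t = tally(["wake"] * 7)
        assert (t.pct_wake, t.pct_sleep, t.pct_excluded) == (100.0, 0.0, 0.0)

    def test_percentages_rederive_counts(self):
        t = tally(["wake"] * 446 + ["sleep"] * 98 + ["excluded"] * 56)
        for pct, count in [(t.pct_wake, 446), (t.pct_sleep, 98),
                           (t.pct_excluded, 56)]:
            assert round(t.n_total * pct / 100) == count

    def test_round_half_up(self):
        assert round_half_up_pct(1, 8) == 12.5
        assert round_half_up_pct(25, 200) == 12.5
        assert round_half_up_pct(1, 16) == 6.3  # 6.25 rounds up

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tally([])


class TestAcceleration:
    def test_exact_ramp(self):
        dt = 0.5
        n = int(450.0 / dt)
        t = np.arange(n) * dt
        v = np.where(t >= 210.0, 0.22 * (t - 210.0), 0.0)
        tr = _trial(0.0, v=v)
        assert acceleration(tr) == pytest.approx(0.22, abs=1e-9)

    def test_constant_speed_zero_slope(self):
        tr = _trial(0.0, v=np.full(int(450.0 / 0.5), 3.0))
        assert acceleration(tr) == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        dt = 0.5
        n = int(450.0 / dt)
        t = np.arange(n) * dt
        v = 0.1 * t + rng.normal(0, 0.3, n)
        tr = _trial(0.0, v=v)
        mask = (t >= 210.0) & (t < 270.0)
        tt, vv = t[mask], v[mask]
        slope = (np.sum((tt - tt.mean()) * (vv - vv.mean()))
                 / np.sum((tt - tt.mean()) ** 2))
        assert acceleration(tr) == pytest.approx(slope, abs=1e-10)

    def test_shift_invariance(self, rng):
        dt = 0.5
        n = int(450.0 / dt)
        v = rng.normal(2.0, 0.5, n)
        a1 = acceleration(_trial(0.0, v=v))
        a2 = acceleration(_trial(0.0, v=v + 5.0))
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestPercentChange:
    def test_halving(self):
        t = np.arange(20.0)
        trace = np.where(t < 10, 10.0, 5.0)
        assert percent_change(trace, t, (0, 10), (10, 20)) == pytest.approx(-50.0)

    def test_equal_means_zero(self, rng):
        t = np.arange(40.0)
        trace = np.concatenate([rng.permutation(np.arange(20.0))] * 2)
        assert percent_change(trace, t, (0, 20), (20, 40)) == pytest.approx(0.0)

    def test_zero_baseline_flagged(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError, match="zero baseline"):
            percent_change(np.zeros(10), t, (0, 5), (5, 10))


class TestResponseSummary:
    def test_sleep_wake_acceleration_recovered(self):
        trials = synthetic.simulate_stim_trials(
            12, 8, mode="responsiveness", wake_accel=0.02,
            sleep_accel=0.005, seed=13)
        rs = response_summary(trials, "responsiveness")
        assert rs.effects["wake"].mean == pytest.approx(0.02, abs=0.005)
        assert rs.effects["sleep"].mean == pytest.approx(0.005, abs=0.005)
        assert rs.test is not None and rs.test.p < 0.01

    def test_identical_conditions_null(self):
        a = synthetic.simulate_stim_trials(8, 4, mode="reversibility",
                                           condition="ATR+", seed=20)
        b = synthetic.simulate_stim_trials(8, 4, mode="reversibility",
                                           condition="ATR-", seed=21)
        rs = response_summary(a + b, "reversibility")
        diff = rs.effects["ATR+"].mean - rs.effects["ATR-"].mean
        assert abs(diff) < 0.1
        assert rs.test.p > 0.05

    def test_condition_effect_recovered(self):
        a = synthetic.simulate_stim_trials(20, 4, mode="reversibility",
                                           condition="ATR+",
                                           post_effect=1.0, seed=22)
        b = synthetic.simulate_stim_trials(20, 4, mode="reversibility",
                                           condition="ATR-", seed=23)
        rs = response_summary(a + b, "reversibility")
        diff = rs.effects["ATR+"].mean - rs.effects["ATR-"].mean
        assert diff == pytest.approx(1.0, abs=0.15)
        assert rs.test.p < 0.01

    def test_single_trial_per_worm_mean_is_that_trial(self):
        trials = synthetic.simulate_stim_trials(
            5, 1, mode="reversibility", seed=30)
        rs = response_summary(trials, "reversibility")
        from nemasleep.stimulus import REV_POST_S, classify_trial
        for tr in trials:
            if classify_trial(tr, "reversibility") == "excluded":
                continue
            mask = (tr.t >= tr.stim_end_s) & (tr.t < tr.stim_end_s + REV_POST_S)
            expected = tr.v[mask].mean()
            got = rs.per_worm.loc[rs.per_worm.worm_id == tr.worm_id,
                                  "value"].iloc[0]
            assert got == pytest.approx(expected)

    def test_classification_deterministic_and_order_free(self):
        trials = synthetic.simulate_stim_trials(6, 6, seed=31)
        labels1 = [classify_trial(t, "responsiveness") for t in trials]
        labels2 = [classify_trial(t, "responsiveness")
                   for t in reversed(trials)][::-1]
        assert labels1 == labels2
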