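import numpy as np
import pandas as pd
import pytest

import breathtrack as bt
from breathtrack.exceptions import DegenerateSignalError, InvalidArgumentError
from breathtrack.tracking import phase_align, score_trial, tracking_error
from breathtrack.waveforms import Waveform, keypress_to_waveform


def _regular_events(f, dur, lag_s=0.0, jitter_sd=0.0, rng=None):
    """Alternating button events on a breath-like grid: trough 1, peak 2."""
    rows, k = [], 0
    while k / f < dur:
        rows.append((k / f, 1))
        if k / f + 0.5 / f < dur:
            rows.append((k / f + 0.5 / f, 2))
        k += 1
    ev = pd.DataFrame(rows, columns=["time_s", "button"])
    ev["time_s"] += lag_s
    if jitter_sd > 0:
        ev["time_s"] += rng.normal(0, jitter_sd, len(ev))
    ev = ev[(ev.time_s >= 0) & (ev.time_s < dur)].sort_values("time_s")
    return ev


class TestPhaseAlign:
    def test_self_alignment_is_zero_lag(self):
        w = bt.circle_waveform(5.0, duration=30.0)
        aln = phase_align(w, w, 500)
        assert aln.lag_samples == 0
        assert aln.ncc_max == pytest.approx(1.0)

    def test_shifted_copy_recovers_shift(self):
        ev = _regular_events(0.2, 30.0)
        stim = keypress_to_waveform(ev, 30.0)
        ev2 = ev.copy()
        ev2["time_s"] += 150 / 500.0
        key = keypress_to_waveform(ev2[ev2.time_s < 30.0], 30.0)
        aln = phase_align(stim, key, 500)
        assert aln.lag_samples == 150
        assert aln.ncc_max == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("lag_ms", [-400, -120, 0, 150, 400])
    def test_lag_recovery_with_jitter(self, lag_ms):
        rng = np.random.default_rng(17)
        ev = _regular_events(0.21, 30.0)
        stim = keypress_to_waveform(ev, 30.0)
        ev2 = _regular_events(0.21, 30.0, lag_s=lag_ms / 1000, jitter_sd=0.030, rng=rng)
        key = keypress_to_waveform(ev2, 30.0)
        aln = phase_align(stim, key, 500)
        assert abs(aln.lag_samples - lag_ms / 2) <= 15

    def test_brute_force_oracle_agreement(self):
        """The chosen lag maximizes a directly computed overlap correlation."""
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.normal(size=4000))
        y = np.roll(x, 37) + rng.normal(0, 0.1, 4000)
        wx, wy = Waveform(x, rate=500), Waveform(y, rate=500)
        aln = phase_align(wx, wy, 100)

        def pearson(lag):
            if lag >= 0:
                a, b = x[: len(x) - lag], y[lag:]
            else:
                a, b = x[-lag:], y[: len(x) + lag]
            return np.corrcoef(a, b)[0, 1]

        brute = max(range(-100, 101), key=lambda L: pearson(L))
        assert aln.lag_samples == brute == 37

    def test_antisymmetric_on_tie_free_inputs(self):
        rng = np.random.default_rng(8)
        x = np.cumsum(rng.normal(size=3000))
        y = np.roll(x, -52)
        wx, wy = Waveform(x, rate=500), Waveform(y, rate=500)
        assert phase_align(wx, wy, 200).lag_samples == -phase_align(wy, wx, 200).lag_samples

    def test_zero_variance_rejected(self):
        flat = Waveform(np.zeros(3000), rate=500)
        wavy = Waveform(np.sin(np.arange(3000) / 50), rate=500)
        with pytest.raises(DegenerateSignalError):
            phase_align(flat, wavy, 100)


class TestTrackingError:
    def test_exact_presses_give_zero_error(self):
        t = np.arange(10, dtype=float)
        assert tracking_error(t, t) == 0.0

    def test_constant_offset_absorbed_by_alignment(self):
        """End to end: a 120 ms transduction lag leaves ~zero residual error."""
        ev = _regular_events(0.2, 30.0)
        ev2 = ev.copy()
        ev2["time_s"] += 0.120
        ev2 = ev2[ev2.time_s < 30.0]
        res = score_trial(ev, ev2, onset_s=0.0, duration_s=30.0, rate=500.0)
        assert res["mean_abs_error_ms"] < 2.0
        assert res["lag_samples"] == 60

    def test_folded_normal_calibration(self):
        """Gaussian jitter sigma yields mean |error| ~ sigma*sqrt(2/pi)."""
        rng = np.random.default_rng(23)
        sigma = 0.100
        infl = np.arange(200, dtype=float) * 3.0
        press = infl + rng.normal(0, sigma, len(infl))
        got = tracking_error(infl, np.sort(press))
        expected = sigma * 1000 * np.sqrt(2 / np.pi)
        assert abs(got - expected) <= 10.0

    def test_empty_press_list_is_unscorable(self):
        with pytest.raises(InvalidArgumentError):
            tracking_error([1.0, 2.0], [])

    def test_error_monotone_in_jitter(self):
        means = []
        for sigma in [0.0, 0.030, 0.060, 0.120]:
            rng = np.random.default_rng(99)
            infl = np.arange(300, dtype=float) * 2.5
            press = np.sort(infl + rng.normal(0, sigma, len(infl)))
            means.append(tracking_error(infl, press))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))


class TestScoreSession:
    def test_row_bookkeeping_actmatch_scores_both_targets(self, default_session):
        log, trace, _ = default_session
        res = bt.score_session(log, trace)
        per = res.groupby(["condition", "target"]).size()
        assert per[("ActInt", "breath")] == 4
        assert per[("ActExt", "circle")] == 4
        assert per[("ActMatch", "breath")] == 4
        assert per[("ActMatch", "circle")] == 4
        assert len(res) == 16

    def test_perfect_agent_near_zero_error_on_unpaced_targets(self, perfect_session):
        log, trace, _ = perfect_session
        res = bt.score_session(log, trace)
        by = res.groupby(["condition", "target"]).mean_abs_error_ms.mean()
        # analytic circle schedules align exactly; breath extrema carry
        # sub-sample detection error plus boundary-breath asymmetry
        assert by[("ActExt", "circle")] < 2.0
        assert by[("ActMatch", "circle")] < 2.0
        assert by[("ActInt", "breath")] < 15.0
        # paced breathing carries one entrainment breath per block
        assert by[("ActMatch", "breath")] < 150.0
        assert res.scorable.all()

    def test_recovered_lag_matches_agent_transduction_lag(self, perfect_session):
        log, trace, _ = perfect_session
        res = bt.score_session(log, trace)
        unpaced = res[~((res.condition == "ActMatch") & (res.target == "breath"))]
        assert np.allclose(unpaced.lag_ms, 200.0, atol=6.0)

    def test_no_active_trials_rejected(self, default_session):
        log, trace, _ = default_session
        passive = bt.SessionLog(
            trials=log.trials[log.trials.condition.isin(["PasExt", "PasInt"])],
            events=log.events.iloc[0:0],
        )
        with pytest.raises(InvalidArgumentError):
            bt.score_session(passive, trace)

    def test_missing_presses_flagged_not_dropped(self, default_session):
        log, trace, _ = default_session
        empty = bt.SessionLog(trials=log.trials, events=log.events.iloc[0:0])
        res = bt.score_session(empty, trace)
        assert len(res) == 16
        assert (~res.scorable).all()
        assert res.mean_abs_error_ms.isna().all()
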