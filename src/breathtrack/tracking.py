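"""Phase alignment and tracking-accuracy scoring.

Button presses transduce the perceived stimulus with a systematic lag
(motor + hardware), so the stimulus waveform is first phase-corrected to
maximally align with the keypress waveform via normalized cross-correlation
(NCC): Pearson correlation at every integer lag up to ±1 s (±500 samples at
500 Hz), each lag normalized on its own overlap and restricted to the
interior (anchor-constrained) support of both waveforms, so that clamped
extrapolation at trial edges cannot bias the lag estimate.  Tracking
accuracy is then the mean absolute deviation, in milliseconds, from each
phase-corrected stimulus inflection point to the nearest keypress — lower
is better.

For scoring, the stimulus is represented in the same ±1 anchor coding as
the keypress waveform (−1 at inhalation/expansion onsets, +1 at
exhalation/contraction onsets, linear in between): aligning like-coded
waveforms makes the lag estimator unbiased, which a raw belt trace or the
pausing circle-radius trace against a keypress triangle is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateSignalError, InvalidArgumentError
from .respsignal import (
    TRACKING_PRESET,
    RespirationTrace,
    detect_extrema,
    smooth_and_center,
    zscore,
)
from .synth import SessionLog
from .waveforms import circle_inflections, keypress_to_waveform, Waveform

MAX_LAG_SAMPLES = 500  # one second at the 500 Hz belt rate
MIN_OVERLAP = 16  # fewest jointly valid samples for a lag to be considered


@dataclass(frozen=True)
class Alignment:
    lag_samples: int
    ncc_max: float
    shifted_stimulus: Waveform


def _pearson_at_lags(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int,
    valid_x: np.ndarray | None = None,
    valid_y: np.ndarray | None = None,
) -> np.ndarray:
    """Pearson correlation of overlapping segments at lags −max_lag..+max_lag.

    Positive lag means ``y`` trails ``x`` (the response is delayed relative
    to the stimulus).  Samples flagged invalid in either series are dropped
    from that lag's overlap before normalizing.
    """
    n = len(x)
    if valid_x is None:
        valid_x = np.ones(n, dtype=bool)
    if valid_y is None:
        valid_y = np.ones(n, dtype=bool)
    out = np.full(2 * max_lag + 1, -np.inf)
    for i, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            xs, ys = x[: n - lag], y[lag:]
            m = valid_x[: n - lag] & valid_y[lag:]
        else:
            xs, ys = x[-lag:], y[: n + lag]
            m = valid_x[-lag:] & valid_y[: n + lag]
        if m.sum() < MIN_OVERLAP:
            continue
        xs, ys = xs[m], ys[m]
        sx, sy = xs.std(), ys.std()
        if sx == 0 or sy == 0:
            continue
        out[i] = ((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sy)
    return out


def phase_align(
    stimulus: Waveform, keypress: Waveform, max_lag_samples: int = MAX_LAG_SAMPLES
) -> Alignment:
    """Find the integer lag maximizing the NCC and shift the stimulus by it.

    Ties (within 1e-12) break toward the smallest ``|lag|``.  The shifted
    stimulus is the input delayed by ``lag`` samples with edge samples held
    (and excluded from its interior support), so that its features line up
    with the keypress waveform.
    """
    if stimulus.n_samples != keypress.n_samples or stimulus.rate != keypress.rate:
        raise InvalidArgumentError("stimulus and keypress waveforms must share length and rate")
    if stimulus.n_samples <= 2 * max_lag_samples:
        raise InvalidArgumentError("waveform too short for the requested lag range")
    x, y = stimulus.values, keypress.values
    if x.std() == 0 or y.std() == 0:
        raise DegenerateSignalError("zero-variance waveform cannot be phase-aligned")

    ncc = _pearson_at_lags(x, y, max_lag_samples, stimulus.valid_mask, keypress.valid_mask)
    if not np.isfinite(ncc).any():
        raise DegenerateSignalError("no lag with sufficient valid overlap")
    lags = np.arange(-max_lag_samples, max_lag_samples + 1)
    best = ncc.max()
    candidates = lags[ncc >= best - 1e-12]
    lag = int(candidates[np.argmin(np.abs(candidates))])

    shifted = np.empty_like(x)
    if lag > 0:
        shifted[lag:] = x[:-lag]
        shifted[:lag] = x[0]
    elif lag < 0:
        shifted[:lag] = x[-lag:]
        shifted[lag:] = x[-1]
    else:
        shifted[:] = x
    if stimulus.interior is not None:
        lo, hi = stimulus.interior
        interior = (lo + lag, hi + lag)
    else:
        interior = (max(0, lag), stimulus.n_samples + min(0, lag))
    return Alignment(
        lag_samples=lag,
        ncc_max=float(best),
        shifted_stimulus=Waveform(
            shifted, rate=stimulus.rate, origin=stimulus.origin, t0=stimulus.t0, interior=interior
        ),
    )


def tracking_error(stimulus_inflections_s, keypress_times_s) -> float:
    """Mean absolute deviation (ms) from each inflection to the nearest keypress.

    Inflection times must already be phase-corrected.  Any button counts as
    a response; inflections without a nearby press contribute their distance
    to the nearest available press (no cap).
    """
    infl = np.sort(np.asarray(stimulus_inflections_s, dtype=float))
    press = np.sort(np.asarray(keypress_times_s, dtype=float))
    if infl.size == 0:
        raise InvalidArgumentError("no stimulus inflections to score")
    if press.size == 0:
        raise InvalidArgumentError("no keypresses: trial is unscorable")
    pos = np.searchsorted(press, infl)
    left = press[np.clip(pos - 1, 0, press.size - 1)]
    right = press[np.clip(pos, 0, press.size - 1)]
    dist = np.minimum(np.abs(infl - left), np.abs(infl - right))
    return float(dist.mean() * 1000.0)


def _anchor_frame(times: np.ndarray, buttons: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"time_s": times, "button": buttons})


def _breath_anchors(trace: RespirationTrace, lo: float, hi: float) -> pd.DataFrame:
    """Breath inflections inside [lo, hi) as anchor events (trough→1, peak→2).

    Extrema are detected on the full run so trial-boundary truncation cannot
    distort edge extrema, then restricted to the trial window.
    """
    ext = detect_extrema(trace, **TRACKING_PRESET)
    t0, fs = trace.start_time, trace.sampling_rate
    times = np.concatenate([ext.trough_indices, ext.peak_indices]) / fs + t0
    buttons = np.concatenate(
        [np.ones(ext.n_troughs, dtype=int), np.full(ext.n_peaks, 2, dtype=int)]
    )
    order = np.argsort(times)
    times, buttons = times[order], buttons[order]
    keep = (times >= lo) & (times < hi)
    return _anchor_frame(times[keep] , buttons[keep])


def _circle_anchors(period_s: float, duration_s: float, t0: float) -> pd.DataFrame:
    sched = circle_inflections(period_s, duration_s, t0=t0)
    buttons = np.where(sched["kind"] == "expansion_onset", 1, 2)
    return _anchor_frame(sched["time_s"].to_numpy(), buttons)


def score_trial(
    anchors: pd.DataFrame,
    events: pd.DataFrame,
    onset_s: float,
    duration_s: float,
    rate: float,
    max_lag_samples: int = MAX_LAG_SAMPLES,
    strict_buttons: bool = False,
) -> dict:
    """Align one trial's stimulus anchors with its keypresses and score it.

    Both signals are rendered as ±1 anchor-coded waveforms at ``rate``;
    after phase correction, inflections whose corrected time leaves the
    trial window are edge samples and are dropped from scoring.
    """
    if len(anchors) == 0:
        raise InvalidArgumentError("no stimulus inflections in trial")
    if len(events) == 0:
        raise InvalidArgumentError("no keypresses: trial is unscorable")
    stim = keypress_to_waveform(anchors, duration_s, rate=rate, t0=onset_s)
    key = keypress_to_waveform(events, duration_s, rate=rate, t0=onset_s)
    max_lag = min(max_lag_samples, stim.n_samples // 2 - 1)
    aln = phase_align(stim, key, max_lag)
    shift_s = aln.lag_samples / rate
    lo, hi = onset_s, onset_s + duration_s

    def _score(infl_times, press_times):
        corrected = np.asarray(infl_times, dtype=float) + shift_s
        corrected = corrected[(corrected >= lo) & (corrected < hi)]
        if corrected.size == 0:
            raise InvalidArgumentError("all corrected inflections left the trial window")
        return tracking_error(corrected, press_times), corrected.size

    if strict_buttons:
        total, count = 0.0, 0
        for btn in (1, 2):
            it = anchors.loc[anchors["button"] == btn, "time_s"].to_numpy()
            pt = events.loc[events["button"] == btn, "time_s"].to_numpy()
            if it.size and pt.size:
                err, n = _score(it, pt)
                total += err * n
                count += n
        if count == 0:
            raise InvalidArgumentError("no matchable inflection/press pairs")
        err, n_infl = total / count, count
    else:
        err, n_infl = _score(anchors["time_s"].to_numpy(), events["time_s"].to_numpy())
    return dict(
        lag_samples=aln.lag_samples,
        lag_ms=shift_s * 1000.0,
        ncc_max=aln.ncc_max,
        mean_abs_error_ms=err,
        n_inflections=n_infl,
    )


def score_session(
    session: SessionLog,
    trace: RespirationTrace,
    max_lag_samples: int = MAX_LAG_SAMPLES,
    strict_buttons: bool = False,
) -> pd.DataFrame:
    """Score every active trial of a session against its tracking target(s).

    Targets per condition: breath for ActInt, circle for ActExt, and both
    for ActMatch (keypresses there must align with the circle and with the
    paced breath).  The belt trace is smoothed, mean-corrected, and z-scored
    once per run; breath inflections use the 1 s minimum-spacing detector
    preset, circle inflections come from the analytic stimulus schedule.
    Trials without usable keypresses are returned flagged, never dropped.

    ``strict_buttons`` restricts matching so button 1 only scores against
    inhalation/expansion onsets and button 2 against exhalation/contraction
    onsets (the default matches any button, the plain nearest-press rule).
    """
    active = session.trials[session.trials["condition"].isin(("ActInt", "ActExt", "ActMatch"))]
    if len(active) == 0:
        raise InvalidArgumentError("session contains no active trials")
    z = zscore(smooth_and_center(trace))
    rate = trace.sampling_rate
    rows = []
    for tr in active.itertuples(index=False):
        targets = {"ActInt": ["breath"], "ActExt": ["circle"], "ActMatch": ["breath", "circle"]}[
            tr.condition
        ]
        lo = tr.onset_s
        ev = session.events[
            (session.events["time_s"] >= lo) & (session.events["time_s"] < lo + tr.duration_s)
        ]
        for target in targets:
            row = dict(
                trial_id=f"{tr.condition}_b{tr.block}",
                participant=tr.participant,
                session=tr.session,
                block=tr.block,
                condition=tr.condition,
                target=target,
                lag_samples=np.nan,
                lag_ms=np.nan,
                ncc_max=np.nan,
                mean_abs_error_ms=np.nan,
                n_inflections=0,
                scorable=False,
            )
            try:
                if target == "breath":
                    anchors = _breath_anchors(z, lo, lo + tr.duration_s)
                else:
                    if not np.isfinite(tr.circle_period_s):
                        raise InvalidArgumentError("no circle stimulus in this trial")
                    anchors = _circle_anchors(tr.circle_period_s, tr.duration_s, lo)
                row.update(
                    score_trial(
                        anchors, ev, lo, tr.duration_s, rate, max_lag_samples, strict_buttons
                    ),
                    scorable=True,
                )
            except (InvalidArgumentError, DegenerateSignalError):
                pass
            rows.append(row)
    return pd.DataFrame(rows)
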