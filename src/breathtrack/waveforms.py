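"""Stimulus and behaviour waveform reconstruction.

Active task conditions produce three periodic timeseries on a shared 500 Hz
grid: the respiration belt amplitude, the visual circle radius phase, and a
waveform interpolated from button presses.  Button "1" (inhalation /
circle-expansion onset) is coded −1 (trough of the cycle) and button "2"
(exhalation / contraction onset) is coded +1 (peak), with linear
interpolation in between.

The circle stimulus follows a piecewise-linear kinematic rule: the radius
phase rises from −1 to +1 over half the participant's respiratory period,
pauses at +1 for 0.2× the expansion time, falls back to −1 at the same rate,
pauses again, and repeats.  One full cycle therefore lasts 1.2× the
respiratory period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .respsignal import RespirationTrace

DEFAULT_RATE = 500.0  # Hz, matches the respiration belt

#: Pause duration after each expansion/contraction, as a fraction of the
#: expansion (half-period) time.
CIRCLE_PAUSE_FRACTION = 0.2


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled unitless timeseries in [−1, 1] (circle/keypress).

    ``interior`` marks the sample range actually constrained by data
    (between the first and last interpolation anchor); samples outside it
    are clamped extrapolation and are excluded from phase alignment.
    """

    values: np.ndarray
    rate: float = DEFAULT_RATE
    origin: str = "keypress"  # one of {respiration, circle, keypress}
    t0: float = 0.0
    interior: tuple | None = None  # (first_valid_index, last_valid_index_exclusive)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.rate <= 0:
            raise InvalidArgumentError("rate must be positive")

    @property
    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        if self.interior is not None:
            lo, hi = self.interior
            mask[: max(0, lo)] = False
            mask[min(self.n_samples, hi) :] = False
        return mask

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate


@dataclass(frozen=True)
class TrialSegment:
    """A trial-window slice of a run-level trace or waveform."""

    condition: str
    onset_s: float
    duration_s: float
    data: object  # RespirationTrace or Waveform restricted to the window


def keypress_to_waveform(
    events: pd.DataFrame, duration: float, rate: float = DEFAULT_RATE, t0: float = 0.0
) -> Waveform:
    """Interpolate button-press events into a continuous ±1 waveform.

    ``events`` needs columns ``time_s`` and ``button`` (1 or 2).  Anchors are
    −1 at button-1 presses and +1 at button-2 presses; values between anchors
    are linear, and the waveform is held constant before the first and after
    the last press.
    """
    n = int(round(duration * rate))
    if len(events) == 0:
        warnings.warn("no keypress events; returning all-zero waveform", stacklevel=2)
        return Waveform(np.zeros(n), rate=rate, origin="keypress", t0=t0)

    ev = events.sort_values("time_s", kind="stable")
    bad = set(ev["button"].unique()) - {1, 2}
    if bad:
        raise InvalidArgumentError(f"unknown button codes: {sorted(bad)}")
    if ev["time_s"].duplicated().any():
        warnings.warn("duplicate keypress timestamps; keeping last", stacklevel=2)
        ev = ev.drop_duplicates("time_s", keep="last")
    t = ev["time_s"].to_numpy(dtype=float) - t0
    if t.min() < -1e-9 or t.max() > duration + 1e-9:
        raise InvalidArgumentError("keypress events outside [0, duration]")
    anchors = np.where(ev["button"].to_numpy() == 1, -1.0, 1.0)
    grid = np.arange(n) / rate
    values = np.interp(grid, t, anchors)  # np.interp clamps beyond end anchors
    interior = (int(np.ceil(t[0] * rate)), int(np.floor(t[-1] * rate)) + 1)
    return Waveform(values, rate=rate, origin="keypress", t0=t0, interior=interior)


def circle_cycle_s(period_s: float, include_pauses: bool = True) -> float:
    """Length of one full circle cycle for a given respiratory period."""
    if period_s <= 0:
        raise InvalidArgumentError("period_s must be positive")
    half = period_s / 2.0
    pause = CIRCLE_PAUSE_FRACTION * half if include_pauses else 0.0
    return 2 * (half + pause)


def circle_waveform(
    period_s: float,
    duration: float,
    rate: float = DEFAULT_RATE,
    t0: float = 0.0,
    include_pauses: bool = True,
) -> Waveform:
    """Piecewise-linear circle radius phase, starting at −1 (fully contracted).

    Segment schedule per cycle: rise −1→+1 over ``period_s/2``; hold at +1
    for ``0.2·period_s/2``; fall +1→−1 over ``period_s/2``; hold at −1 for
    ``0.2·period_s/2``.  ``include_pauses=False`` drops the holds, making the
    pulse period equal the respiratory period exactly.
    """
    if period_s <= 0:
        raise InvalidArgumentError("period_s must be positive")
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    half = period_s / 2.0
    pause = CIRCLE_PAUSE_FRACTION * half if include_pauses else 0.0
    cycle = 2 * (half + pause)
    n = int(round(duration * rate))
    phase = np.arange(n) / rate % cycle
    values = np.empty(n)
    rising = phase < half
    values[rising] = -1.0 + 2.0 * phase[rising] / half
    hold_hi = (phase >= half) & (phase < half + pause)
    values[hold_hi] = 1.0
    falling = (phase >= half + pause) & (phase < 2 * half + pause)
    values[falling] = 1.0 - 2.0 * (phase[falling] - half - pause) / half
    values[phase >= 2 * half + pause] = -1.0
    return Waveform(values, rate=rate, origin="circle", t0=t0)


def circle_inflections(
    period_s: float,
    duration: float,
    t0: float = 0.0,
    include_pauses: bool = True,
) -> pd.DataFrame:
    """Analytic schedule of circle phase changes within [t0, t0+duration).

    Returns a frame with ``time_s`` and ``kind`` ∈ {expansion_onset,
    contraction_onset} — the cues participants track (button 1 at expansion
    onset, button 2 at contraction onset).
    """
    half = period_s / 2.0
    pause = CIRCLE_PAUSE_FRACTION * half if include_pauses else 0.0
    cycle = 2 * (half + pause)
    rows = []
    k = 0
    while k * cycle < duration:
        t_rise = k * cycle
        t_fall = k * cycle + half + pause
        if t_rise < duration:
            rows.append((t0 + t_rise, "expansion_onset"))
        if t_fall < duration:
            rows.append((t0 + t_fall, "contraction_onset"))
        k += 1
    return pd.DataFrame(rows, columns=["time_s", "kind"])


def segment_trials(run, trials: pd.DataFrame) -> list[TrialSegment]:
    """Cut a run-level trace or waveform into per-trial segments.

    ``trials`` needs columns ``condition``, ``onset_s``, ``duration_s``.
    Windows must lie within the run and not overlap.
    """
    segments: list[TrialSegment] = []
    if len(trials) == 0:
        return segments
    ordered = trials.sort_values("onset_s")
    prev_end = -np.inf
    for _, tr in ordered.iterrows():
        onset, dur = float(tr["onset_s"]), float(tr["duration_s"])
        if onset < prev_end - 1e-9:
            raise InvalidArgumentError(f"trial at {onset} s overlaps the previous trial")
        prev_end = onset + dur
        if isinstance(run, RespirationTrace):
            data = run.slice_window(onset, dur)
        elif isinstance(run, Waveform):
            i0 = int(round((onset - run.t0) * run.rate))
            n = int(round(dur * run.rate))
            if i0 < 0 or i0 + n > run.n_samples:
                raise InvalidArgumentError(
                    f"trial '{tr['condition']}' at {onset} s extends beyond the run"
                )
            data = Waveform(run.values[i0 : i0 + n], rate=run.rate, origin=run.origin, t0=onset)
        else:
            raise InvalidArgumentError(f"cannot segment object of type {type(run).__name__}")
        segments.append(
            TrialSegment(condition=str(tr["condition"]), onset_s=onset, duration_s=dur, data=data)
        )
    return segments
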