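"""Synthetic respiration, stimulus, and keypress generation with ground truth.

Emulates a five-condition interoceptive/exteroceptive attention session:

- ``PasExt``  passive viewing of a pulsing circle (no responses),
- ``PasInt``  passive attention to the breath, stationary circle,
- ``ActExt``  button tracking of the circle's expansion/contraction,
- ``ActInt``  button tracking of the participant's own inhalation/exhalation,
- ``ActMatch`` button tracking of the circle while pacing the breath to it.

The belt signal is modelled as ``amplitude(t)·sin(phase(t)) + noise`` where
the phase integrates a per-breath random-walk instantaneous frequency and
the amplitude follows a slow per-breath random walk.  Condition blocks add
frequency/depth offsets (attention to the breath slows and deepens it).
Simulated button presses anchor to true signal inflections (inhalation
onset → button 1, exhalation onset → button 2; expansion onset → button 1,
contraction onset → button 2) with a constant transduction lag, Gaussian
jitter, and occasional misses, so every downstream stage has an exact
ground truth to recover.

A block-summary-level cohort generator (`simulate_summary_table`) produces
condition-block outcome tables directly for mixed-model studies where full
500 Hz signal synthesis would be wasteful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .respsignal import RespirationTrace
from .waveforms import circle_inflections

CONDITIONS = ("PasExt", "PasInt", "ActExt", "ActInt", "ActMatch")
ACTIVE_CONDITIONS = ("ActExt", "ActInt", "ActMatch")

FREQ_FLOOR_HZ = 0.05  # frequencies driven below this by drift are clipped

#: Default condition offsets, scaled to mirror the ordering seen in breath
#: attention tasks: interoceptive attention slows (≈−0.02 Hz) and deepens
#: breathing; exogenous pacing (ActMatch) deepens it less.
DEFAULT_FREQUENCY_OFFSETS = {"ActInt": -0.024, "PasInt": -0.015, "ActMatch": -0.002}
DEFAULT_AMPLITUDE_OFFSETS = {"ActInt": 0.40, "ActMatch": 0.29, "PasInt": 0.12}


@dataclass(frozen=True)
class BreathingProfile:
    """Generative parameters for the quasi-periodic belt signal.

    ``base_frequency`` defaults to 0.21 Hz, a typical adult resting rate.
    Drift SDs are random-walk innovations applied once per breath.
    """

    base_frequency: float = 0.21
    frequency_drift_sd: float = 0.005
    amplitude: float = 1.0
    amplitude_drift_sd: float = 0.02
    noise_sd: float = 0.05
    condition_frequency_offsets: dict = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCY_OFFSETS)
    )
    condition_amplitude_offsets: dict = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDE_OFFSETS)
    )

    def __post_init__(self):
        if not (0.05 < self.base_frequency < 1.0):
            raise InvalidArgumentError("base_frequency must lie in (0.05, 1.0) Hz")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        for c, off in self.condition_frequency_offsets.items():
            if self.base_frequency + off <= 0:
                raise InvalidArgumentError(f"offset for {c} drives frequency <= 0")


@dataclass(frozen=True)
class AgentProfile:
    """Response model for a simulated participant's button presses."""

    transduction_lag_ms: float = 200.0
    jitter_sd_ms: float = 50.0
    miss_rate: float = 0.02

    def __post_init__(self):
        if not (0 <= self.miss_rate < 1):
            raise InvalidArgumentError("miss_rate must be in [0, 1)")
        if self.jitter_sd_ms < 0:
            raise InvalidArgumentError("jitter_sd_ms must be >= 0")


@dataclass(frozen=True)
class SessionDesign:
    """Block structure of one scanning run."""

    blocks_per_condition: int = 4
    block_duration_s: float = 30.0
    conditions: tuple = CONDITIONS
    gap_s: float = 0.0
    shuffle: bool = True

    def __post_init__(self):
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise InvalidArgumentError(f"unknown condition labels: {sorted(unknown)}")
        if self.block_duration_s <= 10:
            raise InvalidArgumentError("block_duration_s must exceed 10 s")

    @property
    def run_duration_s(self) -> float:
        n = self.blocks_per_condition * len(self.conditions)
        return n * (self.block_duration_s + self.gap_s)


@dataclass(frozen=True)
class GroundTruth:
    """Exact generating-process quantities for a synthetic trace/session.

    ``breath_events``: frame with columns ``time_s`` and ``kind`` in
    {inhalation_onset, exhalation_onset}; inhalation onsets are signal
    troughs, exhalation onsets peaks.
    """

    breath_events: pd.DataFrame
    instantaneous_frequency: np.ndarray
    true_envelope_amplitude: np.ndarray
    true_lag_ms: float | None = None

    @property
    def n_breaths(self) -> int:
        return int((self.breath_events["kind"] == "inhalation_onset").sum())


@dataclass(frozen=True)
class SessionLog:
    """Trial table + keypress events for one run."""

    trials: pd.DataFrame  # participant, session, block, condition, onset_s, duration_s, circle_period_s
    events: pd.DataFrame  # time_s, button
    participant: str = "p01"
    session: int = 1


def _substream(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic per-(participant, session, ...) random substream."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *[int(k) for k in keys]]))


# ---------------------------------------------------------------------------
# respiration generation


def _condition_offsets_at(schedule, t, freq_offsets, amp_offsets):
    if schedule is None:
        return 0.0, 0.0
    for onset, dur, cond in schedule:
        if onset <= t < onset + dur:
            return freq_offsets.get(cond, 0.0), amp_offsets.get(cond, 0.0)
    return 0.0, 0.0


def _paced_block_at(pacing_schedule, t):
    if pacing_schedule is None:
        return None
    for onset, dur, cycle_s in pacing_schedule:
        if onset <= t < onset + dur:
            return onset, dur, cycle_s
    return None


def generate_respiration(
    profile: BreathingProfile,
    duration: float,
    rate: float = 500.0,
    seed: int = 0,
    condition_schedule=None,
    pacing_schedule=None,
    run_id: str = "synthetic",
) -> tuple[RespirationTrace, GroundTruth]:
    """Simulate a belt trace breath-by-breath.

    ``condition_schedule`` is an optional list of ``(onset_s, duration_s,
    condition)`` applying the profile's condition offsets to breaths starting
    inside each block.  ``pacing_schedule`` is an optional list of
    ``(onset_s, duration_s, cycle_s)`` blocks in which breathing entrains to
    an external pacing stimulus: after one phase-snapping entrainment breath,
    inhalation onsets lock to the pacing grid ``onset + k*cycle_s``.  The
    returned ground truth matches the generating process exactly: the event
    list holds the true inhalation (trough) and exhalation (peak) onsets,
    and the per-sample arrays hold the integrated instantaneous frequency
    and the noise-free envelope amplitude.
    """
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be positive")
    if duration <= 3.0 / profile.base_frequency:
        raise InvalidArgumentError("duration must cover at least three breath cycles")
    if rate < 50:
        raise InvalidArgumentError("sampling rate must be >= 50 Hz")

    rng = np.random.default_rng(seed)
    freq_offs = profile.condition_frequency_offsets
    amp_offs = profile.condition_amplitude_offsets

    # per-breath random walks
    breath_starts = [0.0]
    breath_freqs, breath_amps = [], []
    f_walk, a_walk = profile.base_frequency, profile.amplitude
    t = 0.0
    clipped = False
    while t < duration:
        _, a_off = _condition_offsets_at(condition_schedule, t, freq_offs, amp_offs)
        paced = _paced_block_at(pacing_schedule, t)
        if paced is not None:
            b_onset, _, cycle_s = paced
            # snap the next inhalation onset to the pacing grid
            k = np.ceil((t - b_onset) / cycle_s - 1e-9)
            next_inh = b_onset + k * cycle_s
            gap = next_inh - t
            if gap < 0.4 * cycle_s:  # too soon: entrain over one longer breath
                gap += cycle_s
            breath_dur = cycle_s if abs(gap - cycle_s) < 1e-9 else gap
            f_b = 1.0 / breath_dur
        else:
            f_off, _ = _condition_offsets_at(condition_schedule, t, freq_offs, amp_offs)
            f_b = f_walk + f_off
        if f_b < FREQ_FLOOR_HZ:
            f_b = FREQ_FLOOR_HZ
            clipped = True
        a_b = max(a_walk + a_off, 0.05)
        breath_freqs.append(f_b)
        breath_amps.append(a_b)
        t += 1.0 / f_b
        breath_starts.append(t)
        f_walk += rng.normal(0.0, profile.frequency_drift_sd)
        a_walk += rng.normal(0.0, profile.amplitude_drift_sd)
        a_walk = max(a_walk, 0.05)
    if clipped:
        warnings.warn(
            f"instantaneous frequency clipped at the {FREQ_FLOOR_HZ} Hz floor", stacklevel=2
        )

    breath_starts = np.asarray(breath_starts)
    breath_freqs = np.asarray(breath_freqs)
    breath_amps = np.asarray(breath_amps)

    n = int(round(duration * rate))
    times = np.arange(n) / rate
    b_idx = np.clip(np.searchsorted(breath_starts, times, side="right") - 1, 0, len(breath_freqs) - 1)
    inst_freq = breath_freqs[b_idx]
    # phase integrates exactly within each piecewise-constant-frequency breath
    phase = -np.pi / 2 + 2 * np.pi * (
        _cum_phase(breath_starts, breath_freqs)[b_idx] + (times - breath_starts[b_idx]) * inst_freq
    )
    envelope = np.interp(times, breath_starts[:-1], breath_amps)
    samples = envelope * np.sin(phase) + rng.normal(0.0, profile.noise_sd, size=n)

    events = []
    for t0, f_b in zip(breath_starts[:-1], breath_freqs):
        if t0 < duration:
            events.append((t0, "inhalation_onset"))
        t_peak = t0 + 0.5 / f_b
        if t_peak < duration:
            events.append((t_peak, "exhalation_onset"))
    gt = GroundTruth(
        breath_events=pd.DataFrame(events, columns=["time_s", "kind"]),
        instantaneous_frequency=inst_freq,
        true_envelope_amplitude=envelope,
    )
    trace = RespirationTrace(samples=samples, sampling_rate=rate, start_time=0.0, run_id=run_id)
    return trace, gt


def _cum_phase(breath_starts: np.ndarray, breath_freqs: np.ndarray) -> np.ndarray:
    """Cycles completed at the start of each breath (0, 1, 2, ... by design)."""
    durations = np.diff(breath_starts)
    return np.concatenate([[0.0], np.cumsum(durations * breath_freqs)])[: len(breath_freqs)]


# ---------------------------------------------------------------------------
# session generation


def _make_trial_table(design: SessionDesign, rng, participant, session) -> pd.DataFrame:
    labels = [c for c in design.conditions for _ in range(design.blocks_per_condition)]
    order = rng.permutation(len(labels)) if design.shuffle else np.arange(len(labels))
    rows = []
    t = 0.0
    block_counter = {c: 0 for c in design.conditions}
    for k in order:
        cond = labels[k]
        block_counter[cond] += 1
        rows.append(
            dict(
                participant=participant,
                session=session,
                block=block_counter[cond],
                condition=cond,
                onset_s=t,
                duration_s=design.block_duration_s,
            )
        )
        t += design.block_duration_s + design.gap_s
    return pd.DataFrame(rows)


def _presses_from_anchors(anchor_times, buttons, agent: AgentProfile, rng, lo, hi):
    rows = []
    for t_a, btn in zip(anchor_times, buttons):
        if rng.uniform() < agent.miss_rate:
            continue
        t_press = t_a + agent.transduction_lag_ms / 1000.0 + rng.normal(
            0.0, agent.jitter_sd_ms / 1000.0
        )
        if lo <= t_press < hi:
            rows.append((t_press, btn))
    return rows


def generate_session(
    breathing: BreathingProfile,
    agent: AgentProfile,
    design: SessionDesign = SessionDesign(),
    seed: int = 0,
    rate: float = 500.0,
    participant: str = "p01",
    session: int = 1,
) -> tuple[SessionLog, RespirationTrace, GroundTruth]:
    """Simulate one full run: trial table, belt trace, and keypress events.

    The circle period for circle-paced blocks equals the session's estimated
    breathing period (``1/base_frequency``), mirroring the calibration of
    the visual stimulus to each participant's in-scanner rate; the circle in
    ``PasInt`` is stationary (period NaN).  Keypresses exist only in Active
    conditions: in ``ActInt`` they anchor to the true breath inflections, in
    ``ActExt``/``ActMatch`` to the circle's expansion/contraction onsets,
    each with the agent's transduction lag, jitter, and miss rate.
    """
    from .waveforms import circle_cycle_s

    rng = _substream(seed, 0)
    trials = _make_trial_table(design, rng, participant, session)
    schedule = [
        (r.onset_s, r.duration_s, r.condition) for r in trials.itertuples(index=False)
    ]
    circle_period = 1.0 / breathing.base_frequency
    # breathing entrains to the circle in ActMatch blocks
    pacing = [
        (r.onset_s, r.duration_s, circle_cycle_s(circle_period))
        for r in trials.itertuples(index=False)
        if r.condition == "ActMatch"
    ]
    trace, gt = generate_respiration(
        breathing,
        duration=design.run_duration_s,
        rate=rate,
        seed=int(rng.integers(2**31 - 1)),
        condition_schedule=schedule,
        pacing_schedule=pacing,
        run_id=f"{participant}_ses-{session}",
    )
    trials["circle_period_s"] = [
        np.nan if c == "PasInt" else circle_period for c in trials["condition"]
    ]

    press_rows = []
    for tr in trials.itertuples(index=False):
        if tr.condition not in ACTIVE_CONDITIONS:
            continue
        lo, hi = tr.onset_s, tr.onset_s + tr.duration_s
        if tr.condition == "ActInt":
            # include events slightly before onset: their (lagged) presses can
            # still fall inside the block, as a participant's would
            ev = gt.breath_events
            in_block = ev[(ev["time_s"] >= lo - 2.0) & (ev["time_s"] < hi)]
            anchors = in_block["time_s"].to_numpy()
            buttons = np.where(in_block["kind"] == "inhalation_onset", 1, 2)
        else:  # circle-paced
            infl = circle_inflections(circle_period, tr.duration_s, t0=lo)
            anchors = infl["time_s"].to_numpy()
            buttons = np.where(infl["kind"] == "expansion_onset", 1, 2)
        press_rows.extend(_presses_from_anchors(anchors, buttons, agent, rng, lo, hi))

    events = pd.DataFrame(press_rows, columns=["time_s", "button"]).sort_values(
        "time_s", ignore_index=True
    )
    events["button"] = events["button"].astype(int) if len(events) else events["button"]
    gt = GroundTruth(
        breath_events=gt.breath_events,
        instantaneous_frequency=gt.instantaneous_frequency,
        true_envelope_amplitude=gt.true_envelope_amplitude,
        true_lag_ms=agent.transduction_lag_ms,
    )
    log = SessionLog(trials=trials, events=events, participant=participant, session=session)
    return log, trace, gt


# ---------------------------------------------------------------------------
# cohort-scale summary generator


def cohort_design(
    n_participants: int = 22,
    n_sessions: int = 2,
    blocks_per_condition: int = 4,
    conditions=CONDITIONS,
) -> pd.DataFrame:
    """Design skeleton: one row per (participant, session, condition, block).

    Participants are split into two intervention groups; session index
    doubles as assessment time (baseline / post), matching a two-group
    longitudinal design.  Default dimensions give 22 × 2 × 5 × 4 = 880 rows.
    """
    rows = [
        dict(
            participant=f"p{p:02d}",
            group="intervention" if p % 2 == 0 else "control",
            session=s + 1,
            time="baseline" if s == 0 else "post",
            condition=c,
            block=b + 1,
        )
        for p in range(n_participants)
        for s in range(n_sessions)
        for c in conditions
        for b in range(blocks_per_condition)
    ]
    return pd.DataFrame(rows)


def simulate_summary_table(
    n_participants: int = 22,
    n_sessions: int = 2,
    blocks_per_condition: int = 4,
    seed: int = 0,
    freq_base: float = 0.21,
    freq_participant_sd: float = 0.05,
    freq_residual_sd: float = 0.048,
    freq_condition_offsets: dict | None = None,
    rvt_base: float = 2.5,
    rvt_participant_sd: float = 0.15,
    rvt_residual_sd: float = 0.54,
    rvt_condition_offsets: dict | None = None,
    within_correlation: float = 0.0,
) -> pd.DataFrame:
    """Condition-block outcome table for mixed-model analysis.

    Each block's frequency and RVT are a participant random intercept plus a
    condition offset plus residual noise; ``within_correlation`` sets the
    correlation of the two residuals, emulating the rate/depth trade-off
    (faster breathing tends to be shallower).  Defaults follow the study
    conditions: 22 participants × 2 sessions × 5 conditions × 4 blocks = 880
    rows, interoception ≈0.02 Hz slower and markedly deeper.
    """
    if not (-1.0 < within_correlation < 1.0):
        raise InvalidArgumentError("within_correlation must be in (-1, 1)")
    if freq_condition_offsets is None:
        freq_condition_offsets = dict(DEFAULT_FREQUENCY_OFFSETS)
    if rvt_condition_offsets is None:
        # ordering PasExt ≈ ActExt < PasInt < ActMatch < ActInt
        rvt_condition_offsets = {"PasExt": 0.08, "PasInt": 0.29, "ActMatch": 0.71, "ActInt": 0.99}

    rng = np.random.default_rng(seed)
    table = cohort_design(n_participants, n_sessions, blocks_per_condition)
    n = len(table)
    participants = table["participant"].unique()
    f_int = dict(zip(participants, rng.normal(0.0, freq_participant_sd, len(participants))))
    r_int = dict(zip(participants, rng.normal(0.0, rvt_participant_sd, len(participants))))

    cov = np.array(
        [
            [freq_residual_sd**2, within_correlation * freq_residual_sd * rvt_residual_sd],
            [within_correlation * freq_residual_sd * rvt_residual_sd, rvt_residual_sd**2],
        ]
    )
    resid = rng.multivariate_normal([0.0, 0.0], cov, size=n)

    table["frequency_hz"] = (
        freq_base
        + table["participant"].map(f_int).to_numpy()
        + table["condition"].map(lambda c: freq_condition_offsets.get(c, 0.0)).to_numpy()
        + resid[:, 0]
    )
    table["rvt_au"] = (
        rvt_base
        + table["participant"].map(r_int).to_numpy()
        + table["condition"].map(lambda c: rvt_condition_offsets.get(c, 0.0)).to_numpy()
        + resid[:, 1]
    )
    return table
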