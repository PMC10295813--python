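"""Respiration-belt signal processing.

Implements the preprocessing and feature-extraction chain applied to
chest-belt amplitude recordings in breath-attention experiments:

1. zero-phase low-pass smoothing and mean correction,
2. per-run z-scoring,
3. peak/trough detection with amplitude-prominence and temporal-spacing
   constraints,
4. breathing-frequency estimation (whole-segment FFT argmax and a
   sliding-window variant producing one value per fMRI volume),
5. respiratory volume per time (RVT): the gap between the linearly
   interpolated peak envelope and trough envelope of the z-scored signal.

All amplitudes are in arbitrary belt units; frequency is in Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .exceptions import DegenerateSignalError, InvalidArgumentError

#: Physiological breathing band (Hz).  Spectral estimates are restricted to
#: this band; adult resting respiration sits near 0.2-0.3 Hz.
FREQ_BAND = (0.05, 1.0)

#: Detector presets: (prominence in z-units between adjacent peak/trough,
#: minimum separation in seconds between consecutive same-type extrema).
RVT_PRESET = {"prominence_sd": 0.5, "min_separation_s": 2.0}
#: For behavioural tracking the only constraint is that individual breaths
#: are unlikely to be shorter than 1 s, so peaks are spaced >= 1 s apart and
#: no amplitude-prominence pruning is applied.
TRACKING_PRESET = {"prominence_sd": 0.0, "min_separation_s": 1.0}


@dataclass(frozen=True)
class RespirationTrace:
    """Uniformly sampled belt amplitude series.

    Parameters
    ----------
    samples : array of amplitudes (arbitrary units).
    sampling_rate : Hz.
    start_time : s, onset of the first sample relative to the run clock.
    run_id : free-form label.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    run_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        if self.samples.ndim != 1:
            raise InvalidArgumentError("samples must be one-dimensional")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def slice_window(self, onset_s: float, duration_s: float) -> "RespirationTrace":
        """Extract the sub-trace covering [onset_s, onset_s + duration_s)."""
        i0 = int(round((onset_s - self.start_time) * self.sampling_rate))
        n = int(round(duration_s * self.sampling_rate))
        if i0 < 0 or i0 + n > self.n_samples:
            raise InvalidArgumentError(
                f"window [{onset_s}, {onset_s + duration_s}) s outside run extent "
                f"[{self.start_time}, {self.start_time + self.duration}) s"
            )
        return replace(self, samples=self.samples[i0 : i0 + n], start_time=onset_s)


@dataclass(frozen=True)
class ExtremaSet:
    """Indices of respiratory peaks and troughs in a z-scored trace."""

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    prominence_threshold_sd: float
    min_separation_s: float

    @property
    def n_peaks(self) -> int:
        return len(self.peak_indices)

    @property
    def n_troughs(self) -> int:
        return len(self.trough_indices)

    def all_indices(self) -> np.ndarray:
        """Merged, time-ordered extrema indices (peaks and troughs)."""
        return np.sort(np.concatenate([self.peak_indices, self.trough_indices]))


@dataclass(frozen=True)
class TrialFrequency:
    """Whole-segment spectral frequency estimate with a confidence flag.

    ``peak_fraction`` is the share of in-band spectral power concentrated at
    the winning bin and its two neighbours; a diffuse spectrum (white noise)
    yields a small value and ``low_confidence=True``.
    """

    value_hz: float
    peak_fraction: float
    low_confidence: bool

    def __float__(self) -> float:
        return float(self.value_hz)


@dataclass(frozen=True)
class FrequencySeries:
    """Breathing frequency evaluated on a time grid (e.g. fMRI volume onsets)."""

    values: np.ndarray
    grid: np.ndarray
    window_s: float

    def __post_init__(self):
        if len(self.values) != len(self.grid):
            raise InvalidArgumentError("values and grid must have equal length")


@dataclass(frozen=True)
class RVTSeries:
    """Per-sample RVT and its defining envelopes, on the trace's sample grid."""

    values: np.ndarray
    upper_envelope: np.ndarray
    lower_envelope: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.sampling_rate


# ---------------------------------------------------------------------------
# preprocessing


def smooth_and_center(trace: RespirationTrace, window_s: float = 1.0) -> RespirationTrace:
    """Zero-phase low-pass smoothing followed by mean correction.

    The filter is a moving average of width ``window_s`` run forward and
    backward (``filtfilt``), which doubles the attenuation and cancels the
    phase delay, so breath peak positions are not shifted.
    """
    n_win = int(round(window_s * trace.sampling_rate))
    if n_win < 3:
        raise InvalidArgumentError("smoothing window must span at least 3 samples")
    if trace.n_samples <= 3 * n_win:
        raise InvalidArgumentError("trace shorter than smoothing window padding")
    b = np.ones(n_win) / n_win
    smoothed = sps.filtfilt(b, [1.0], trace.samples)
    smoothed -= smoothed.mean()
    return replace(trace, samples=smoothed)


def zscore(trace: RespirationTrace) -> RespirationTrace:
    """Normalize to zero mean, unit standard deviation over the run."""
    sd = trace.samples.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSignalError("cannot z-score a zero-variance signal")
    return replace(trace, samples=(trace.samples - trace.samples.mean()) / sd)


# ---------------------------------------------------------------------------
# extrema detection


def _enforce_alternation(z: np.ndarray, peaks: list, troughs: list):
    """Keep strict peak/trough alternation.

    Within any run of consecutive same-type extrema, only the most extreme
    member (highest peak, lowest trough) survives.
    """
    events = [(i, +1) for i in peaks] + [(i, -1) for i in troughs]
    events.sort()
    kept = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev_idx = kept[-1][0]
            better = z[idx] > z[prev_idx] if kind == +1 else z[idx] < z[prev_idx]
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    return kept


def detect_extrema(
    trace: RespirationTrace,
    prominence_sd: float = 0.5,
    min_separation_s: float = 2.0,
) -> ExtremaSet:
    """Find respiratory peaks and troughs in a z-scored trace.

    Consecutive peaks (and consecutive troughs) must be at least
    ``min_separation_s`` apart; after enforcing strict alternation, any
    adjacent peak-trough pair closer than ``prominence_sd`` z-units in
    amplitude is pruned (the less extreme member is dropped) and alternation
    is re-enforced, until stable.
    """
    z = trace.samples
    dist = max(1, int(round(min_separation_s * trace.sampling_rate)))
    peaks, _ = sps.find_peaks(z, distance=dist)
    troughs, _ = sps.find_peaks(-z, distance=dist)
    if len(peaks) == 0 and len(troughs) == 0:
        warnings.warn("no respiratory extrema found; RVT undefined", stacklevel=2)
        return ExtremaSet(np.array([], int), np.array([], int), prominence_sd, min_separation_s)

    kept = _enforce_alternation(z, list(peaks), list(troughs))

    # amplitude (vertical) constraint between adjacent peak/trough pairs
    changed = True
    while changed and prominence_sd > 0:
        changed = False
        for j in range(len(kept) - 1):
            (i1, k1), (i2, k2) = kept[j], kept[j + 1]
            if abs(z[i1] - z[i2]) < prominence_sd:
                drop = j if abs(z[i1]) < abs(z[i2]) else j + 1
                del kept[drop]
                kept = _enforce_alternation(
                    z,
                    [i for i, k in kept if k == +1],
                    [i for i, k in kept if k == -1],
                )
                changed = True
                break

    peak_idx = np.array(sorted(i for i, k in kept if k == +1), dtype=int)
    trough_idx = np.array(sorted(i for i, k in kept if k == -1), dtype=int)
    return ExtremaSet(peak_idx, trough_idx, prominence_sd, min_separation_s)


# ---------------------------------------------------------------------------
# frequency estimation


def _band_periodogram(x: np.ndarray, fs: float, resolution_hz: float = 0.005):
    """Zero-padded periodogram restricted to the physiological band."""
    n_fft = max(len(x), int(np.ceil(fs / resolution_hz)))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    power = np.abs(np.fft.rfft(x - x.mean(), n=n_fft)) ** 2
    band = (freqs >= FREQ_BAND[0]) & (freqs <= FREQ_BAND[1])
    return freqs[band], power[band]


def estimate_frequency_trial(
    trace: RespirationTrace, low_confidence_fraction: float = 0.2
) -> TrialFrequency:
    """Breathing frequency of a segment: argmax of the zero-padded FFT power
    spectrum within the 0.05-1.0 Hz band, resolution <= 0.01 Hz.
    """
    if trace.duration < 10.0:
        raise InvalidArgumentError(
            f"segment of {trace.duration:.1f} s too short for spectral estimation (need >= 10 s)"
        )
    freqs, power = _band_periodogram(trace.samples, trace.sampling_rate)
    total = power.sum()
    if total == 0:
        raise DegenerateSignalError("flat segment has no spectral power")
    k = int(np.argmax(power))
    lo, hi = max(0, k - 1), min(len(power), k + 2)
    peak_fraction = float(power[lo:hi].sum() / total)
    return TrialFrequency(
        value_hz=float(freqs[k]),
        peak_fraction=peak_fraction,
        low_confidence=peak_fraction < low_confidence_fraction,
    )


def estimate_frequency_sliding(
    trace: RespirationTrace,
    window_s: float = 10.0,
    tr_s: float = 2.0,
    n_volumes: int | None = None,
) -> FrequencySeries:
    """Sliding-window frequency: one value per fMRI volume onset.

    Windows are centered on each volume onset; near the run edges the
    window is shifted inward so it always spans the full ``window_s``
    (edge volumes use this constrained-window estimate, never imputation).
    """
    if trace.duration < window_s:
        raise InvalidArgumentError("trace shorter than the sliding window")
    if n_volumes is None:
        n_volumes = int(np.floor(trace.duration / tr_s))
    if n_volumes < 1:
        raise InvalidArgumentError("empty volume grid")
    grid = trace.start_time + np.arange(n_volumes) * tr_s
    fs = trace.sampling_rate
    half = window_s / 2.0
    values = np.empty(n_volumes)
    for k, t in enumerate(grid):
        t0 = min(max(trace.start_time, t - half), trace.start_time + trace.duration - window_s)
        t1 = t0 + window_s
        i0 = int(round((t0 - trace.start_time) * fs))
        i1 = min(int(round((t1 - trace.start_time) * fs)), trace.n_samples)
        freqs, power = _band_periodogram(trace.samples[i0:i1], fs)
        values[k] = freqs[int(np.argmax(power))] if power.sum() > 0 else np.nan
    return FrequencySeries(values=values, grid=grid, window_s=window_s)


# ---------------------------------------------------------------------------
# RVT


def compute_rvt(trace: RespirationTrace, extrema: ExtremaSet) -> RVTSeries:
    """RVT as the gap between linearly interpolated peak and trough envelopes.

    Samples before the first / after the last extremum hold the nearest
    envelope value.  Inputs are expected z-scored, so RVT is in z-units.
    """
    if extrema.n_peaks < 2 or extrema.n_troughs < 2:
        raise DegenerateSignalError(
            f"need >= 2 peaks and >= 2 troughs for an envelope, got "
            f"{extrema.n_peaks} peaks / {extrema.n_troughs} troughs"
        )
    z = trace.samples
    idx = np.arange(len(z))
    upper = np.interp(idx, extrema.peak_indices, z[extrema.peak_indices])
    lower = np.interp(idx, extrema.trough_indices, z[extrema.trough_indices])
    return RVTSeries(
        values=upper - lower,
        upper_envelope=upper,
        lower_envelope=lower,
        sampling_rate=trace.sampling_rate,
        start_time=trace.start_time,
    )
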