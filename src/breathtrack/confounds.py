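"""Per-volume nuisance regressors and per-trial covariates.

fMRI analyses of breath-attention tasks must control for respiratory
frequency and depth (RVT), which modulate blood CO2 and hence BOLD signal
globally.  This module turns the sample-level physiological series into
(1) a confound table with one row per acquired volume, suitable for a
first-level GLM, and (2) per-trial covariate averages for group-level
models.  Output follows the confound-regressor TSV convention (one row per
volume, named columns, tab-separated); imaging-derived columns (motion,
DVARS, FD) are accepted as pass-through but never computed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .respsignal import (
    FrequencySeries,
    RespirationTrace,
    RVTSeries,
    estimate_frequency_trial,
)

CONFOUND_COLUMNS = ["volume_index", "onset_s", "resp_frequency_hz", "rvt_au"]


def build_confound_table(
    freq: FrequencySeries,
    rvt: RVTSeries,
    n_volumes: int,
    tr_s: float = 2.0,
    passthrough: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One confound row per acquired volume.

    Frequency comes from the sliding-window estimator evaluated on the
    volume grid; RVT per volume is the mean of the sample-level RVT series
    over each TR interval.  The physio recording must cover the scan (edge
    tolerance of one sliding window).
    """
    if n_volumes < 1:
        raise InvalidArgumentError("n_volumes must be >= 1")
    if len(freq.values) < n_volumes:
        raise InvalidArgumentError(
            f"frequency series has {len(freq.values)} values for {n_volumes} volumes"
        )
    rvt_duration = len(rvt.values) / rvt.sampling_rate
    scan_end = n_volumes * tr_s
    if rvt_duration + freq.window_s < scan_end:
        uncovered = [k for k in range(n_volumes) if (k + 1) * tr_s > rvt_duration + freq.window_s]
        raise InvalidArgumentError(
            f"physio recording ({rvt_duration:.1f} s) does not cover volumes {uncovered}"
        )
    fs = rvt.sampling_rate
    rvt_per_vol = np.empty(n_volumes)
    for k in range(n_volumes):
        i0 = int(round(k * tr_s * fs))
        i1 = min(int(round((k + 1) * tr_s * fs)), len(rvt.values))
        rvt_per_vol[k] = rvt.values[i0:i1].mean() if i1 > i0 else rvt.values[-1]
    out = pd.DataFrame(
        {
            "volume_index": np.arange(n_volumes),
            "onset_s": np.arange(n_volumes) * tr_s,
            "resp_frequency_hz": freq.values[:n_volumes],
            "rvt_au": rvt_per_vol,
        }
    )
    if passthrough is not None:
        if len(passthrough) != n_volumes:
            raise InvalidArgumentError("pass-through columns must have one row per volume")
        out = pd.concat([out, passthrough.reset_index(drop=True)], axis=1)
    return out


def trial_average(series, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial mean of a frequency or RVT series over each trial window."""
    rows = []
    if isinstance(series, FrequencySeries):
        t, v = np.asarray(series.grid), np.asarray(series.values)
        # each grid value represents the interval up to the next volume onset
        step = t[1] - t[0] if len(t) > 1 else 0.0
        extent = (t[0], t[-1] + step + 1e-9)
    elif isinstance(series, RVTSeries):
        t, v = series.times, series.values
        extent = (t[0], t[-1] + 1.0 / series.sampling_rate + 1e-9)
    else:
        raise InvalidArgumentError(f"cannot average object of type {type(series).__name__}")
    for tr in trials.itertuples(index=False):
        lo, hi = tr.onset_s, tr.onset_s + tr.duration_s
        if lo < extent[0] - 1e-9 or hi > extent[1] + 1e-6:
            raise InvalidArgumentError(
                f"trial window [{lo}, {hi}) s outside series extent {extent}"
            )
        mask = (t >= lo) & (t < hi)
        rows.append(
            dict(condition=tr.condition, onset_s=lo, duration_s=tr.duration_s,
                 mean_value=float(v[mask].mean()) if mask.any() else np.nan)
        )
    return pd.DataFrame(rows, columns=["condition", "onset_s", "duration_s", "mean_value"])


def trial_covariates(
    trace: RespirationTrace, rvt: RVTSeries, trials: pd.DataFrame
) -> pd.DataFrame:
    """Group-level covariates per trial: spectral frequency and mean RVT.

    The trial frequency is a whole-segment FFT estimate (not the mean of the
    sliding series), so short trials get the full segment's resolution.
    """
    rows = []
    for tr in trials.itertuples(index=False):
        segment = trace.slice_window(tr.onset_s, tr.duration_s)
        f = estimate_frequency_trial(segment)
        mask = (rvt.times >= tr.onset_s) & (rvt.times < tr.onset_s + tr.duration_s)
        row = {c: getattr(tr, c) for c in trials.columns}
        row.update(mean_frequency_hz=f.value_hz, mean_rvt_au=float(rvt.values[mask].mean()))
        rows.append(row)
    cols = list(trials.columns) + ["mean_frequency_hz", "mean_rvt_au"]
    return pd.DataFrame(rows, columns=cols)


def write_confounds_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
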