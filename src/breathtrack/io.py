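"""Plain-text readers/writers for physio traces and session logs.

Respiration traces are exchanged either as a two-column TSV
(``time_s``, ``amplitude``) or as a BIDS-style physio pair: a header-less
columns TSV plus a JSON sidecar holding ``SamplingFrequency``,
``StartTime`` and ``Columns``.  Session logs are two TSVs: a trial table
(participant, session, block, condition, onset_s, duration_s,
circle_period_s) and a keypress event table (time_s, button).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .respsignal import RespirationTrace
from .synth import SessionLog

TRIAL_COLUMNS = [
    "participant", "session", "block", "condition", "onset_s", "duration_s", "circle_period_s",
]
EVENT_COLUMNS = ["time_s", "button"]


def write_respiration_tsv(trace: RespirationTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "amplitude": trace.samples})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_respiration_tsv(path, run_id: str = "") -> RespirationTrace:
    df = pd.read_csv(path, sep="\t")
    if not {"time_s", "amplitude"} <= set(df.columns):
        raise InvalidArgumentError(f"{path}: expected columns time_s, amplitude")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise InvalidArgumentError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-4):
        raise InvalidArgumentError(f"{path}: sampling is not uniform")
    return RespirationTrace(
        samples=df["amplitude"].to_numpy(),
        sampling_rate=1.0 / dt[0],
        start_time=float(t[0]),
        run_id=run_id or Path(path).stem,
    )


def write_physio_bids(trace: RespirationTrace, stem) -> tuple[Path, Path]:
    """Write ``<stem>_physio.tsv`` (no header) and ``<stem>_physio.json``."""
    stem = Path(stem)
    tsv = stem.with_name(stem.name + "_physio.tsv")
    sidecar = stem.with_name(stem.name + "_physio.json")
    np.savetxt(tsv, trace.samples[:, None], fmt="%.6f", delimiter="\t")
    sidecar.write_text(
        json.dumps(
            {
                "SamplingFrequency": trace.sampling_rate,
                "StartTime": trace.start_time,
                "Columns": ["respiratory"],
            },
            indent=2,
        )
    )
    return tsv, sidecar


def read_physio_bids(tsv_path, run_id: str = "") -> RespirationTrace:
    tsv_path = Path(tsv_path)
    sidecar = tsv_path.with_suffix(".json")
    if not sidecar.exists():
        raise InvalidArgumentError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = np.loadtxt(tsv_path, ndmin=2)
    col = meta.get("Columns", ["respiratory"]).index("respiratory")
    return RespirationTrace(
        samples=data[:, col],
        sampling_rate=float(meta["SamplingFrequency"]),
        start_time=float(meta.get("StartTime", 0.0)),
        run_id=run_id or tsv_path.stem,
    )


def write_session_tsvs(log: SessionLog, out_dir, prefix: str = "") -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials_path = out_dir / f"{prefix}trials.tsv"
    events_path = out_dir / f"{prefix}events.tsv"
    log.trials[TRIAL_COLUMNS].to_csv(trials_path, sep="\t", index=False, float_format="%.4f")
    log.events[EVENT_COLUMNS].to_csv(events_path, sep="\t", index=False, float_format="%.4f")
    return trials_path, events_path


def read_session_tsvs(trials_path, events_path) -> SessionLog:
    trials = pd.read_csv(trials_path, sep="\t")
    events = pd.read_csv(events_path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise InvalidArgumentError(f"{trials_path}: missing columns {sorted(missing)}")
    if set(EVENT_COLUMNS) - set(events.columns):
        raise InvalidArgumentError(f"{events_path}: expected columns time_s, button")
    participant = str(trials["participant"].iloc[0]) if len(trials) else "p01"
    session = int(trials["session"].iloc[0]) if len(trials) else 1
    return SessionLog(trials=trials, events=events, participant=participant, session=session)
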