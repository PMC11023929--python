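"""Reading and writing sessions in simple open formats.

A session directory holds:

* ``lfp.dat``      -- float32 little-endian, C order, channels x samples
* ``lfp.json``     -- sidecar: fs, dtype, shape, per-channel depth/label, t0
* ``spikes.tsv``   -- one row per spike: unit_id, spike_time, region, session_id
* ``behavior.tsv`` -- uniformly sampled behavioural columns
* ``behavior.json``-- sidecar: track_length
* ``stimuli.tsv``  -- onset_time, kind, duration

Event tables are delimited text with a header, times printed at sub-millisecond
precision; ``read_events(write_events(E)) == E`` to float round-off.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BehaviorTrace,
    EventTable,
    FormatError,
    LfpRecording,
    SpikeTable,
    StimulusLog,
)

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def write_lfp(lfp: LfpRecording, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = lfp.voltage.astype("<f4")
    data.tofile(directory / "lfp.dat")
    sidecar = {
        "fs": lfp.fs,
        "dtype": "<f4",
        "n_channels": lfp.n_channels,
        "n_samples": lfp.n_samples,
        "channel_depth": [float(d) for d in lfp.channel_depth],
        "channel_label": list(lfp.channel_label),
        "t0": lfp.t0,
        "units": "mV",
    }
    (directory / "lfp.json").write_text(json.dumps(sidecar, indent=1))


def read_lfp(directory: Path) -> LfpRecording:
    directory = Path(directory)
    sidecar_path = directory / "lfp.json"
    if not sidecar_path.exists():
        raise FormatError(f"missing LFP sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    raw = np.fromfile(directory / "lfp.dat", dtype=meta["dtype"])
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    if raw.size != n_ch * n_s:
        raise FormatError(
            f"lfp.dat holds {raw.size} samples; sidecar implies {n_ch} x {n_s}"
        )
    return LfpRecording(
        voltage=raw.reshape(n_ch, n_s).astype(float),
        fs=float(meta["fs"]),
        channel_depth=np.asarray(meta["channel_depth"], dtype=float),
        channel_label=[str(x) for x in meta["channel_label"]],
        t0=float(meta.get("t0", 0.0)),
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_spikes(spikes: SpikeTable, path: Path) -> None:
    _write_tsv(spikes.to_frame(), Path(path))


def read_spikes(path: Path) -> SpikeTable:
    df = pd.read_csv(path, sep="\t")
    return SpikeTable.from_frame(df)


def write_behavior(behavior: BehaviorTrace, directory: Path) -> None:
    directory = Path(directory)
    _write_tsv(behavior.to_frame(), directory / "behavior.tsv")
    (directory / "behavior.json").write_text(
        json.dumps({"track_length": behavior.track_length})
    )


def read_behavior(directory: Path) -> BehaviorTrace:
    directory = Path(directory)
    df = pd.read_csv(directory / "behavior.tsv", sep="\t")
    meta = json.loads((directory / "behavior.json").read_text())
    return BehaviorTrace(
        t=df["t"].to_numpy(),
        position=df["position"].to_numpy(),
        speed=df["speed"].to_numpy(),
        pupil_diameter=df["pupil_diameter"].to_numpy(),
        pupil_speed=df["pupil_speed"].to_numpy(),
        facial_motion=df["facial_motion"].to_numpy(),
        track_length=float(meta["track_length"]),
    )


def write_stimuli(stimuli: StimulusLog, path: Path) -> None:
    _write_tsv(stimuli.to_frame(), Path(path))


def read_stimuli(path: Path) -> StimulusLog:
    df = pd.read_csv(path, sep="\t")
    if not len(df):
        return StimulusLog.empty()
    return StimulusLog(
        onset_time=df["onset_time"].to_numpy(),
        kind=df["kind"].to_numpy(dtype=object),
        duration=df["duration"].to_numpy(),
    )


def write_events(events: EventTable, path: Path) -> None:
    _write_tsv(events.to_frame(), Path(path))


def read_events(path: Path) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    return EventTable.from_frame(df)


# ---------------------------------------------------------------------------
# Matrices (posteriors, peri-event tensors)
# ---------------------------------------------------------------------------

def write_matrix(matrix: np.ndarray, path: Path, **meta) -> None:
    """Binary little-endian float64 matrix with a JSON sidecar."""
    path = Path(path)
    m = np.asarray(matrix, dtype="<f8")
    m.tofile(path)
    sidecar = {"dtype": "<f8", "shape": list(m.shape)}
    sidecar.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_matrix(path: Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    m = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
    return m.astype(float), meta


# ---------------------------------------------------------------------------
# Whole sessions
# ---------------------------------------------------------------------------

def write_session(
    directory: Path,
    lfp: LfpRecording,
    spikes: SpikeTable,
    behavior: BehaviorTrace,
    stimuli: StimulusLog,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_lfp(lfp, directory)
    write_spikes(spikes, directory / "spikes.tsv")
    write_behavior(behavior, directory)
    write_stimuli(stimuli, directory / "stimuli.tsv")


def read_session(
    directory: Path,
) -> tuple[LfpRecording, SpikeTable, BehaviorTrace, StimulusLog]:
    """Load and validate a full session; invariants are checked on load."""
    directory = Path(directory)
    lfp = read_lfp(directory)
    spikes = read_spikes(directory / "spikes.tsv")
    behavior = read_behavior(directory)
    stimuli = read_stimuli(directory / "stimuli.tsv")
    return lfp, spikes, behavior, stimuli
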