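"""Shared data types for laminar LFP event analysis.

All times are seconds (float); bin edges are half-open ``[start, end)`` and
events are assigned to bins by their peak time.  Channel index 0 is the most
superficial contact; depth (micrometres) increases downward along the probe.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dspike")

#: Closed set of event kinds.
EVENT_KINDS = ("SPWR", "DS1", "DS2", "DS_unclassified", "HIGH_FIRING")

#: Closed set of stimulus kinds.
STIMULUS_KINDS = ("tone", "puff")


class ValidationError(ValueError):
    """An object violated one of its declared invariants."""


class FormatError(ValueError):
    """An on-disk representation is inconsistent or unreadable."""


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Named random substream derived from a single session-level seed.

    Every shuffle / simulation procedure draws from its own substream so that
    stages are individually reproducible regardless of execution order.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

@dataclass
class LfpRecording:
    """Multichannel extracellular voltage (millivolts), channels x samples."""

    voltage: np.ndarray
    fs: float
    channel_depth: np.ndarray
    channel_label: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.channel_depth = np.asarray(self.channel_depth, dtype=float)
        if self.voltage.ndim != 2:
            raise ValidationError("voltage must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        n_ch = self.voltage.shape[0]
        if len(self.channel_depth) != n_ch or len(self.channel_label) != n_ch:
            raise ValidationError("channel metadata length mismatch")
        d = np.diff(self.channel_depth)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("channel_depth must be strictly monotonic")
        if not np.all(np.isfinite(self.voltage)):
            raise ValidationError("voltage contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channels_labeled(self, substring: str) -> np.ndarray:
        """Indices of channels whose label contains ``substring``."""
        return np.array(
            [i for i, lab in enumerate(self.channel_label) if substring in lab],
            dtype=int,
        )


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

@dataclass
class SpikeTable:
    """Unit-resolved spike times with brain-region labels.

    ``spike_times`` maps unit id -> sorted array of spike times (s);
    ``region`` maps unit id -> brain-area label.
    """

    spike_times: dict[int, np.ndarray]
    region: dict[int, str]
    session_id: str = ""

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for uid, t in self.spike_times.items():
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(t < 0) or np.any(np.diff(t) < 0)):
                raise ValidationError(f"unit {uid}: spike times must be sorted, >= 0")
            if uid not in self.region:
                raise ValidationError(f"unit {uid}: missing region label")
            clean[int(uid)] = t
        self.spike_times = clean

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.spike_times)

    @property
    def n_units(self) -> int:
        return len(self.spike_times)

    @property
    def regions(self) -> list[str]:
        return sorted({self.region[u] for u in self.spike_times})

    def units_in_region(self, region: str) -> list[int]:
        return [u for u in self.unit_ids if self.region[u] == region]

    def subset(self, unit_ids: Iterable[int]) -> "SpikeTable":
        ids = list(unit_ids)
        return SpikeTable(
            {u: self.spike_times[u] for u in ids},
            {u: self.region[u] for u in ids},
            self.session_id,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for uid in self.unit_ids:
            t = self.spike_times[uid]
            rows.append(
                pd.DataFrame(
                    {
                        "unit_id": uid,
                        "spike_time": t,
                        "region": self.region[uid],
                        "session_id": self.session_id,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["unit_id", "spike_time", "region", "session_id"]
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpikeTable":
        times: dict[int, np.ndarray] = {}
        region: dict[int, str] = {}
        session = ""
        if len(df):
            session = str(df["session_id"].iloc[0])
            for uid, g in df.groupby("unit_id"):
                times[int(uid)] = np.sort(g["spike_time"].to_numpy(dtype=float))
                region[int(uid)] = str(g["region"].iloc[0])
        return cls(times, region, session)


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------

@dataclass
class BehaviorTrace:
    """Uniformly sampled behavioural signals on a circular track."""

    t: np.ndarray
    position: np.ndarray
    speed: np.ndarray
    pupil_diameter: np.ndarray
    pupil_speed: np.ndarray
    facial_motion: np.ndarray
    track_length: float = 120.0

    def __post_init__(self) -> None:
        arrays = [
            "t", "position", "speed", "pupil_diameter", "pupil_speed",
            "facial_motion",
        ]
        n = None
        for name in arrays:
            a = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, a)
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValidationError("behaviour columns must share length")
        dt = np.diff(self.t)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValidationError("t must be strictly increasing and uniform")
        if np.any(self.position < 0) or np.any(self.position >= self.track_length):
            raise ValidationError("position must lie in [0, track_length)")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else np.nan

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def signal(self, name: str) -> np.ndarray:
        if name not in (
            "position", "speed", "pupil_diameter", "pupil_speed", "facial_motion"
        ):
            raise KeyError(name)
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "position": self.position,
                "speed": self.speed,
                "pupil_diameter": self.pupil_diameter,
                "pupil_speed": self.pupil_speed,
                "facial_motion": self.facial_motion,
            }
        )


def unwrap_position(position: np.ndarray, track_length: float) -> np.ndarray:
    """Continuous (unwrapped) track coordinate from a wrapped position trace."""
    pos = np.asarray(position, dtype=float)
    jumps = np.diff(pos)
    wraps = np.zeros_like(pos)
    wraps[1:] = np.cumsum(
        (jumps < -track_length / 2).astype(float)
        - (jumps > track_length / 2).astype(float)
    )
    return pos + wraps * track_length


def circular_distance(a, b, track_length: float) -> np.ndarray:
    """Signed circular distance a - b on a track of given length (in (-L/2, L/2])."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % track_length
    return np.where(d > track_length / 2, d - track_length, d)


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

@dataclass
class EventTable:
    """Detected LFP events, sorted by peak time."""

    kind: np.ndarray
    peak_time: np.ndarray
    amplitude: np.ndarray
    half_width: np.ndarray
    channel_index: np.ndarray
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = np.asarray(self.kind, dtype=object)
        self.peak_time = np.asarray(self.peak_time, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.half_width = np.asarray(self.half_width, dtype=float)
        self.channel_index = np.asarray(self.channel_index, dtype=int)
        n = self.peak_time.size
        for name in ("kind", "amplitude", "half_width", "channel_index"):
            if getattr(self, name).size != n:
                raise ValidationError("event columns must share length")
        for k in self.kind:
            if k not in EVENT_KINDS:
                raise ValidationError(f"unknown event kind {k!r}")
        if n and np.any(np.diff(self.peak_time) < 0):
            raise ValidationError("peak times must be sorted")
        ds_mask = np.isin(self.kind.astype(str), ("DS1", "DS2", "DS_unclassified"))
        if np.any(~np.isfinite(self.amplitude[ds_mask])):
            raise ValidationError("amplitude required for DS events")
        self.extra = {k: np.asarray(v) for k, v in self.extra.items()}
        for k, v in self.extra.items():
            if v.size != n:
                raise ValidationError(f"extra column {k!r} length mismatch")

    def __len__(self) -> int:
        return self.peak_time.size

    @classmethod
    def empty(cls) -> "EventTable":
        return cls(
            np.array([], dtype=object), np.array([]), np.array([]),
            np.array([]), np.array([], dtype=int),
        )

    @classmethod
    def from_times(
        cls,
        kind: str | Sequence[str],
        peak_time: np.ndarray,
        amplitude: np.ndarray | float = np.nan,
        half_width: np.ndarray | float = np.nan,
        channel_index: np.ndarray | int = -1,
        extra: Mapping[str, np.ndarray] | None = None,
    ) -> "EventTable":
        t = np.asarray(peak_time, dtype=float)
        n = t.size

        def col(x, dtype):
            a = np.asarray(x, dtype=dtype)
            return np.full(n, a, dtype=dtype) if a.ndim == 0 else a

        kinds = np.full(n, kind, dtype=object) if isinstance(kind, str) else \
            np.asarray(kind, dtype=object)
        order = np.argsort(t, kind="stable")
        ex = {k: col(v, None)[order] for k, v in (extra or {}).items()}
        return cls(
            kinds[order], t[order], col(amplitude, float)[order],
            col(half_width, float)[order], col(channel_index, int)[order], ex,
        )

    def select(self, mask: np.ndarray) -> "EventTable":
        return EventTable(
            self.kind[mask], self.peak_time[mask], self.amplitude[mask],
            self.half_width[mask], self.channel_index[mask],
            {k: v[mask] for k, v in self.extra.items()},
        )

    def of_kind(self, kind: str) -> "EventTable":
        return self.select(self.kind.astype(str) == kind)

    def with_kinds(self, kinds: Sequence[str]) -> "EventTable":
        """Copy with per-event kinds replaced (e.g. after classification)."""
        return EventTable(
            np.asarray(kinds, dtype=object), self.peak_time, self.amplitude,
            self.half_width, self.channel_index, dict(self.extra),
        )

    @staticmethod
    def concat(tables: Sequence["EventTable"]) -> "EventTable":
        tables = [t for t in tables if len(t)]
        if not tables:
            return EventTable.empty()
        keys = sorted(set.intersection(*[set(t.extra) for t in tables]))
        kind = np.concatenate([t.kind for t in tables])
        peak = np.concatenate([t.peak_time for t in tables])
        amp = np.concatenate([t.amplitude for t in tables])
        hw = np.concatenate([t.half_width for t in tables])
        ch = np.concatenate([t.channel_index for t in tables])
        ex = {k: np.concatenate([t.extra[k] for t in tables]) for k in keys}
        order = np.argsort(peak, kind="stable")
        return EventTable(
            kind[order], peak[order], amp[order], hw[order], ch[order],
            {k: v[order] for k, v in ex.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "kind": self.kind.astype(str),
                "peak_time": self.peak_time,
                "amplitude": self.amplitude,
                "half_width": self.half_width,
                "channel_index": self.channel_index,
            }
        )
        for k, v in self.extra.items():
            df[k] = v
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        base = {"kind", "peak_time", "amplitude", "half_width", "channel_index"}
        extra = {
            c: df[c].to_numpy() for c in df.columns if c not in base
        }
        if not len(df):
            out = cls.empty()
            out.extra = {k: np.asarray(v) for k, v in extra.items()}
            return out
        return cls(
            df["kind"].to_numpy(dtype=object),
            df["peak_time"].to_numpy(dtype=float),
            df["amplitude"].to_numpy(dtype=float),
            df["half_width"].to_numpy(dtype=float),
            df["channel_index"].to_numpy(dtype=int),
            extra,
        )


def exclude_multikind(
    events: EventTable, window_s: float = 0.2
) -> EventTable:
    """Drop events with an event of a *different* kind within ``window_s``.

    Mirrors the pre-analysis exclusion of events contaminated by another event
    type inside the peri-event window.
    """
    t = events.peak_time
    k = events.kind.astype(str)
    keep = np.ones(len(events), dtype=bool)
    for i in range(len(events)):
        j = i - 1
        while j >= 0 and t[i] - t[j] <= window_s:
            if k[j] != k[i]:
                keep[i] = keep[j] = False
            j -= 1
    return events.select(keep)


# ---------------------------------------------------------------------------
# Stimuli
# ---------------------------------------------------------------------------

@dataclass
class StimulusLog:
    """Sensory stimulation events (tones / air puffs)."""

    onset_time: np.ndarray
    kind: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        self.onset_time = np.asarray(self.onset_time, dtype=float)
        self.kind = np.asarray(self.kind, dtype=object)
        self.duration = np.asarray(self.duration, dtype=float)
        if self.onset_time.size and np.any(np.diff(self.onset_time) < 0):
            raise ValidationError("stimulus onsets must be sorted")
        for k in self.kind:
            if k not in STIMULUS_KINDS:
                raise ValidationError(f"unknown stimulus kind {k!r}")

    def __len__(self) -> int:
        return self.onset_time.size

    @classmethod
    def empty(cls) -> "StimulusLog":
        return cls(np.array([]), np.array([], dtype=object), np.array([]))

    def of_kind(self, kind: str) -> "StimulusLog":
        m = self.kind.astype(str) == kind
        return StimulusLog(self.onset_time[m], self.kind[m], self.duration[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_time": self.onset_time,
                "kind": self.kind.astype(str),
                "duration": self.duration,
            }
        )
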