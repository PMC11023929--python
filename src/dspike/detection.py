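"""Dentate-spike and sharp-wave-ripple detection from laminar LFP.

DSs are found as large positive peaks of the 5-100 Hz bandpassed hilus
signal (threshold in standard deviations of the filtered trace); SPW-Rs as
excursions of the Hilbert envelope of the 120-180 Hz bandpassed CA1
pyramidal-layer signal that reach 5 SD at the peak and stay above 3 SD for at
least 25 ms.  All filters are zero-phase (forward-backward Butterworth,
order 3) so peak times are not skewed by group delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import EventTable, LfpRecording, StimulusLog


@dataclass
class DetectionParams:
    ds_band: tuple = (5.0, 100.0)
    ds_threshold_sd: float = 4.5
    ds_merge_ms: float = 25.0
    swr_band: tuple = (120.0, 180.0)
    swr_peak_sd: float = 5.0
    swr_sustain_sd: float = 3.0
    swr_sustain_ms: float = 25.0
    sync_window_ms: float = 100.0
    evoked_window_ms: float = 200.0
    filter_order: int = 3

    def __post_init__(self) -> None:
        for lo, hi in (self.ds_band, self.swr_band):
            if not 0 < lo < hi:
                raise ValueError("band edges must satisfy 0 < low < high")
        for thr in (self.ds_threshold_sd, self.swr_peak_sd, self.swr_sustain_sd):
            if thr <= 0:
                raise ValueError("thresholds must be positive")


def bandpass(x: np.ndarray, fs: float, band: tuple, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth bandpass."""
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _check_length(lfp: LfpRecording, low_hz: float) -> None:
    settle = int(np.ceil(3.0 * lfp.fs / low_hz))
    if lfp.n_samples < 2 * settle:
        raise ValueError(
            f"trace of {lfp.n_samples} samples is shorter than twice the "
            f"filter settling span ({settle} samples)"
        )


def detect_ds(
    lfp: LfpRecording,
    hilus_channel: int,
    params: DetectionParams | None = None,
) -> EventTable:
    """Detect dentate spikes on the hilus channel.

    Returns events of kind ``DS_unclassified``; amplitude is the filtered
    trace at the peak, half-width the width at half that amplitude on the
    filtered trace.  Super-threshold peaks closer than one template width
    are merged, keeping the larger.
    """
    params = params or DetectionParams()
    if not 0 <= hilus_channel < lfp.n_channels:
        raise IndexError("hilus_channel outside probe")
    _check_length(lfp, params.ds_band[0])
    filt = bandpass(
        lfp.voltage[hilus_channel], lfp.fs, params.ds_band, params.filter_order
    )
    sd = filt.std()
    thr = params.ds_threshold_sd * sd
    distance = max(1, int(round(params.ds_merge_ms / 1000.0 * lfp.fs)))
    peaks, _ = signal.find_peaks(filt, height=thr, distance=distance)
    if peaks.size == 0:
        return EventTable.empty()
    widths = signal.peak_widths(filt, peaks, rel_height=0.5)[0]
    return EventTable.from_times(
        "DS_unclassified",
        lfp.t0 + peaks / lfp.fs,
        amplitude=filt[peaks],
        half_width=widths / lfp.fs * 1000.0,
        channel_index=hilus_channel,
    )


def detect_swr(
    lfp: LfpRecording,
    pyramidal_channel: int,
    params: DetectionParams | None = None,
) -> EventTable:
    """Detect sharp-wave ripples on the CA1 pyramidal channel.

    One event per super-3-SD envelope excursion that lasts at least
    ``swr_sustain_ms`` and contains a 5 SD envelope peak; the ripple time is
    the maximum positive value of the filtered trace within the excursion.
    """
    params = params or DetectionParams()
    if not 0 <= pyramidal_channel < lfp.n_channels:
        raise IndexError("pyramidal_channel outside probe")
    _check_length(lfp, params.swr_band[0])
    filt = bandpass(
        lfp.voltage[pyramidal_channel], lfp.fs, params.swr_band, params.filter_order
    )
    env = np.abs(signal.hilbert(filt))
    z = (env - env.mean()) / env.std()

    above = z >= params.swr_sustain_sd
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]

    min_len = int(round(params.swr_sustain_ms / 1000.0 * lfp.fs))
    times, amps, durs = [], [], []
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        if z[s:e].max() < params.swr_peak_sd:
            continue
        i = s + int(np.argmax(filt[s:e]))
        times.append(lfp.t0 + i / lfp.fs)
        amps.append(filt[i])
        durs.append((e - s) / lfp.fs * 1000.0)
    if not times:
        return EventTable.empty()
    return EventTable.from_times(
        "SPWR",
        np.asarray(times),
        amplitude=np.asarray(amps),
        half_width=np.nan,
        channel_index=pyramidal_channel,
        extra={"duration_ms": np.asarray(durs)},
    )


def coincidence(
    events_a: EventTable, events_b: EventTable, window_ms: float = 100.0
) -> tuple[float, list[tuple[int, int]]]:
    """Fraction of synchronous events and greedy nearest-neighbour pairs.

    Events are matched greedily by smallest time difference within the
    window, each at most once; the fraction is computed with the table
    holding fewer events as the reference (tie broken to ``events_a``).
    """
    w = window_ms / 1000.0
    ta, tb = events_a.peak_time, events_b.peak_time
    cand = []
    for i, t in enumerate(ta):
        j0 = np.searchsorted(tb, t - w)
        j1 = np.searchsorted(tb, t + w, side="right")
        for j in range(j0, j1):
            cand.append((abs(t - tb[j]), i, j))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    n_ref = min(len(events_a), len(events_b))
    fraction = len(pairs) / n_ref if n_ref else 0.0
    return fraction, pairs


def evoked_latency(
    events: EventTable, stimuli: StimulusLog, window_ms: float = 200.0
) -> tuple[np.ndarray, float]:
    """Per-stimulus latency (ms) of the first DS2 strictly after onset within
    the window (NaN if none), and the fraction of stimuli with a hit."""
    w = window_ms / 1000.0
    t_ev = events.of_kind("DS2").peak_time
    lat = np.full(len(stimuli), np.nan)
    for i, onset in enumerate(stimuli.onset_time):
        j = np.searchsorted(t_ev, onset, side="right")
        if j < t_ev.size and t_ev[j] - onset <= w:
            lat[i] = (t_ev[j] - onset) * 1000.0
    frac = float(np.mean(np.isfinite(lat))) if len(stimuli) else 0.0
    return lat, frac


def event_rate(events: EventTable, intervals) -> float:
    """Events per second of the supplied (disjoint) time intervals."""
    intervals = sorted((float(s), float(e)) for s, e in intervals)
    total = 0.0
    prev_end = -np.inf
    for s, e in intervals:
        if s < prev_end:
            raise ValueError("intervals must be disjoint")
        total += e - s
        prev_end = e
    if total <= 0:
        raise ValueError("total interval duration is zero")
    t = events.peak_time
    count = sum(int(np.sum((t >= s) & (t < e))) for s, e in intervals)
    return count / total


def suggest_channels(lfp: LfpRecording) -> dict:
    """Rank channels by ripple-band and DS-band power (guidance only; the
    analysis channels are user-specified)."""
    rip_p, ds_p = [], []
    for i in range(lfp.n_channels):
        rip = bandpass(lfp.voltage[i], lfp.fs, (120.0, 180.0))
        ds = bandpass(lfp.voltage[i], lfp.fs, (5.0, 100.0))
        rip_p.append(float(np.mean(rip**2)))
        # DS band skewness-weighted power favours channels with positive spikes
        ds_p.append(float(np.mean(ds**2) * max(0.0, np.mean(ds**3))))
    return {
        "ripple_power": np.asarray(rip_p),
        "ds_power": np.asarray(ds_p),
        "pyramidal_channel": int(np.argmax(rip_p)),
        "hilus_channel": int(np.argmax(ds_p)),
    }
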