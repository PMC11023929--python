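"""Peri-event firing statistics, shuffle modulation tests, brain-wide
high-firing peaks, behaviour-change tests and motion-state segmentation.

Peri-event rates use 10 ms bins over +/-200 ms around each event peak and
are z-scored against each unit's session-wide mean and SD, computed from the
100 ms-binned whole-session rate smoothed with a Gaussian (sigma = 5 bins).
The modulation null redraws every peri-event spike uniformly within the
window (preserving per-event spike counts); a unit is significantly
modulated when the maximal bin of its event-averaged trace strictly exceeds
the 99.5th percentile of shuffled maxima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .core import BehaviorTrace, EventTable, SpikeTable

logger = logging.getLogger("dspike")

PERI_WINDOW_S = 0.2
PERI_BIN_S = 0.01
N_PERI_BINS = int(round(2 * PERI_WINDOW_S / PERI_BIN_S))  # 40


@dataclass
class PeriEventRates:
    unit_id: int
    event_kind: str
    rate_z: np.ndarray      # events x 40 bins
    peak_z: float           # max of the event-averaged trace
    session_mean: float     # Hz
    session_sd: float       # Hz

    @property
    def mean_trace(self) -> np.ndarray:
        return self.rate_z.mean(axis=0)


@dataclass
class ModulationResult:
    unit_id: int
    event_kind: str
    significant: bool
    percentile_threshold: float
    peak_bin_time: float    # ms relative to the event peak
    peak_z: float
    null_threshold_z: float


def session_rate_stats(
    spike_times: np.ndarray,
    duration: float,
    bin_s: float = 0.1,
    smooth_sigma_bins: float = 5.0,
) -> tuple[float, float]:
    """Session mean and SD (Hz) of the smoothed whole-session firing rate."""
    n_bins = max(1, int(np.ceil(duration / bin_s)))
    counts, _ = np.histogram(spike_times, bins=n_bins, range=(0.0, n_bins * bin_s))
    rate = gaussian_filter1d(counts.astype(float) / bin_s, smooth_sigma_bins)
    return float(rate.mean()), float(rate.std())


def _peri_counts(
    spike_times: np.ndarray, event_times: np.ndarray, window_s: float, bin_s: float
) -> np.ndarray:
    """Per-event spike counts in peri-event bins (events x n_bins)."""
    n_bins = int(round(2 * window_s / bin_s))
    out = np.zeros((event_times.size, n_bins), dtype=float)
    for i, t in enumerate(event_times):
        rel = spike_times[
            np.searchsorted(spike_times, t - window_s):
            np.searchsorted(spike_times, t + window_s)
        ] - t
        if rel.size:
            idx = np.floor((rel + window_s) / bin_s).astype(int)
            np.add.at(out[i], np.clip(idx, 0, n_bins - 1), 1.0)
    return out


def perievent_zscores(
    spikes: SpikeTable,
    events: EventTable,
    duration: float | None = None,
) -> dict[int, PeriEventRates]:
    """Peri-event z-scored rates per unit for events of a single kind.

    Units with zero session SD (e.g. zero spikes) are excluded with a log
    entry.
    """
    kinds = set(events.kind.astype(str))
    if len(kinds) > 1:
        raise ValueError("events must be of a single kind")
    kind = kinds.pop() if kinds else ""
    if duration is None:
        last = max((t[-1] for t in spikes.spike_times.values() if t.size), default=0.0)
        duration = max(last, events.peak_time.max() + PERI_WINDOW_S if len(events) else 0.0)

    out: dict[int, PeriEventRates] = {}
    for uid in spikes.unit_ids:
        st = spikes.spike_times[uid]
        mean, sd = session_rate_stats(st, duration)
        if sd <= 0:
            logger.info("unit %d excluded from peri-event z-scores (zero SD)", uid)
            continue
        counts = _peri_counts(st, events.peak_time, PERI_WINDOW_S, PERI_BIN_S)
        rate_z = (counts / PERI_BIN_S - mean) / sd
        out[uid] = PeriEventRates(
            unit_id=uid, event_kind=kind, rate_z=rate_z,
            peak_z=float(rate_z.mean(axis=0).max()) if len(events) else np.nan,
            session_mean=mean, session_sd=sd,
        )
    return out


def modulation_test(
    spikes: SpikeTable,
    events: EventTable,
    n_shuffles: int = 100,
    percentile: float = 99.5,
    rng: np.random.Generator | None = None,
    duration: float | None = None,
) -> dict[int, ModulationResult]:
    """Shuffle test for positive event-locked modulation.

    The null redraws each peri-event spike uniformly within the +/-200 ms
    window (per-event spike counts preserved); pooling across events this is
    a multinomial redistribution of the unit's total peri-event spike count
    over the 40 bins.  The observed event-averaged maximum must strictly
    exceed the ``percentile`` of shuffled maxima.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    rng = rng or np.random.default_rng()
    rates = perievent_zscores(spikes, events, duration=duration)
    kind = str(events.kind[0]) if len(events) else ""
    n_ev = max(1, len(events))

    out: dict[int, ModulationResult] = {}
    p_uniform = np.full(N_PERI_BINS, 1.0 / N_PERI_BINS)
    for uid, r in rates.items():
        pooled = _peri_counts(
            spikes.spike_times[uid], events.peak_time, PERI_WINDOW_S, PERI_BIN_S
        ).sum(axis=0)
        # observed and shuffled statistics share the same pooled-count
        # arithmetic so that exact ties compare as ties
        def z_of(counts):
            return (counts / n_ev / PERI_BIN_S - r.session_mean) / r.session_sd

        obs_trace = z_of(pooled)
        obs_max = float(obs_trace.max())
        # the per-event uniform redraw preserves per-event counts; the
        # pooled count is then a multinomial redistribution over the bins
        null_counts = rng.multinomial(int(pooled.sum()), p_uniform,
                                      size=n_shuffles)
        null_max = z_of(null_counts).max(axis=1)
        thr = float(np.percentile(null_max, percentile, method="higher"))
        peak_bin = int(np.argmax(obs_trace))
        out[uid] = ModulationResult(
            unit_id=uid, event_kind=kind,
            significant=bool(obs_max > thr),
            percentile_threshold=percentile,
            peak_bin_time=(peak_bin + 0.5) * PERI_BIN_S * 1000.0 - PERI_WINDOW_S * 1000.0,
            peak_z=obs_max, null_threshold_z=thr,
        )
    return out


def high_firing_peaks(
    spikes: SpikeTable,
    bin_s: float = 0.01,
    percentile: float = 99.9,
    duration: float | None = None,
) -> EventTable:
    """Peaks of the population-average firing rate above its 99.9th
    percentile, returned as events of kind ``HIGH_FIRING``."""
    if spikes.n_units == 0:
        raise ValueError("high_firing_peaks requires at least one unit")
    if duration is None:
        duration = max(t[-1] for t in spikes.spike_times.values() if t.size)
    n_bins = int(np.ceil(duration / bin_s))
    pooled = np.zeros(n_bins)
    for t in spikes.spike_times.values():
        c, _ = np.histogram(t, bins=n_bins, range=(0.0, n_bins * bin_s))
        pooled += c
    trace = pooled / spikes.n_units / bin_s
    thr = np.percentile(trace, percentile)
    peaks, _ = find_peaks(trace, height=thr + 1e-12)
    if peaks.size == 0:
        return EventTable.empty()
    return EventTable.from_times(
        "HIGH_FIRING", (peaks + 0.5) * bin_s,
        extra={"rate_hz": trace[peaks]},
    )


def behavior_change_test(
    trace: BehaviorTrace,
    events: EventTable,
    signal: str = "pupil_speed",
    pre_window: tuple = (-0.290, -0.085),
    post_window: tuple = (-0.020, 0.085),
    n_shuffle_draws: int = 200,
    shift_range_s: float = 2.0,
    percentile: float = 97.5,
    rng: np.random.Generator | None = None,
):
    """Per-event post-minus-pre signal change with a +/- ``shift_range_s``
    event-shift null; events above the pooled null's ``percentile`` flagged.

    Returns ``(changes, flags, threshold, used_mask)``; events whose windows
    (or shifted windows) would fall outside the trace are skipped.
    """
    rng = rng or np.random.default_rng()
    x = trace.signal(signal)
    t0, dt, n = float(trace.t[0]), trace.dt, trace.t.size

    def window_mean(times, w):
        i0 = np.round((times + w[0] - t0) / dt).astype(int)
        i1 = np.round((times + w[1] - t0) / dt).astype(int)
        out = np.empty(times.size)
        for k, (a, b) in enumerate(zip(i0, i1)):
            out[k] = x[a:b].mean() if 0 <= a < b <= n else np.nan
        return out

    times = events.peak_time
    lo = min(pre_window[0], post_window[0]) - shift_range_s
    hi = max(pre_window[1], post_window[1]) + shift_range_s
    used = (times + lo >= t0) & (times + hi <= t0 + n * dt)
    if not np.all(used):
        logger.info("behavior_change_test: %d events near edges skipped",
                    int(np.sum(~used)))
    tu = times[used]
    changes = window_mean(tu, post_window) - window_mean(tu, pre_window)

    shifts = rng.uniform(-shift_range_s, shift_range_s, size=(n_shuffle_draws, tu.size))
    null = np.empty((n_shuffle_draws, tu.size))
    for k in range(n_shuffle_draws):
        ts = tu + shifts[k]
        null[k] = window_mean(ts, post_window) - window_mean(ts, pre_window)
    pooled = null[np.isfinite(null)]
    thr = float(np.percentile(pooled, percentile)) if pooled.size else np.nan
    flags = changes > thr
    return changes, flags, thr, used


def segment_motion_state(
    trace: BehaviorTrace, threshold_cm_s: float = 1.0
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Maximal immobility (< threshold) and locomotion (>= threshold)
    intervals; together they tile the sampled span."""
    below = trace.speed < threshold_cm_s
    dt = trace.dt
    t_edge = np.r_[trace.t, trace.t[-1] + dt]
    immobility, locomotion = [], []
    i = 0
    n = below.size
    while i < n:
        j = i
        while j < n and below[j] == below[i]:
            j += 1
        (immobility if below[i] else locomotion).append(
            (float(t_edge[i]), float(t_edge[j]))
        )
        i = j
    return immobility, locomotion


def dff(fluorescence: np.ndarray, t: np.ndarray | None = None) -> np.ndarray:
    """Delta-F/F with a least-squares cubic-polynomial baseline B(t):
    returns (F - B) / B; raises if the baseline is not strictly positive."""
    f = np.asarray(fluorescence, dtype=float)
    if f.size < 4:
        raise ValueError("dff needs at least 4 samples")
    tt = np.asarray(t, dtype=float) if t is not None else np.arange(f.size, dtype=float)
    coef = np.polynomial.polynomial.polyfit(tt, f, deg=3)
    baseline = np.polynomial.polynomial.polyval(tt, coef)
    if np.any(baseline <= 0):
        raise ValueError("polynomial baseline crosses zero; dF/F undefined")
    return (f - baseline) / baseline


def event_zscore(
    trace: np.ndarray, fs: float, event_indices: np.ndarray,
    window_s: float = 1.0, baseline_s: float = 1.0,
) -> np.ndarray:
    """Event-aligned traces standardized by the preceding ``baseline_s`` of
    data (events x samples over [0, window_s) after the event)."""
    nb = int(round(baseline_s * fs))
    nw = int(round(window_s * fs))
    out = []
    for i in event_indices:
        if i - nb < 0 or i + nw > trace.size:
            continue
        base = trace[i - nb : i]
        sd = base.std()
        out.append((trace[i : i + nw] - base.mean()) / (sd if sd > 0 else 1.0))
    return np.asarray(out)
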