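"""Bayesian position decoding and replay-trajectory fitting.

Position on the 120 cm circular treadmill is discretized into 24 five-cm
bins.  With a flat prior, independent units and Poisson spike counts in a
20 ms window, the log posterior over position bins is

    log P(x | n)  =  sum_i [ n_i log(r_i(x) tau) - r_i(x) tau ]  + const,

normalized so each posterior row sums to one; the decoded position is the
argmax bin.  Decoding is done in log space, and tuning curves are floored at
a small positive rate for numerical stability.

Candidate replay events are bounded by smoothed multi-unit activity (1 ms
bins, 21 ms Hanning kernel) exceeding its mean, with boundaries shrunk to
the first and last occupied bins and a 50 ms - 2 s duration rule.
Trajectory slopes come from a posterior-weighted circular-linear regression
(grid search over slopes with the closed-form best phase per slope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import BehaviorTrace, EventTable, SpikeTable, unwrap_position

N_POSITION_BINS = 24
BIN_CM = 5.0
DECODE_TAU_S = 0.02


@dataclass
class TuningCurves:
    unit_ids: list
    rate_by_bin: np.ndarray     # units x n_bins, Hz
    occupancy_s: np.ndarray     # per bin
    track_length: float = 120.0

    @property
    def n_bins(self) -> int:
        return self.rate_by_bin.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.track_length / self.n_bins


@dataclass
class PosteriorMatrix:
    window_start: float
    p: np.ndarray               # time-steps x position bins, rows sum to 1
    window_ms: float = 20.0
    step_ms: float = 5.0


@dataclass
class CandidateEvent:
    start: float
    end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class TrajectoryFit:
    slope: float                # position bins per time step (circular)
    phase: float                # radians
    r_squared: float


# ---------------------------------------------------------------------------
# Tuning curves
# ---------------------------------------------------------------------------

def _interval_mask(t: np.ndarray, intervals) -> np.ndarray:
    m = np.zeros(t.size, dtype=bool)
    for s, e in intervals:
        m |= (t >= s) & (t < e)
    return m


def _times_in_intervals(times: np.ndarray, intervals) -> np.ndarray:
    keep = np.zeros(times.size, dtype=bool)
    for s, e in intervals:
        keep |= (times >= s) & (times < e)
    return times[keep]


def tuning_curves(
    spikes: SpikeTable,
    behavior: BehaviorTrace,
    intervals,
    n_bins: int = N_POSITION_BINS,
    smooth_sigma_bins: float = 1.0,
    floor_hz: float = 0.01,
    unit_ids=None,
) -> TuningCurves:
    """Occupancy-normalized position tuning restricted to the supplied
    (locomotion) intervals; counts and occupancy are smoothed circularly
    before division, and rates floored at ``floor_hz``."""
    L = behavior.track_length
    mask = _interval_mask(behavior.t, intervals)
    pos = behavior.position[mask]
    edges = np.linspace(0.0, L, n_bins + 1)
    occ_counts, _ = np.histogram(pos, bins=edges)
    occupancy = occ_counts * behavior.dt
    if np.any(occupancy <= 0):
        bad = int(np.argmin(occupancy))
        raise ValueError(f"zero locomotion occupancy in position bin {bad}")

    unwrapped = unwrap_position(behavior.position, L)
    ids = list(unit_ids) if unit_ids is not None else spikes.unit_ids
    rates = np.empty((len(ids), n_bins))
    occ_s = gaussian_filter1d(occupancy, smooth_sigma_bins, mode="wrap") \
        if smooth_sigma_bins > 0 else occupancy
    for k, uid in enumerate(ids):
        st = _times_in_intervals(spikes.spike_times[uid], intervals)
        sp = np.interp(st, behavior.t, unwrapped) % L
        counts, _ = np.histogram(sp, bins=edges)
        c = gaussian_filter1d(counts.astype(float), smooth_sigma_bins, mode="wrap") \
            if smooth_sigma_bins > 0 else counts.astype(float)
        rates[k] = c / occ_s
    return TuningCurves(ids, np.maximum(rates, floor_hz), occupancy, L)


def spatial_information(rates: np.ndarray, occupancy: np.ndarray) -> float:
    """Skaggs spatial information (bits/spike) of one tuning curve."""
    p = occupancy / occupancy.sum()
    mean_rate = float(np.sum(p * rates))
    if mean_rate <= 0:
        return 0.0
    rel = rates / mean_rate
    nz = rel > 0
    return float(np.sum(p[nz] * rel[nz] * np.log2(rel[nz])))


def select_place_cells(
    spikes: SpikeTable,
    behavior: BehaviorTrace,
    intervals,
    n_shuffles: int = 100,
    percentile: float = 95.0,
    min_shift_s: float = 20.0,
    rng: np.random.Generator | None = None,
) -> list:
    """Units whose spatial information exceeds the ``percentile`` of a
    circular spike-shift null (computed on the concatenated locomotion
    time base)."""
    rng = rng or np.random.default_rng()
    curves = tuning_curves(spikes, behavior, intervals)
    starts = np.array([s for s, _ in intervals])
    lengths = np.array([e - s for s, e in intervals])
    cum = np.r_[0.0, np.cumsum(lengths)]
    total = cum[-1]

    def to_linear(times):
        idx = np.searchsorted(starts, times, side="right") - 1
        return cum[idx] + (times - starts[idx])

    def to_session(lin):
        idx = np.searchsorted(cum[1:], lin, side="right")
        idx = np.clip(idx, 0, starts.size - 1)
        return starts[idx] + (lin - cum[idx])

    selected = []
    for k, uid in enumerate(curves.unit_ids):
        st = _times_in_intervals(spikes.spike_times[uid], intervals)
        obs = spatial_information(curves.rate_by_bin[k], curves.occupancy_s)
        if st.size < 10:
            continue
        lin = to_linear(st)
        null = np.empty(n_shuffles)
        for s in range(n_shuffles):
            shift = rng.uniform(min_shift_s, total - min_shift_s)
            shifted = np.sort(to_session((lin + shift) % total))
            sub = spikes.subset([uid])
            sub.spike_times[uid] = shifted
            c = tuning_curves(sub, behavior, intervals, unit_ids=[uid])
            null[s] = spatial_information(c.rate_by_bin[0], c.occupancy_s)
        if obs > np.percentile(null, percentile):
            selected.append(uid)
    return selected


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def decode(
    counts: np.ndarray, curves: TuningCurves, tau: float = DECODE_TAU_S
) -> np.ndarray:
    """Posterior over position bins given per-unit spike counts.

    ``counts`` is (units,) or (windows, units); returns matching posterior
    rows on the probability simplex (flat prior, Poisson likelihood,
    log-space accumulation).
    """
    counts = np.asarray(counts, dtype=float)
    single = counts.ndim == 1
    counts = np.atleast_2d(counts)
    r = curves.rate_by_bin  # units x bins
    if np.all(r <= 0):
        raise ValueError("all-zero tuning curves")
    if counts.shape[1] != r.shape[0]:
        raise ValueError("counts do not match the number of units")
    log_like = counts @ np.log(r * tau) - (r * tau).sum(axis=0)[None, :]
    log_like -= log_like.max(axis=1, keepdims=True)
    post = np.exp(log_like)
    post /= post.sum(axis=1, keepdims=True)
    return post[0] if single else post


def _window_counts(
    spikes: SpikeTable, unit_ids, starts: np.ndarray, window_s: float
) -> np.ndarray:
    out = np.empty((starts.size, len(unit_ids)))
    for j, uid in enumerate(unit_ids):
        st = spikes.spike_times[uid]
        out[:, j] = np.searchsorted(st, starts + window_s) - np.searchsorted(st, starts)
    return out


def decode_sliding(
    spikes: SpikeTable,
    curves: TuningCurves,
    t_start: float,
    t_end: float,
    window_s: float = 0.02,
    step_s: float = 0.005,
) -> PosteriorMatrix:
    """Sliding-window posterior matrix over [t_start, t_end]."""
    starts = np.arange(t_start, t_end - window_s + 1e-12, step_s)
    counts = _window_counts(spikes, curves.unit_ids, starts, window_s)
    post = decode(counts, curves, tau=window_s)
    return PosteriorMatrix(
        window_start=t_start, p=np.atleast_2d(post),
        window_ms=window_s * 1000.0, step_ms=step_s * 1000.0,
    )


def decoding_errors(
    spikes: SpikeTable,
    curves: TuningCurves,
    behavior: BehaviorTrace,
    event_times: np.ndarray,
    window_s: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Decoded and actual position bins for one window centred per event."""
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("no events to decode")
    counts = _window_counts(
        spikes, curves.unit_ids, event_times - window_s / 2, window_s
    )
    post = decode(counts, curves, tau=window_s)
    decoded = np.argmax(post, axis=1)
    L = behavior.track_length
    pos = np.interp(
        event_times, behavior.t, unwrap_position(behavior.position, L)
    ) % L
    actual = np.minimum(
        (pos / (L / curves.n_bins)).astype(int), curves.n_bins - 1
    )
    return decoded, actual


def error_overrepresentation(
    decoded_bins: np.ndarray,
    actual_bins: np.ndarray,
    n_bins: int = N_POSITION_BINS,
    n_shifts: int = 1000,
    max_shift_bins: int = 12,
    percentile: float = 97.5,
    rng: np.random.Generator | None = None,
):
    """Signed circular decoding-error histogram with a circular-shift null.

    Each null iteration shifts every decoded position by an independent
    uniform draw in +/- ``max_shift_bins`` (i.e. +/-60 cm in 5 cm bins) and
    records the maximal bin proportion; observed bins above the null's
    ``percentile`` are flagged as over-represented.

    Returns ``(proportions, flagged, threshold, error_bins)`` where
    ``error_bins`` are the signed errors in bins (-n_bins/2 .. n_bins/2-1).
    """
    rng = rng or np.random.default_rng()
    decoded = np.asarray(decoded_bins, dtype=int)
    actual = np.asarray(actual_bins, dtype=int)
    half = n_bins // 2

    def signed_err(d):
        return (d - actual + half) % n_bins - half

    obs = signed_err(decoded)
    prop = np.bincount(obs + half, minlength=n_bins) / obs.size

    shifts = rng.integers(-max_shift_bins, max_shift_bins + 1,
                          size=(n_shifts, decoded.size))
    shifted = (decoded[None, :] + shifts - actual[None, :] + half) % n_bins
    null_max = np.empty(n_shifts)
    for k in range(n_shifts):
        null_max[k] = np.bincount(shifted[k], minlength=n_bins).max()
    null_max /= decoded.size
    thr = float(np.percentile(null_max, percentile))
    flagged = prop > thr
    return prop, flagged, thr, np.arange(-half, half)


# ---------------------------------------------------------------------------
# Candidate events and trajectory fits
# ---------------------------------------------------------------------------

def candidate_events(
    spikes: SpikeTable,
    intervals,
    bin_s: float = 0.001,
    hann_ms: float = 21.0,
    min_duration_s: float = 0.05,
    max_duration_s: float = 2.0,
) -> list[CandidateEvent]:
    """Candidate population events from smoothed multi-unit activity.

    MUA (pooled 1 ms spike counts, 21 ms Hanning smoothing) must exceed its
    mean over the supplied intervals; boundaries are shrunk inwards to the
    first/last bin containing a raw spike and events outside the 50 ms - 2 s
    duration band are discarded.
    """
    if spikes.n_units == 0:
        raise ValueError("candidate_events requires at least one unit")
    t_max = max(
        [e for _, e in intervals]
        + [t[-1] for t in spikes.spike_times.values() if t.size]
    )
    n = int(np.ceil(t_max / bin_s)) + 1
    raw = np.zeros(n)
    for st in spikes.spike_times.values():
        c, _ = np.histogram(st, bins=n, range=(0.0, n * bin_s))
        raw += c
    kernel = np.hanning(int(round(hann_ms / 1000.0 / bin_s)))
    kernel /= kernel.sum()
    mua = np.convolve(raw, kernel, mode="same")
    centers = (np.arange(n) + 0.5) * bin_s
    in_mask = _interval_mask(centers, intervals)
    if not np.any(in_mask):
        return []
    mean_mua = mua[in_mask].mean()

    above = (mua > mean_mua) & in_mask
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, n]

    out = []
    for s, e in zip(starts, ends):
        occupied = np.nonzero(raw[s:e] > 0)[0]
        if occupied.size == 0:
            continue
        s2, e2 = s + occupied[0], s + occupied[-1] + 1
        dur = (e2 - s2) * bin_s
        if min_duration_s <= dur <= max_duration_s:
            out.append(
                CandidateEvent(
                    start=s2 * bin_s, end=e2 * bin_s,
                    n_spikes=int(raw[s2:e2].sum()),
                )
            )
    return out


def fit_trajectory(
    posterior: PosteriorMatrix | np.ndarray,
    slope_grid: tuple = (-3.0, 3.0, 0.01),
) -> TrajectoryFit:
    """Posterior-weighted circular-linear regression of position on time step.

    For each candidate slope the phase maximizing the posterior-weighted mean
    resultant is closed-form; the best slope maximizes the resultant length.
    R-squared is one minus the ratio of the weighted circular residual
    variance to the slope-zero (stationary) residual variance.
    """
    p = posterior.p if isinstance(posterior, PosteriorMatrix) else np.asarray(posterior)
    if p.ndim != 2 or p.shape[0] < 3:
        raise ValueError("trajectory fit needs at least 3 time steps")
    S, n_bins = p.shape
    w = p / p.sum()
    theta = 2 * np.pi * (np.arange(n_bins) + 0.5) / n_bins
    t_steps = np.arange(S, dtype=float)

    lo, hi, step = slope_grid
    slopes = np.arange(lo, hi + step / 2, step)
    ang_slopes = 2 * np.pi * slopes / n_bins
    # resultant z(s) = sum_{t,x} w[t,x] exp(i(theta_x - s_ang t))
    phase_t = np.exp(-1j * np.outer(ang_slopes, t_steps))      # slopes x S
    pos_vec = (w * np.exp(1j * theta)[None, :]).sum(axis=1)    # per time step
    z = phase_t @ pos_vec                                      # per slope
    rho = np.abs(z)
    best = int(np.argmax(rho))
    # prefer the smaller |slope| on exact ties (stationary reading)
    ties = np.nonzero(np.isclose(rho, rho[best], rtol=0, atol=1e-12))[0]
    if ties.size > 1:
        best = int(ties[np.argmin(np.abs(slopes[ties]))])
    v_res = 1.0 - rho[best]
    i_zero = int(np.argmin(np.abs(slopes)))
    v_tot = 1.0 - rho[i_zero]
    if v_tot < 1e-12:
        r2 = 1.0 if v_res < 1e-12 else 0.0
    else:
        r2 = max(0.0, 1.0 - v_res / v_tot)
    return TrajectoryFit(
        slope=float(slopes[best]),
        phase=float(np.angle(z[best])),
        r_squared=float(min(1.0, r2)),
    )
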