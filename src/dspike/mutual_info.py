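"""Time-resolved mutual-information coupling between brain regions.

Regional spike counts in 5 ms bins over +/-200 ms around event peaks are
discretized into four uniform-count (quartile) states; plug-in mutual
information (log base 2) is computed per time bin across event trials, and
the mean over the -200..-100 ms baseline bins is subtracted.  Significance
comes from a Monte-Carlo null that permutes whole event trials of one
region, preserving each region's temporal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import EventTable, SpikeTable

MI_WINDOW_S = 0.2
MI_BIN_S = 0.005
N_MI_BINS = int(round(2 * MI_WINDOW_S / MI_BIN_S))  # 80

#: Peri-event bin centres (s, relative to the event peak).
BIN_CENTERS = (np.arange(N_MI_BINS) + 0.5) * MI_BIN_S - MI_WINDOW_S
#: Baseline bins: centres in [-200, -100) ms.
BASELINE_MASK = (BIN_CENTERS >= -0.2) & (BIN_CENTERS < -0.1)


@dataclass
class MiResult:
    region_pair: tuple
    delta_mi_max: float          # bits
    p_value: float
    n_trials: int
    timecourse: np.ndarray       # delta-MI per 5 ms bin
    n_sessions: int = 1
    significant: bool = field(init=False, default=False)


def discretize_counts(
    spikes: SpikeTable,
    events: EventTable,
    region: str,
    bin_s: float = MI_BIN_S,
    n_states: int = 4,
) -> np.ndarray:
    """Trials x time-bins state matrix for one region.

    Pooled regional spike counts per 5 ms bin are mapped to ``n_states``
    states by empirical uniform-count (quantile) boundaries computed over
    all trials and bins; counts equal to a boundary go to the lower state.
    """
    units = spikes.units_in_region(region)
    if not units:
        raise ValueError(f"no units in region {region!r}")
    n_bins = int(round(2 * MI_WINDOW_S / bin_s))
    counts = np.zeros((len(events), n_bins))
    for u in units:
        st = spikes.spike_times[u]
        for i, t in enumerate(events.peak_time):
            rel = st[
                np.searchsorted(st, t - MI_WINDOW_S):
                np.searchsorted(st, t + MI_WINDOW_S)
            ] - t
            if rel.size:
                idx = np.clip(
                    np.floor((rel + MI_WINDOW_S) / bin_s).astype(int), 0, n_bins - 1
                )
                np.add.at(counts[i], idx, 1.0)
    qs = np.quantile(counts, np.arange(1, n_states) / n_states)
    return np.searchsorted(qs, counts, side="left").astype(np.int8)


def mutual_information(joint: np.ndarray) -> float:
    """Plug-in MI (bits) of an explicit joint probability table."""
    p = np.asarray(joint, dtype=float)
    p = p / p.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def _mi_per_bin(states_a: np.ndarray, states_b: np.ndarray, n_states: int = 4) -> np.ndarray:
    """MI (bits) per time bin across trials; inputs are trials x bins."""
    T, B = states_a.shape
    codes = states_a.astype(np.int64) * n_states + states_b
    offset = np.arange(B) * n_states * n_states
    flat = (codes + offset[None, :]).ravel()
    tables = np.bincount(flat, minlength=n_states * n_states * B).reshape(
        B, n_states, n_states
    )
    p = tables / T
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p / (px * py))
    return np.nansum(term, axis=(1, 2))


def _baseline(mi: np.ndarray) -> np.ndarray:
    """Per-row baseline: mean over the -200..-100 ms bins when the row spans
    the full peri-event window, otherwise the overall mean."""
    if mi.shape[1] == N_MI_BINS:
        return mi[:, BASELINE_MASK].mean(axis=1)
    return mi.mean(axis=1)


def mutual_info_timecourse(
    states_a: np.ndarray, states_b: np.ndarray, n_states: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-subtracted MI timecourse.

    Returns ``(delta_mi, mi)`` per time bin; ``delta_mi`` has the mean over
    the -200..-100 ms bins removed.
    """
    if states_a.shape != states_b.shape:
        raise ValueError("state matrices must share trials and bins")
    if states_a.shape[0] < 2:
        raise ValueError("mutual information needs at least 2 trials")
    mi = _mi_per_bin(states_a, states_b, n_states)
    return mi - _baseline(mi[None, :])[0], mi


def mi_significance(
    states_a: np.ndarray,
    states_b: np.ndarray,
    n_shuffles: int = 5000,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
    region_pair: tuple = ("A", "B"),
    n_states: int = 4,
    chunk: int = 250,
) -> MiResult:
    """Monte-Carlo significance of the maximal delta-MI.

    The null permutes whole event trials (rows) of ``states_b``; the p-value
    uses the +1 correction, ``p = (1 + #{null >= obs}) / (1 + n_shuffles)``.
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    rng = rng or np.random.default_rng()
    dmi, _ = mutual_info_timecourse(states_a, states_b, n_states)
    obs = float(dmi.max())
    T, B = states_a.shape
    nss = n_states * n_states
    offset = (np.arange(B) * nss)[None, None, :]
    exceed = 0
    done = 0
    while done < n_shuffles:
        k = min(chunk, n_shuffles - done)
        perms = np.stack([rng.permutation(T) for _ in range(k)])
        codes = states_a[None, :, :].astype(np.int64) * n_states + states_b[perms]
        flat = (codes + offset + (np.arange(k) * B * nss)[:, None, None]).ravel()
        tables = np.bincount(flat, minlength=k * B * nss).reshape(k, B, n_states, n_states)
        p = tables / T
        px = p.sum(axis=3, keepdims=True)
        py = p.sum(axis=2, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = p * np.log2(p / (px * py))
        mi = np.nansum(term, axis=(2, 3))
        null_max = (mi - _baseline(mi)[:, None]).max(axis=1)
        exceed += int(np.sum(null_max >= obs))
        done += k
    p_val = (1 + exceed) / (1 + n_shuffles)
    res = MiResult(
        region_pair=tuple(region_pair), delta_mi_max=obs, p_value=p_val,
        n_trials=T, timecourse=dmi,
    )
    res.significant = p_val < alpha
    return res


def coupling_graph(
    results: list[MiResult],
    min_sessions: int = 5,
    alpha: float = 0.01,
) -> tuple[nx.Graph, dict]:
    """Weighted graph of significantly coupled region pairs.

    An edge is drawn for pairs with ``p < alpha`` and at least
    ``min_sessions`` contributing sessions; the weight is the maximal
    delta-MI.  The summary reports the percentage of significant pairs among
    those eligible and the summed delta-MI over significant pairs.
    """
    g = nx.Graph()
    eligible = [r for r in results if r.n_sessions >= min_sessions]
    n_sig = 0
    total_mi = 0.0
    for r in eligible:
        g.add_nodes_from(r.region_pair)
        if r.p_value < alpha:
            g.add_edge(*r.region_pair, weight=r.delta_mi_max)
            n_sig += 1
            total_mi += r.delta_mi_max
    summary = {
        "n_pairs_tested": len(eligible),
        "n_significant": n_sig,
        "percent_significant": 100.0 * n_sig / len(eligible) if eligible else 0.0,
        "sum_significant_delta_mi": total_mi,
    }
    return g, summary
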