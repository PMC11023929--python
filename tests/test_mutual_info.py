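"""Mutual information: brute-force formula oracle, discretization rules,
shuffle significance and the coupling graph."""

import numpy as np
import pytest

from dspike import mutual_info
from dspike.core import EventTable, SpikeTable, rng_for
from dspike.mutual_info import (
    MiResult,
    coupling_graph,
    discretize_counts,
    mi_significance,
    mutual_info_timecourse,
    mutual_information,
)


def brute_force_mi(joint):
    """Direct summation of sum_xy P(x,y) log2(P(x,y)/(P(x)P(y)))."""
    p = np.asarray(joint, dtype=float)
    p = p / p.sum()
    total = 0.0
    for x in range(p.shape[0]):
        for y in range(p.shape[1]):
            if p[x, y] > 0:
                total += p[x, y] * np.log2(
                    p[x, y] / (p[x].sum() * p[:, y].sum())
                )
    return total


@pytest.mark.parametrize(
    "joint",
    [
        np.array([[0.4, 0.1], [0.1, 0.4]]),
        np.eye(4) / 4.0,
        np.full((4, 4), 1 / 16.0),
        np.array([[0.5, 0.0], [0.25, 0.25]]),
    ],
)
def test_plugin_mi_matches_brute_force(joint):
    assert mutual_information(joint) == pytest.approx(brute_force_mi(joint),
                                                      abs=1e-12)


def test_known_mi_value():
    # [[.4,.1],[.1,.4]]: MI = 1 - H(0.2) = 0.2781 bits
    assert mutual_information([[0.4, 0.1], [0.1, 0.4]]) == pytest.approx(
        0.27807, abs=1e-4
    )


def test_yoked_uniform_streams_give_two_bits():
    """Identical 4-state uniform streams: MI = log2(4) = 2 bits per bin and
    the baseline-subtracted timecourse is identically zero."""
    states = np.tile(np.arange(4, dtype=np.int8), (25, 1)).T.reshape(100, 1)
    states = np.tile(states, (1, 80))
    dmi, mi = mutual_info_timecourse(states, states)
    np.testing.assert_allclose(mi, 2.0, atol=1e-12)
    np.testing.assert_allclose(dmi, 0.0, atol=1e-12)


def test_independent_streams_small_delta():
    rng = rng_for(0, "mi-indep")
    a = rng.integers(0, 4, size=(400, 80)).astype(np.int8)
    b = rng.integers(0, 4, size=(400, 80)).astype(np.int8)
    dmi, mi = mutual_info_timecourse(a, b)
    # plug-in bias is positive but baseline subtraction removes it
    assert np.abs(dmi).max() < 0.05
    assert mi.mean() < 0.05


def test_mi_symmetry_and_nonnegativity():
    rng = rng_for(1, "mi-sym")
    a = rng.integers(0, 4, size=(100, 80)).astype(np.int8)
    b = ((a + rng.integers(0, 2, a.shape)) % 4).astype(np.int8)
    _, mi_ab = mutual_info_timecourse(a, b)
    _, mi_ba = mutual_info_timecourse(b, a)
    np.testing.assert_allclose(mi_ab, mi_ba, atol=1e-12)
    assert np.all(mi_ab >= -1e-12)


def test_discretize_identity_on_uniform_four_counts():
    """Counts uniform over {0,1,2,3} map to states 0..3 identically."""
    rng = rng_for(2, "disc")
    counts = rng.permuted(np.tile(np.arange(4), 2000)).reshape(100, 80)
    spikes, events = _spikes_from_counts(counts, rng)
    states = discretize_counts(spikes, events, "R")
    np.testing.assert_array_equal(states, counts)


def _spikes_from_counts(counts, rng, region="R"):
    """One pooled unit whose 5 ms bin counts around each event equal
    ``counts`` exactly."""
    n_trials, n_bins = counts.shape
    event_times = 5.0 + 10.0 * np.arange(n_trials)
    times = []
    for i, te in enumerate(event_times):
        for b in range(n_bins):
            c = int(counts[i, b])
            if c:
                left = te - 0.2 + b * 0.005
                times.extend(left + rng.uniform(1e-6, 0.005 - 1e-6, c))
    spikes = SpikeTable({0: np.sort(times)}, {0: region})
    events = EventTable.from_times("DS2", event_times, amplitude=1.0)
    return spikes, events


def test_discretize_poisson_occupancy_matches_exact_oracle():
    """Poisson(2) counts under quartile binning with ties to the lower
    state: occupancies follow the exact pmf-derived values (~.41/.27/.18/.14),
    not a uniform 25 % split."""
    from scipy.stats import poisson

    rng = rng_for(3, "disc-poisson")
    counts = rng.poisson(2.0, size=(200, 80))
    spikes, events = _spikes_from_counts(counts, rng)
    states = discretize_counts(spikes, events, "R")
    occ = np.bincount(states.ravel(), minlength=4) / states.size
    # oracle: empirical quartiles of Poisson(2) are 1, 2, 3; ties go down
    expected = np.array([
        poisson.cdf(1, 2.0),
        poisson.pmf(2, 2.0),
        poisson.pmf(3, 2.0),
        1 - poisson.cdf(3, 2.0),
    ])
    np.testing.assert_allclose(occ, expected, atol=0.03)


def test_constant_counts_single_state():
    rng = rng_for(4, "disc-const")
    counts = np.full((50, 80), 3)
    spikes, events = _spikes_from_counts(counts, rng)
    states = discretize_counts(spikes, events, "R")
    assert len(np.unique(states)) == 1
    dmi, mi = mutual_info_timecourse(states, states)
    np.testing.assert_allclose(mi, 0.0, atol=1e-12)
    with pytest.raises(ValueError):
        discretize_counts(spikes, events, "NOPE")


def test_mi_significance_yoked_and_errors():
    rng = rng_for(5, "mi-sig")
    base = rng.integers(0, 4, size=(60, 80)).astype(np.int8)
    # event-locked coupling: yoked states in the post-event half only
    a = base.copy()
    b = rng.integers(0, 4, size=(60, 80)).astype(np.int8)
    b[:, 40:] = a[:, 40:]
    res = mi_significance(a, b, n_shuffles=400, rng=rng)
    assert res.p_value == pytest.approx(1 / 401)
    assert res.significant
    with pytest.raises(ValueError):
        mi_significance(a, b, n_shuffles=0)
    with pytest.raises(ValueError):
        mutual_info_timecourse(a[:1], b[:1])


def test_mi_significance_type_one_rate():
    """Independent streams: ~1 % of runs significant at alpha 0.01."""
    rng = rng_for(6, "mi-type1")
    hits = 0
    n_rep = 150
    for _ in range(n_rep):
        a = rng.integers(0, 4, size=(40, 80)).astype(np.int8)
        b = rng.integers(0, 4, size=(40, 80)).astype(np.int8)
        res = mi_significance(a, b, n_shuffles=300, rng=rng)
        hits += res.significant
    rate = hits / n_rep
    assert rate < 0.04  # 1 % nominal; 3 binomial SD + slack at 150 reps


def test_coupled_pair_recovery_end_to_end():
    """Four regions, one pair sharing per-event gain variability: the
    coupling graph recovers exactly that edge."""
    rng = rng_for(7, "mi-system")
    n_trials, pooled_hz, gain = 300, 240.0, 4.0
    event_times = 5.0 + 10.0 * np.arange(n_trials)
    edges = np.arange(-0.2, 0.2001, 0.005)
    kernel = np.exp(-0.5 * ((edges[:-1] + 0.0025) / 0.05) ** 2)
    shared = rng.uniform(0.0, 1.0, n_trials)
    spikes, regions = {}, {}
    for uid, reg in enumerate(("A", "B", "C", "D")):
        s = shared if reg in ("A", "B") else rng.uniform(0.0, 1.0, n_trials)
        times = []
        for ti, te in enumerate(event_times):
            lam = pooled_hz * 0.005 * (1.0 + gain * s[ti] * kernel)
            c = rng.poisson(lam)
            for b in np.nonzero(c)[0]:
                times.extend(te + edges[b] + rng.uniform(0, 0.005, c[b]))
        spikes[uid] = np.sort(times)
        regions[uid] = reg
    table = SpikeTable(spikes, regions)
    events = EventTable.from_times("DS2", event_times, amplitude=1.0)
    states = {r: discretize_counts(table, events, r) for r in "ABCD"}
    results = []
    for i, x in enumerate("ABCD"):
        for y in "ABCD"[i + 1:]:
            results.append(
                mi_significance(states[x], states[y], n_shuffles=500,
                                rng=rng, region_pair=(x, y))
            )
    graph, summary = coupling_graph(results, min_sessions=1)
    assert list(graph.edges) == [("A", "B")]
    assert summary["percent_significant"] == pytest.approx(100 / 6, abs=1e-9)


def test_coupling_graph_rules():
    def make(pair, p, n_sessions):
        r = MiResult(pair, 0.5, p, 100, np.zeros(80), n_sessions)
        return r

    results = [
        make(("A", "B"), 0.001, 6),
        make(("A", "C"), 0.001, 2),   # too few sessions -> excluded
        make(("B", "C"), 0.5, 7),
    ]
    g, s = coupling_graph(results, min_sessions=5)
    assert list(g.edges) == [("A", "B")]
    assert s["n_pairs_tested"] == 2 and s["percent_significant"] == 50.0
    g0, s0 = coupling_graph([], min_sessions=5)
    assert s0["percent_significant"] == 0.0 and not g0.edges
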