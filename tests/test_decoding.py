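"""Bayesian decoder oracle, tuning curves, candidate events, trajectory
fits and the error-overrepresentation null."""

import numpy as np
import pytest

from dspike import decoding, perievent
from dspike.core import BehaviorTrace, SpikeTable, rng_for
from dspike.decoding import (
    PosteriorMatrix,
    TuningCurves,
    candidate_events,
    decode,
    error_overrepresentation,
    fit_trajectory,
    tuning_curves,
)


def brute_force_posterior(counts, rates, tau):
    """Explicit Poisson-product enumeration over position bins."""
    from math import exp, factorial

    counts = np.asarray(counts)
    n_bins = rates.shape[1]
    post = np.empty(n_bins)
    for x in range(n_bins):
        p = 1.0
        for i, n in enumerate(counts):
            lam = rates[i, x] * tau
            p *= lam ** n * exp(-lam) / factorial(int(n))
        post[x] = p
    return post / post.sum()


def test_decode_matches_brute_force_enumeration():
    """decode equals the Poisson-product oracle on all <=3-unit / <=5-bin
    instances drawn over a grid of rates and counts."""
    rng = rng_for(0, "decode-oracle")
    for n_units in (1, 2, 3):
        for n_bins in (2, 3, 5):
            for _ in range(20):
                rates = rng.uniform(0.01, 30.0, size=(n_units, n_bins))
                counts = rng.integers(0, 5, size=n_units)
                curves = TuningCurves(list(range(n_units)), rates,
                                      np.ones(n_bins))
                post = decode(counts, curves, tau=0.02)
                oracle = brute_force_posterior(counts, rates, 0.02)
                np.testing.assert_allclose(post, oracle, rtol=1e-9, atol=1e-12)


def test_decode_hand_case_and_uniform():
    rates = np.array([[10.0, 1.0, 1.0], [1.0, 1.0, 10.0]])
    curves = TuningCurves([0, 1], rates, np.ones(3))
    post = decode(np.array([1, 0]), curves, tau=0.02)
    oracle = brute_force_posterior([1, 0], rates, 0.02)
    np.testing.assert_allclose(post, oracle, rtol=1e-9)
    assert np.argmax(post) == 0
    flat = TuningCurves([0, 1], np.full((2, 24), 3.0), np.ones(24))
    post = decode(np.array([2, 1]), flat)
    np.testing.assert_allclose(post, 1 / 24.0, atol=1e-12)


def test_posterior_rows_sum_to_one_and_scale_invariance():
    rng = rng_for(1, "decode-simplex")
    rates = rng.uniform(0.01, 20.0, size=(10, 24))
    curves = TuningCurves(list(range(10)), rates, np.ones(24))
    counts = rng.integers(0, 4, size=(50, 10))
    post = decode(counts, curves)
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(post >= 0)
    # a unit with flat tuning contributes an x-independent factor and
    # cannot change the posterior
    rates_flat = np.vstack([rates, np.full((1, 24), 4.0)])
    curves_flat = TuningCurves(list(range(11)), rates_flat, np.ones(24))
    counts_flat = np.column_stack([counts, rng.integers(0, 4, size=50)])
    np.testing.assert_allclose(decode(counts_flat, curves_flat), post,
                               rtol=1e-9, atol=1e-12)


def _behavior_laps(dur=300.0, fs=50.0, speed=15.0):
    n = int(dur * fs)
    t = np.arange(n) / fs
    pos = (speed * t) % 120.0
    return BehaviorTrace(t=t, position=pos, speed=np.full(n, speed),
                         pupil_diameter=np.ones(n), pupil_speed=np.zeros(n),
                         facial_motion=np.zeros(n))


def test_tuning_curves_localized_and_flat_units():
    rng = rng_for(2, "tuning")
    beh = _behavior_laps()
    loco = [(0.0, 300.0)]
    # unit firing only near 40 cm; homogeneous unit at 4 Hz
    on_times = beh.t[(np.abs(beh.position - 42.5) < 2.4)]
    u0 = np.sort(rng.choice(on_times, size=200) + rng.uniform(0, 0.01, 200))
    u1 = np.sort(rng.uniform(0, 300.0, rng.poisson(4.0 * 300)))
    table = SpikeTable({0: u0, 1: u1}, {0: "CA1", 1: "CA1"})
    curves = tuning_curves(table, beh, loco)
    assert np.argmax(curves.rate_by_bin[0]) == 8  # bin centred at 42.5 cm
    assert curves.rate_by_bin[0].max() > 5 * np.median(curves.rate_by_bin[0])
    flat = curves.rate_by_bin[1]
    assert flat.std() / flat.mean() < 0.3
    assert np.all(curves.rate_by_bin >= 0.01)  # floor


def test_tuning_curve_zero_occupancy_error():
    beh = _behavior_laps(dur=10.0)
    table = SpikeTable({0: np.array([1.0])}, {0: "CA1"})
    with pytest.raises(ValueError, match="bin"):
        tuning_curves(table, beh, [(0.0, 2.0)])  # only part of the track


def test_preferred_position_recovery(session600):
    """Recovered preferred bin matches the injected tuning for >= 95 % of
    place cells."""
    session, truth = session600
    _, loco = perievent.segment_motion_state(session.behavior, 1.0)
    tun = truth.unit_tuning
    ids = tun.loc[tun.is_place == 1, "unit_id"].astype(int).tolist()
    curves = tuning_curves(session.spikes, session.behavior, loco, unit_ids=ids)
    pref_true = tun.set_index("unit_id").loc[ids, "pref_cm"].to_numpy()
    pref_rec = curves.bin_centers[np.argmax(curves.rate_by_bin, axis=1)]
    err = np.abs(((pref_rec - pref_true + 60) % 120) - 60)
    assert np.mean(err <= 5.0) >= 0.95


def test_candidate_events_rules():
    rng = rng_for(3, "mua")
    dur = 120.0
    spikes = {
        u: np.sort(rng.uniform(0, dur, rng.poisson(0.5 * dur)))
        for u in range(20)
    }
    # one strong 100 ms burst at t = 60 s
    for u in range(20):
        spikes[u] = np.sort(np.r_[spikes[u], 60.0 + rng.uniform(0, 0.1, 10)])
    table = SpikeTable(spikes, {u: "X" for u in spikes})
    events = candidate_events(table, [(0.0, dur)])
    hits = [e for e in events if e.start < 60.05 < e.end + 0.05]
    assert len(hits) == 1
    assert 0.05 <= hits[0].duration <= 0.3
    # single spike in silence -> below minimum duration, discarded
    lone = SpikeTable({0: np.array([5.0])}, {0: "X"})
    assert candidate_events(lone, [(0.0, 10.0)]) == []


def test_candidate_events_unit_permutation_invariance():
    rng = rng_for(4, "mua-perm")
    spikes = {u: np.sort(rng.uniform(0, 60.0, 120)) for u in range(8)}
    t1 = SpikeTable(spikes, {u: "X" for u in spikes})
    t2 = SpikeTable({7 - u: v for u, v in spikes.items()}, {u: "X" for u in spikes})
    e1 = candidate_events(t1, [(0.0, 60.0)])
    e2 = candidate_events(t2, [(0.0, 60.0)])
    assert [(e.start, e.end) for e in e1] == [(e.start, e.end) for e in e2]


def brute_force_circular_fit(p, slopes, n_phase=720):
    """Independent grid search over (slope, phase) maximizing the
    posterior-weighted residual concentration."""
    S, n_bins = p.shape
    w = p / p.sum()
    theta = 2 * np.pi * (np.arange(n_bins) + 0.5) / n_bins
    t = np.arange(S)
    phases = np.linspace(-np.pi, np.pi, n_phase, endpoint=False)
    best = (None, -np.inf)
    for s in slopes:
        pred = 2 * np.pi * s / n_bins * t
        for phi in phases:
            conc = float(np.sum(w * np.cos(theta[None, :] - pred[:, None] - phi)))
            if conc > best[1]:
                best = (s, conc)
    return best[0]


def test_fit_trajectory_cases_and_oracle():
    # moving delta: slope 1 bin/step, R^2 = 1
    p = np.zeros((10, 24))
    p[np.arange(10), np.arange(10)] = 1.0
    fit = fit_trajectory(p)
    assert fit.slope == pytest.approx(1.0, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
    # stationary delta: slope 0 (the DS2 signature)
    p0 = np.zeros((10, 24))
    p0[:, 5] = 1.0
    fit0 = fit_trajectory(p0)
    assert fit0.slope == pytest.approx(0.0, abs=1e-6)
    # noisy sloped posterior: equals the brute-force (slope, phase) search
    rng = rng_for(5, "traj")
    true_slope = -0.6
    p = np.full((12, 24), 0.01)
    for t in range(12):
        mu = (3 + true_slope * t) % 24
        p[t] += np.exp(-0.5 * (((np.arange(24) - mu + 12) % 24 - 12) / 1.0) ** 2)
        p[t] += rng.uniform(0, 0.05, 24)
        p[t] /= p[t].sum()
    fit = fit_trajectory(p)
    oracle = brute_force_circular_fit(p, np.arange(-3.0, 3.0001, 0.01))
    assert fit.slope == pytest.approx(oracle, abs=0.02)
    assert abs(fit.slope - true_slope) / abs(true_slope) < 0.1
    with pytest.raises(ValueError):
        fit_trajectory(p[:2])


def test_error_overrepresentation_perfect_and_null():
    rng = rng_for(6, "err")
    actual = rng.integers(0, 24, 200)
    prop, flagged, thr, bins = error_overrepresentation(
        actual.copy(), actual, rng=rng
    )
    assert prop[bins == 0][0] == 1.0 and flagged[bins == 0][0]
    # uniform random decoding: no bin flagged in the large majority of runs
    any_flagged = []
    for _ in range(40):
        dec = rng.integers(0, 24, 200)
        _, fl, _, _ = error_overrepresentation(dec, actual, n_shifts=400,
                                               rng=rng)
        any_flagged.append(fl.any())
    assert np.mean(any_flagged) < 0.2  # nominal 2.5 % family-wise
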