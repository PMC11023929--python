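"""Peri-event z-scores, modulation shuffles, high-firing peaks, behaviour
change tests, motion segmentation and dF/F baselining."""

import numpy as np
import pytest

from dspike import perievent
from dspike.core import BehaviorTrace, EventTable, SpikeTable, rng_for
from dspike.perievent import (
    behavior_change_test,
    dff,
    high_firing_peaks,
    modulation_test,
    perievent_zscores,
    segment_motion_state,
)

DUR = 400.0


def _poisson_table(rng, n_units, rate_fn, dur=DUR, region="X"):
    spikes = {}
    for u in range(n_units):
        rate = rate_fn(u)
        spikes[u] = np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))
    return SpikeTable(spikes, {u: region for u in range(n_units)})


def _events(rng, n=200, dur=DUR):
    return EventTable.from_times(
        "DS2", np.sort(rng.uniform(10, dur - 10, n)), amplitude=1.0
    )


def test_null_zscores_flat():
    """Homogeneous Poisson units at random event times: the event-averaged
    z-trace stays near zero in every bin."""
    rng = rng_for(0, "zscore-null")
    events = _events(rng)
    n_units = 200
    spikes = _poisson_table(rng, n_units, lambda u: 5.0)
    rates = perievent_zscores(spikes, events, duration=DUR)
    traces = np.stack([r.mean_trace for r in rates.values()])
    assert traces.shape[1] == 40
    # per-unit bin z has SD ~1 over 200 events; the unit average shrinks it
    # by sqrt(n_units), so the 40-bin max stays well under 0.2
    assert np.abs(traces.mean(axis=0)).max() < 0.2


def test_gain_unit_peaks_inside_kernel():
    rng = rng_for(1, "zscore-gain")
    events = _events(rng)
    base = np.sort(rng.uniform(0, DUR, rng.poisson(2.0 * DUR)))
    extra = np.concatenate(
        [t + rng.uniform(-0.05, 0.05, rng.poisson(1.0)) for t in events.peak_time]
    )
    spikes = SpikeTable({0: np.sort(np.r_[base, extra])}, {0: "X"})
    r = perievent_zscores(spikes, events, duration=DUR)[0]
    peak_bin = np.argmax(r.mean_trace)
    assert r.peak_z > 1.0
    assert 15 <= peak_bin <= 24  # within +/-50 ms of the event


def test_zero_spike_unit_excluded_and_relabeling_invariance():
    rng = rng_for(2, "zscore-empty")
    events = _events(rng)
    spikes = SpikeTable(
        {3: np.sort(rng.uniform(0, DUR, 800)), 9: np.array([])},
        {3: "X", 9: "X"},
    )
    res = perievent_zscores(spikes, events, duration=DUR)
    assert 9 not in res and 3 in res
    relabeled = SpikeTable({17: spikes.spike_times[3]}, {17: "Y"})
    res2 = perievent_zscores(relabeled, events, duration=DUR)
    np.testing.assert_allclose(res2[17].rate_z, res[3].rate_z)


def test_modulation_single_spike_not_significant():
    rng = rng_for(3, "mod-degenerate")
    events = _events(rng, n=50)
    spikes = SpikeTable({0: np.array([events.peak_time[0]])}, {0: "X"})
    res = modulation_test(spikes, events, rng=rng, duration=DUR)
    assert not res[0].significant


def test_modulation_power_at_5x_gain():
    """Multiplicative 5x gain (Hanning kernel, +/-50 ms) on 2 Hz units is
    detected in > 90 % of units with 200 events."""
    rng = rng_for(4, "mod-power")
    events = _events(rng)
    grid = np.arange(0, DUR, 0.001) + 0.0005
    kernel = np.zeros(grid.size)
    w = np.hanning(100)
    for t in events.peak_time:
        i = int(t * 1000) - 50
        kernel[i: i + 100] += w
    spikes = {}
    for u in range(60):
        lam = 2.0 * (1.0 + 4.0 * np.minimum(kernel, 1.0)) * 0.001
        c = rng.poisson(lam)
        idx = np.nonzero(c)[0]
        spikes[u] = np.sort(
            np.repeat(idx, c[idx]) * 0.001 + rng.uniform(0, 0.001, c[idx].sum())
        )
    table = SpikeTable(spikes, {u: "X" for u in spikes})
    res = modulation_test(table, events, n_shuffles=1000, rng=rng, duration=DUR)
    assert np.mean([r.significant for r in res.values()]) > 0.9


def test_high_firing_peaks_flags_bursts():
    rng = rng_for(5, "hf")
    burst_times = np.arange(20.0, 380.0, 20.0)
    spikes = {}
    for u in range(20):
        base = rng.uniform(0, DUR, rng.poisson(1.0 * DUR))
        bursts = np.concatenate(
            [t + rng.uniform(0, 0.01, 10) for t in burst_times]
        )
        spikes[u] = np.sort(np.r_[base, bursts])
    table = SpikeTable(spikes, {u: "X" for u in spikes})
    ev = high_firing_peaks(table, duration=DUR)
    recall = np.mean(
        [np.min(np.abs(ev.peak_time - t)) < 0.02 for t in burst_times]
    )
    assert recall == 1.0
    assert len(ev) <= int(0.001 * DUR / 0.01) + len(burst_times)
    with pytest.raises(ValueError):
        high_firing_peaks(SpikeTable({}, {}))


def _behavior(rng, dur=DUR, fs=50.0, noise=1.0):
    n = int(dur * fs)
    return BehaviorTrace(
        t=np.arange(n) / fs,
        position=np.zeros(n), speed=np.zeros(n),
        pupil_diameter=np.full(n, 5.0),
        pupil_speed=np.abs(rng.normal(0, noise, n)),
        facial_motion=np.abs(rng.normal(0, noise, n)),
    )


def test_behavior_change_step_oracle():
    """A brief transient at each event: the measured change equals the
    window-overlap oracle and every event is flagged."""
    rng = rng_for(6, "bstep")
    beh = _behavior(rng, noise=0.01)
    events = EventTable.from_times(
        "DS2", np.arange(20.0, 380.0, 10.0), amplitude=1.0
    )
    fs, amp, dur_tr = 50.0, 1.0, 0.12
    for t in events.peak_time:
        i0 = int(np.ceil(t * fs))
        beh.pupil_speed[i0: i0 + int(dur_tr * fs)] += amp
    # oracle: fraction of the post window [-20, 85] ms covered by [0, 120] ms
    expected = amp * 0.085 / 0.105
    ch, fl, thr, _ = behavior_change_test(beh, events, "pupil_speed", rng=rng)
    assert np.mean(ch) == pytest.approx(expected, rel=0.15)
    assert fl.all()


def test_behavior_change_constant_trace():
    rng = rng_for(7, "bconst")
    beh = _behavior(rng, noise=0.0)
    beh.pupil_speed[:] = 2.0
    events = EventTable.from_times("DS2", np.arange(20.0, 380.0, 10.0),
                                   amplitude=1.0)
    ch, fl, thr, _ = behavior_change_test(beh, events, "pupil_speed", rng=rng)
    np.testing.assert_allclose(ch, 0.0, atol=1e-12)
    assert not fl.any()


def test_behavior_change_null_rate():
    """White-noise trace: ~2.5 % of events flagged (two-sided 97.5th
    percentile construction)."""
    rng = rng_for(8, "bnull")
    flags = []
    for _ in range(20):
        beh = _behavior(rng)
        events = EventTable.from_times(
            "DS2", np.sort(rng.uniform(5, DUR - 5, 150)), amplitude=1.0
        )
        _, fl, _, _ = behavior_change_test(beh, events, "pupil_speed", rng=rng)
        flags.append(fl.mean())
    rate = np.mean(flags)
    # 3 binomial SDs around 0.025 over 3000 event tests
    assert abs(rate - 0.025) < 3 * np.sqrt(0.025 * 0.975 / 3000) + 0.002


def test_behavior_edge_events_skipped():
    rng = rng_for(9, "bedge")
    beh = _behavior(rng)
    events = EventTable.from_times("DS2", np.array([0.5, 100.0]), amplitude=1.0)
    ch, fl, thr, used = behavior_change_test(beh, events, "pupil_speed", rng=rng)
    assert used.tolist() == [False, True] and ch.size == 1


def test_segment_motion_state():
    n = 400
    t = np.arange(n) * 0.02
    speed = np.where((t // 1).astype(int) % 2 == 0, 0.0, 5.0)
    beh = BehaviorTrace(t=t, position=np.zeros(n), speed=speed,
                        pupil_diameter=np.ones(n), pupil_speed=np.zeros(n),
                        facial_motion=np.zeros(n))
    immob, loco = segment_motion_state(beh, 1.0)
    assert len(immob) == 4 and len(loco) == 4
    for s, e in immob:
        assert e - s == pytest.approx(1.0, abs=0.03)
    total = sum(e - s for s, e in immob + loco)
    assert total == pytest.approx(n * 0.02, abs=1e-9)
    # all-zero speed -> single immobility interval
    beh2 = BehaviorTrace(t=t, position=np.zeros(n), speed=np.zeros(n),
                         pupil_diameter=np.ones(n), pupil_speed=np.zeros(n),
                         facial_motion=np.zeros(n))
    immob2, loco2 = segment_motion_state(beh2, 1.0)
    assert len(immob2) == 1 and not loco2


def test_immobile_time_monotone_in_threshold():
    rng = rng_for(10, "seg-mono")
    n = 2000
    beh = BehaviorTrace(
        t=np.arange(n) * 0.02, position=np.zeros(n),
        speed=np.abs(rng.normal(1.0, 1.0, n)),
        pupil_diameter=np.ones(n), pupil_speed=np.zeros(n),
        facial_motion=np.zeros(n),
    )
    times = []
    for thr in (0.5, 1.0, 2.0):
        immob, _ = segment_motion_state(beh, thr)
        times.append(sum(e - s for s, e in immob))
    assert times[0] <= times[1] <= times[2]


def test_dff_polynomial_baseline():
    t = np.linspace(0, 10, 500)
    cubic = 5.0 + 0.5 * t - 0.02 * t**2 + 0.001 * t**3
    np.testing.assert_allclose(dff(cubic, t), 0.0, atol=1e-10)
    np.testing.assert_allclose(dff(np.full(100, 3.0)), 0.0, atol=1e-12)
    # pulse orthogonalized against the cubic basis: the baseline fit then
    # recovers the cubic exactly and dF/F equals the pulse analytically
    pulse = np.zeros_like(t)
    pulse[200:220] = 1.0
    basis = np.vander(t, 4, increasing=True)
    q = cubic * 0.2 * pulse
    q_perp = q - basis @ np.linalg.lstsq(basis, q, rcond=None)[0]
    out = dff(cubic + q_perp, t)
    np.testing.assert_allclose(out, q_perp / cubic, atol=1e-9)
    assert out[205:215].mean() == pytest.approx(0.2, rel=0.15)
    with pytest.raises(ValueError):
        dff(np.linspace(1.0, -1.0, 100))
    with pytest.raises(ValueError):
        dff(np.ones(3))
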