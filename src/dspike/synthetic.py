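"""Synthetic laminar-LFP sessions with known ground truth.

The generator emulates the structure the analysis pipeline is built to
recover: dentate spikes (DS) with laminar current sinks at the outer (DS1) or
middle (DS2) molecular layer, CA1 sharp-wave ripples (SPW-R), place-tuned
Poisson spike trains with event-locked rate modulation, stationary
current-location reactivation during DS2 versus sequential replay during
SPW-R, and arousal transients (pupil / facial motion) following DS2.

Design of the DS template: the laminar profile is specified in CSD space --
a Gaussian sink at the target molecular-layer channel with a deeper Gaussian
source (granule-layer return current) -- and integrated twice to voltage, so
the classification ground truth is exact by construction and the hilus
channels carry the familiar positive voltage peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .core import (
    BehaviorTrace,
    EventTable,
    LfpRecording,
    SpikeTable,
    StimulusLog,
    circular_distance,
    rng_for,
)


# ---------------------------------------------------------------------------
# Probe layout
# ---------------------------------------------------------------------------

def default_probe_labels(n_channels: int = 32) -> list[str]:
    """Anatomical labels for a 32-contact probe spanning CA1 into the hilus."""
    if n_channels != 32:
        raise ValueError("the default laminar layout is defined for 32 channels")
    labels = (
        ["CA1 stratum oriens"] * 4
        + ["CA1 pyramidal"]
        + ["CA1 radiatum"] * 4
        + ["CA1 lacunosum-moleculare"]
        + ["fissure"]
        + ["outer molecular layer"] * 3
        + ["middle molecular layer"] * 3
        + ["inner molecular layer"] * 2
        + ["granule layer"] * 3
        + ["hilus"] * 10
    )
    assert len(labels) == 32
    return labels


#: Key channel indices of the default layout.
PYRAMIDAL_CHANNEL = 4
FISSURE_CHANNEL = 10
DS1_SINK_CHANNEL = 12   # outer molecular layer (shallower)
DS2_SINK_CHANNEL = 15   # middle molecular layer (deeper)
GRANULE_LAST_CHANNEL = 21
HILUS_CHANNEL = 26
CSD_CHANNEL_RANGE = (FISSURE_CHANNEL, GRANULE_LAST_CHANNEL)


# ---------------------------------------------------------------------------
# Parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Generative conditions of a synthetic session.

    Rates are per second of immobility; amplitudes in millivolts; the track
    is a 120 cm circular treadmill.
    """

    n_channels: int = 32
    fs: float = 1250.0
    duration: float = 600.0
    channel_spacing_um: float = 50.0

    # event rates (Hz, during immobility)
    rate_spwr: float = 0.3
    rate_ds2: float = 0.3
    rate_ds1: float = 0.05
    min_event_separation: float = 0.25
    edge_margin: float = 0.3

    # DS template
    ds_amplitude_mv: float = 2.0
    ds_width_ms: float = 25.0
    ds1_sink_channel: int = DS1_SINK_CHANNEL
    ds2_sink_channel: int = DS2_SINK_CHANNEL

    # SPW-R template
    ripple_freq_hz: float = 150.0
    ripple_duration_ms: float = 60.0
    ripple_amplitude_mv: float = 0.25
    sharpwave_amplitude_mv: float = 0.15

    # background noise
    noise_sd_mv: float = 0.1
    noise_exponent: float = 1.0
    common_mode_frac: float = 0.3
    noise_spatial_sigma_ch: float = 1.5

    # units
    n_units: int = 100
    fraction_place_cells: float = 0.5
    place_peak_rate_hz: float = 15.0
    place_sigma_cm: float = 8.0
    baseline_rate_range_hz: tuple = (0.5, 2.0)
    ds2_gain: float = 5.0
    ds1_gain: float = 3.0
    spwr_gain: float = 3.0
    modulation_prob: float = 0.5
    # per-event strength jitter (uniform 1 +/- this), shared by every unit
    # modulated by that event; this trial-to-trial covariability is what
    # couples regions in the mutual-information sense
    event_strength_jitter: float = 0.5
    event_kernel_halfwidth_ms: float = 50.0
    # place cells reactivate their field at the animal's current position
    # during DS2, mirroring the replay model (additive Gaussian profile)
    ds2_reactivation_peak_hz: float = 80.0

    # replay
    replay_peak_rate_hz: float = 80.0
    replay_steps: int = 10
    replay_step_ms: float = 20.0
    replay_slope_range_cm: tuple = (5.0, 15.0)

    # behaviour
    behavior_fs: float = 50.0
    track_length_cm: float = 120.0
    run_speed_cm_s: float = 15.0
    immobile_bout_mean_s: float = 12.0
    run_bout_mean_s: float = 8.0
    min_bout_s: float = 3.0
    speed_threshold_cm_s: float = 1.0
    pupil_dilation_amp: float = 1.0
    # the arousal burst (pupil speed / facial twitch) is brief -- confined to
    # the first ~100 ms after the event -- while the dilation itself is slow
    arousal_transient_s: float = 0.12
    dilation_transient_s: float = 1.5

    # evoked stimulation (off by default)
    n_stim_trials: int = 0
    evoked_prob: float = 0.8
    evoked_latency_s: float = 0.04
    evoked_latency_jitter_s: float = 0.01

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for r in (self.rate_spwr, self.rate_ds2, self.rate_ds1):
            if r < 0:
                raise ValueError("event rates must be >= 0")
        for s in (self.ds1_sink_channel, self.ds2_sink_channel):
            if not 1 <= s < self.n_channels - 4:
                raise ValueError(f"sink channel {s} outside probe interior")


@dataclass
class GroundTruth:
    """Everything the pipeline is supposed to recover.

    ``injected_events`` carries per-event extras: ``position_cm`` and
    ``pupil_amp`` for DS2, ``replay_slope_cm_per_step`` / ``replay_start_cm``
    for SPW-R, and ``evoked`` (0/1).
    """

    injected_events: EventTable
    unit_tuning: pd.DataFrame
    unit_modulation: pd.DataFrame
    stimuli: StimulusLog = field(default_factory=StimulusLog.empty)

    def __post_init__(self) -> None:
        ut = self.unit_tuning
        if len(ut):
            if (ut["sigma_cm"] <= 0).any():
                raise ValueError("tuning widths must be positive")
            if (ut["peak_hz"] < ut["baseline_hz"]).any():
                raise ValueError("peak rate must be >= baseline rate")

    @property
    def replay_truth(self) -> pd.DataFrame:
        ev = self.injected_events.of_kind("SPWR")
        return pd.DataFrame(
            {
                "peak_time": ev.peak_time,
                "slope_cm_per_step": ev.extra["replay_slope_cm_per_step"],
                "start_cm": ev.extra["replay_start_cm"],
            }
        )

    @property
    def ds2_truth(self) -> pd.DataFrame:
        ev = self.injected_events.of_kind("DS2")
        return pd.DataFrame(
            {"peak_time": ev.peak_time, "position_cm": ev.extra["position_cm"]}
        )

    @property
    def arousal_truth(self) -> pd.DataFrame:
        ev = self.injected_events.of_kind("DS2")
        return pd.DataFrame(
            {"peak_time": ev.peak_time, "pupil_amp": ev.extra["pupil_amp"]}
        )


@dataclass
class SessionData:
    """In-memory bundle of one synthetic session."""

    lfp: LfpRecording
    spikes: SpikeTable
    behavior: BehaviorTrace
    stimuli: StimulusLog


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------

def _bout_schedule(params: SimParams) -> list[tuple[float, float, bool]]:
    """Alternating (start, end, is_immobile) bouts covering the session."""
    rng = rng_for(params.rng_seed, "bouts")
    bouts = []
    t, immobile = 0.0, True
    while t < params.duration:
        mean = params.immobile_bout_mean_s if immobile else params.run_bout_mean_s
        dur = max(params.min_bout_s, rng.exponential(mean))
        end = min(t + dur, params.duration)
        bouts.append((t, end, immobile))
        t, immobile = end, not immobile
    return bouts


def immobility_intervals(params: SimParams) -> list[tuple[float, float]]:
    return [(s, e) for s, e, imm in _bout_schedule(params) if imm]


def generate_behavior(params: SimParams, truth: GroundTruth | None = None) -> BehaviorTrace:
    """Laps on the circular track interleaved with immobility, plus pupil and
    facial-motion traces; each DS2 in ``truth`` adds an arousal transient."""
    rng = rng_for(params.rng_seed, "behavior")
    dt = 1.0 / params.behavior_fs
    n = int(round(params.duration * params.behavior_fs))
    t = np.arange(n) * dt

    speed = np.abs(rng.normal(0.0, 0.05, n))  # immobile jitter baseline
    for s, e, imm in _bout_schedule(params):
        if imm:
            continue
        i0, i1 = int(s * params.behavior_fs), int(e * params.behavior_fs)
        seg = np.full(i1 - i0, params.run_speed_cm_s)
        ramp = min(int(0.5 * params.behavior_fs), max(1, (i1 - i0) // 2))
        seg[:ramp] *= np.linspace(0.2, 1.0, ramp)
        seg[-ramp:] *= np.linspace(1.0, 0.2, ramp)
        seg += rng.normal(0.0, 0.5, i1 - i0)
        speed[i0:i1] = np.maximum(seg, params.speed_threshold_cm_s + 0.5)

    position = np.cumsum(speed) * dt % params.track_length_cm

    # slow mean-reverting pupil diameter (OU process)
    pupil = np.empty(n)
    pupil[0] = 5.0
    tau, sig = 5.0, 0.15
    for i in range(1, n):
        pupil[i] = pupil[i - 1] + (5.0 - pupil[i - 1]) / tau * dt \
            + sig * np.sqrt(dt) * rng.standard_normal()
    pupil_speed = np.abs(rng.normal(0.0, 0.05, n))
    facial = np.abs(rng.normal(0.0, 0.08, n))

    if truth is not None:
        ds2 = truth.injected_events.of_kind("DS2")
        amps = ds2.extra.get("pupil_amp", np.full(len(ds2), params.pupil_dilation_amp))
        for te, amp in zip(ds2.peak_time, amps):
            i0 = int(np.ceil(te * params.behavior_fs))
            i1 = min(n, int((te + params.arousal_transient_s) * params.behavior_fs))
            pupil_speed[i0:i1] += amp
            facial[i0:i1] += amp
            # slower dilation of the diameter itself
            j1 = min(n, i0 + int(params.dilation_transient_s * params.behavior_fs))
            w = np.hanning(2 * int(params.dilation_transient_s * params.behavior_fs))
            if j1 > i0:
                pupil[i0:j1] += amp * w[: j1 - i0]

    return BehaviorTrace(
        t=t, position=position, speed=speed, pupil_diameter=pupil,
        pupil_speed=pupil_speed, facial_motion=facial,
        track_length=params.track_length_cm,
    )


# ---------------------------------------------------------------------------
# Event times and ground truth
# ---------------------------------------------------------------------------

def _usable_immobile(params: SimParams) -> list[tuple[float, float]]:
    m = params.edge_margin
    out = []
    for s, e in immobility_intervals(params):
        s2, e2 = max(s + m, m), min(e - m, params.duration - m)
        if e2 > s2:
            out.append((s2, e2))
    return out


def _draw_times(rng, rate, intervals) -> np.ndarray:
    total = sum(e - s for s, e in intervals)
    n = rng.poisson(rate * total)
    u = rng.uniform(0.0, total, n)
    edges = np.cumsum([0.0] + [e - s for s, e in intervals])
    starts = np.array([s for s, _ in intervals])
    idx = np.searchsorted(edges, u, side="right") - 1
    return np.sort(starts[idx] + (u - edges[idx]))


def draw_ground_truth(params: SimParams) -> GroundTruth:
    """Draw event times (Poisson per kind, immobility only, minimum
    separation enforced across all events), unit tuning and modulation."""
    rng = rng_for(params.rng_seed, "events")
    intervals = _usable_immobile(params)
    if not intervals or sum(e - s for s, e in intervals) < 10.0:
        raise ValueError("immobility too scarce for the requested event rates")

    kinds, times = [], []
    for kind, rate in (
        ("SPWR", params.rate_spwr), ("DS2", params.rate_ds2), ("DS1", params.rate_ds1)
    ):
        t = _draw_times(rng, rate, intervals)
        kinds += [kind] * t.size
        times.append(t)
    times = np.concatenate(times) if times else np.array([])
    kinds = np.asarray(kinds, dtype=object)
    order = np.argsort(times, kind="stable")
    times, kinds = times[order], kinds[order]

    keep = []
    last = -np.inf
    for i, tt in enumerate(times):
        if tt - last >= params.min_event_separation:
            keep.append(i)
            last = tt
    times, kinds = times[keep], kinds[keep]

    # evoked stimulation trials
    stim_onsets, stim_kinds, evoked_flags = [], [], []
    if params.n_stim_trials > 0:
        srng = rng_for(params.rng_seed, "stimuli")
        flat = np.concatenate(
            [np.arange(s, e, 0.05) for s, e in intervals]
        )
        next_ok = 20.0
        trial = 0
        for cand in flat:
            if trial >= params.n_stim_trials:
                break
            if cand < next_ok:
                continue
            if times.size and np.min(np.abs(times - cand)) < 0.5:
                continue
            stim_onsets.append(cand)
            stim_kinds.append("tone" if trial % 2 == 0 else "puff")
            if srng.uniform() < params.evoked_prob:
                lat = max(
                    0.005,
                    srng.normal(params.evoked_latency_s, params.evoked_latency_jitter_s),
                )
                times = np.append(times, cand + lat)
                kinds = np.append(kinds, "DS2")
                evoked_flags.append(cand + lat)
            next_ok = cand + srng.uniform(15.0, 45.0)
            trial += 1
        order = np.argsort(times, kind="stable")
        times, kinds = times[order], kinds[order]

    # per-event extras
    behavior = generate_behavior(params)  # base trace, no transients yet
    pos_at = np.interp(times, behavior.t, behavior.position) if times.size else np.array([])
    n_ev = times.size
    slope = np.full(n_ev, np.nan)
    start = np.full(n_ev, np.nan)
    position_cm = np.full(n_ev, np.nan)
    pupil_amp = np.full(n_ev, np.nan)
    evoked = np.zeros(n_ev)
    j = params.event_strength_jitter
    strength = rng.uniform(1.0 - j, 1.0 + j, n_ev) if j > 0 else np.ones(n_ev)
    lo, hi = params.replay_slope_range_cm
    for i in range(n_ev):
        if kinds[i] == "SPWR":
            slope[i] = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
            start[i] = rng.uniform(0.0, params.track_length_cm)
        elif kinds[i] == "DS2":
            position_cm[i] = pos_at[i]
            pupil_amp[i] = params.pupil_dilation_amp
            if any(abs(times[i] - e) < 1e-9 for e in evoked_flags):
                evoked[i] = 1.0

    amp = np.where(
        np.isin(kinds.astype(str), ("DS1", "DS2")), params.ds_amplitude_mv,
        params.ripple_amplitude_mv,
    )
    chan = np.select(
        [kinds.astype(str) == "DS1", kinds.astype(str) == "DS2"],
        [params.ds1_sink_channel, params.ds2_sink_channel],
        default=PYRAMIDAL_CHANNEL,
    )
    events = EventTable.from_times(
        kinds, times, amplitude=amp,
        half_width=np.full(n_ev, np.nan), channel_index=chan,
        extra={
            "replay_slope_cm_per_step": slope,
            "replay_start_cm": start,
            "position_cm": position_cm,
            "pupil_amp": pupil_amp,
            "evoked": evoked,
            "strength": strength,
        },
    )

    trng = rng_for(params.rng_seed, "tuning")
    n_place = int(round(params.fraction_place_cells * params.n_units))
    uid = np.arange(params.n_units)
    is_place = uid < n_place
    pref = trng.uniform(0.0, params.track_length_cm, params.n_units)
    base = trng.uniform(*params.baseline_rate_range_hz, params.n_units)
    regions = np.where(
        is_place, "CA1",
        np.array(["DG", "RSC", "TH", "LS"], dtype=object)[uid % 4],
    )
    tuning = pd.DataFrame(
        {
            "unit_id": uid,
            "is_place": is_place.astype(int),
            "pref_cm": np.where(is_place, pref, np.nan),
            "sigma_cm": params.place_sigma_cm,
            "peak_hz": np.where(is_place, params.place_peak_rate_hz, base),
            "baseline_hz": base,
            "region": regions,
        }
    )
    mod = pd.DataFrame(
        {
            "unit_id": uid,
            "gain_DS1": np.where(
                ~is_place & (trng.uniform(size=params.n_units) < params.modulation_prob),
                params.ds1_gain, 1.0,
            ),
            "gain_DS2": np.where(
                ~is_place & (trng.uniform(size=params.n_units) < params.modulation_prob),
                params.ds2_gain, 1.0,
            ),
            "gain_SPWR": np.where(
                ~is_place & (trng.uniform(size=params.n_units) < params.modulation_prob),
                params.spwr_gain, 1.0,
            ),
        }
    )

    if params.n_stim_trials > 0:
        stim = StimulusLog(
            np.asarray(stim_onsets),
            np.asarray(stim_kinds, dtype=object),
            np.where(np.asarray(stim_kinds, dtype=object) == "tone", 0.35, 0.1),
        )
    else:
        stim = StimulusLog.empty()
    return GroundTruth(events, tuning, mod, stim)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _shaped_noise(rng, n, exponent) -> np.ndarray:
    """Unit-SD Gaussian noise with a 1/f**exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def ds_voltage_profile(n_channels: int, sink_channel: int) -> np.ndarray:
    """Laminar voltage profile whose (negative) second spatial difference has
    its sink exactly at ``sink_channel`` and a deeper return source; deep
    channels carry a positive plateau (the hilar DS positivity)."""
    ch = np.arange(n_channels, dtype=float)

    def g(mu, sig):
        w = np.exp(-0.5 * ((ch - mu) / sig) ** 2)
        return w / w.sum()

    # CSD (sinks negative) targeted at sink_channel; the interior second
    # difference of cumsum(cumsum(x)) lands at index i+1, hence the +1 shift.
    vpp = g(sink_channel + 1, 1.0) - g(sink_channel + 4, 1.5)
    v = np.cumsum(np.cumsum(vpp))
    return v - v[0]


def generate_lfp(params: SimParams, truth: GroundTruth) -> LfpRecording:
    """Background 1/f noise plus injected DS and SPW-R templates."""
    for s in (params.ds1_sink_channel, params.ds2_sink_channel):
        if not 1 <= s < params.n_channels - 4:
            raise ValueError(f"sink channel {s} outside probe")
    ev = truth.injected_events
    if len(ev) and (ev.peak_time.min() < 0 or ev.peak_time.max() >= params.duration):
        raise ValueError("event times must fit in [0, duration)")

    rng = rng_for(params.rng_seed, "lfp")
    n = int(round(params.duration * params.fs))
    n_ch = params.n_channels
    c = params.common_mode_frac
    common = _shaped_noise(rng, n, params.noise_exponent)
    voltage = np.empty((n_ch, n))
    for i in range(n_ch):
        voltage[i] = _shaped_noise(rng, n, params.noise_exponent)
    # volume conduction makes background spatially smooth across contacts;
    # without this correlation any CSD estimate would be noise-dominated
    if params.noise_spatial_sigma_ch > 0:
        from scipy.ndimage import gaussian_filter1d

        voltage = gaussian_filter1d(
            voltage, params.noise_spatial_sigma_ch, axis=0, mode="nearest"
        )
        voltage /= voltage.std(axis=1, keepdims=True)
    voltage = params.noise_sd_mv * (
        np.sqrt(1.0 - c**2) * voltage + c * common[None, :]
    )

    fs = params.fs
    w_ds = int(round(params.ds_width_ms / 1000.0 * fs))
    hann_ds = np.hanning(w_ds)
    prof = {
        "DS1": ds_voltage_profile(n_ch, params.ds1_sink_channel),
        "DS2": ds_voltage_profile(n_ch, params.ds2_sink_channel),
    }
    for k in prof:
        prof[k] = prof[k] * (params.ds_amplitude_mv / prof[k][HILUS_CHANNEL])

    w_rip = int(round(params.ripple_duration_ms / 1000.0 * fs))
    t_rip = np.arange(w_rip) / fs
    ripple = params.ripple_amplitude_mv * np.hanning(w_rip) * np.sin(
        2 * np.pi * params.ripple_freq_hz * (t_rip - t_rip[w_rip // 2])
    )
    w_sw = int(round(0.08 * fs))
    sw_env = -params.sharpwave_amplitude_mv * np.hanning(w_sw)
    sw_channels = np.arange(PYRAMIDAL_CHANNEL + 1, FISSURE_CHANNEL)
    sw_profile = np.exp(
        -0.5 * ((sw_channels - sw_channels.mean()) / 1.5) ** 2
    )

    def add(ch_profile, kernel, center_idx):
        w = kernel.size
        i0 = center_idx - w // 2
        j0, j1 = max(0, i0), min(n, i0 + w)
        if j1 <= j0:
            return
        seg = kernel[j0 - i0 : j1 - i0]
        if np.ndim(ch_profile) == 0:
            voltage[int(ch_profile), j0:j1] += seg
        else:
            voltage[:, j0:j1] += np.outer(ch_profile, seg)

    for kind, tt in zip(ev.kind.astype(str), ev.peak_time):
        idx = int(round(tt * fs))
        if kind in ("DS1", "DS2"):
            add(prof[kind], hann_ds, idx)
        elif kind == "SPWR":
            add(np.asarray(PYRAMIDAL_CHANNEL), ripple, idx)
            for ci, a in zip(sw_channels, sw_profile):
                add(np.asarray(ci), a * sw_env, idx)

    depth = np.arange(n_ch) * params.channel_spacing_um
    return LfpRecording(
        voltage=voltage, fs=fs, channel_depth=depth,
        channel_label=default_probe_labels(n_ch), t0=0.0,
    )


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

def _event_kernel_trace(times, n, grid_dt, half_ms, weights=None) -> np.ndarray:
    """Sum of Hanning bumps (full width 2*half_ms) at event times, each
    scaled by its per-event weight."""
    k = np.zeros(n)
    w = max(3, int(round(2 * half_ms / 1000.0 / grid_dt)))
    hann = np.hanning(w)
    if weights is None:
        weights = np.ones(len(times))
    for tt, sc in zip(times, weights):
        i0 = int(round(tt / grid_dt)) - w // 2
        j0, j1 = max(0, i0), min(n, i0 + w)
        if j1 > j0:
            k[j0:j1] += sc * hann[j0 - i0 : j1 - i0]
    return k


def generate_spikes(
    params: SimParams, truth: GroundTruth, behavior: BehaviorTrace
) -> SpikeTable:
    """Inhomogeneous-Poisson spike trains: baseline + place field during
    locomotion + event-locked gains; sequential replay during SPW-R and
    current-location reactivation during DS2 for place cells."""
    if behavior.t[-1] + behavior.dt < params.duration - 1e-6:
        raise ValueError("behaviour must cover the session duration")
    rng = rng_for(params.rng_seed, "spikes")
    grid_dt = 1e-3
    n = int(round(params.duration / grid_dt))
    tg = (np.arange(n) + 0.5) * grid_dt
    from .core import unwrap_position

    pos = np.interp(
        tg, behavior.t, unwrap_position(behavior.position, behavior.track_length)
    ) % behavior.track_length
    speed = np.interp(tg, behavior.t, behavior.speed)
    loco = speed >= params.speed_threshold_cm_s

    ev = truth.injected_events
    kinds = ev.kind.astype(str)
    strength = ev.extra.get("strength", np.ones(len(ev)))
    kernels = {
        k: _event_kernel_trace(
            ev.peak_time[kinds == k], n, grid_dt,
            params.event_kernel_halfwidth_ms, strength[kinds == k],
        )
        for k in ("DS1", "DS2", "SPWR")
    }
    ds2 = ev.of_kind("DS2")
    spwr = ev.of_kind("SPWR")
    L = params.track_length_cm

    times_out: dict[int, np.ndarray] = {}
    region_out: dict[int, str] = {}
    tuning = truth.unit_tuning.set_index("unit_id")
    mod = truth.unit_modulation.set_index("unit_id")

    step = params.replay_step_ms / 1000.0
    half_span = params.replay_steps * step / 2.0

    for uid in tuning.index:
        row = tuning.loc[uid]
        rate = np.full(n, row["baseline_hz"])
        if row["is_place"]:
            d = circular_distance(pos, row["pref_cm"], L)
            rate = rate + row["peak_hz"] * np.exp(
                -0.5 * (d / row["sigma_cm"]) ** 2
            ) * loco
            # DS2 current-location reactivation: additive Gaussian profile at
            # the animal's position, like the replay model.  The content
            # channel is not scaled by the arousal strength jitter.
            if len(ds2):
                d_ev = circular_distance(
                    ds2.extra["position_cm"], row["pref_cm"], L
                )
                w_ev = np.exp(-0.5 * (d_ev / row["sigma_cm"]) ** 2)
                k_ds2 = _event_kernel_trace(
                    ds2.peak_time, n, grid_dt,
                    params.event_kernel_halfwidth_ms, w_ev,
                )
                rate = rate + params.ds2_reactivation_peak_hz * k_ds2
            # sequential replay during SPW-R
            for te, sl, st, sc in zip(
                spwr.peak_time,
                spwr.extra["replay_slope_cm_per_step"],
                spwr.extra["replay_start_cm"],
                spwr.extra.get("strength", np.ones(len(spwr))),
            ):
                t0 = te - half_span
                i0 = max(0, int(round(t0 / grid_dt)))
                i1 = min(n, i0 + int(round(params.replay_steps * step / grid_dt)))
                if i1 <= i0:
                    continue
                k_step = np.floor((tg[i0:i1] - t0) / step)
                x_traj = (st + sl * k_step) % L
                dtraj = circular_distance(x_traj, row["pref_cm"], L)
                rate[i0:i1] += sc * params.replay_peak_rate_hz * np.exp(
                    -0.5 * (dtraj / row["sigma_cm"]) ** 2
                )
        else:
            g = mod.loc[uid]
            for k, col in (("DS1", "gain_DS1"), ("DS2", "gain_DS2"), ("SPWR", "gain_SPWR")):
                if g[col] != 1.0:
                    rate = rate * (1.0 + (g[col] - 1.0) * kernels[k])

        counts = rng.poisson(rate * grid_dt)
        idx = np.nonzero(counts)[0]
        reps = counts[idx]
        t_sp = np.repeat(idx, reps) * grid_dt + rng.uniform(0, grid_dt, reps.sum())
        times_out[int(uid)] = np.sort(t_sp)
        region_out[int(uid)] = str(row["region"])

    return SpikeTable(times_out, region_out, session_id=f"synth-{params.rng_seed}")


# ---------------------------------------------------------------------------
# Whole sessions
# ---------------------------------------------------------------------------

def simulate_session(params: SimParams) -> tuple[SessionData, GroundTruth]:
    """Generate a complete session in memory."""
    truth = draw_ground_truth(params)
    behavior = generate_behavior(params, truth)
    lfp = generate_lfp(params, truth)
    spikes = generate_spikes(params, truth, behavior)
    return SessionData(lfp, spikes, behavior, truth.stimuli), truth


def write_ground_truth(truth: GroundTruth, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dio.write_events(truth.injected_events, directory / "truth_events.tsv")
    truth.unit_tuning.to_csv(directory / "truth_tuning.tsv", sep="\t", index=False)
    truth.unit_modulation.to_csv(
        directory / "truth_modulation.tsv", sep="\t", index=False
    )


def read_ground_truth(directory: Path) -> GroundTruth:
    directory = Path(directory)
    return GroundTruth(
        dio.read_events(directory / "truth_events.tsv"),
        pd.read_csv(directory / "truth_tuning.tsv", sep="\t"),
        pd.read_csv(directory / "truth_modulation.tsv", sep="\t"),
    )


def generate_session(params: SimParams, directory: Path) -> tuple[Path, GroundTruth]:
    """Generate a session, write it (and its ground truth) to ``directory``."""
    directory = Path(directory)
    session, truth = simulate_session(params)
    dio.write_session(
        directory, session.lfp, session.spikes, session.behavior, session.stimuli
    )
    write_ground_truth(truth, directory)
    (directory / "params.json").write_text(
        pd.Series(asdict(params)).to_json(indent=1)
    )
    return directory, truth
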