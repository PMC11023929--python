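"""End-to-end pipeline: detection -> classification -> peri-event statistics
-> mutual information -> decoding -> population similarity.

``run_pipeline`` is a pure function of (session bytes, config, seed): every
shuffle draws from a named substream of the session-level seed, and each
stage writes its outputs plus a machine-readable ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import classification, decoding, detection, io as dio, mutual_info, patterns, perievent
from .core import EventTable, exclude_multikind, rng_for

logger = logging.getLogger("dspike")


@dataclass
class PipelineConfig:
    """Every analysis parameter, with defaults at the study's values."""

    # detection
    ds_band_low_hz: float = 5.0
    ds_band_high_hz: float = 100.0
    ds_threshold_sd: float = 4.5
    swr_band_low_hz: float = 120.0
    swr_band_high_hz: float = 180.0
    swr_peak_sd: float = 5.0
    swr_sustain_sd: float = 3.0
    swr_sustain_ms: float = 25.0
    sync_window_ms: float = 100.0
    evoked_window_ms: float = 200.0
    # classification
    csd_window_ms: float = 25.0
    dbscan_eps: float = 0.0          # 0 -> knee of the k-distance curve
    dbscan_min_samples: int = 5
    # peri-event statistics
    multikind_exclusion_s: float = 0.2
    modulation_shuffles: int = 100
    modulation_percentile: float = 99.5
    behavior_shuffle_draws: int = 200
    behavior_shift_s: float = 2.0
    behavior_percentile: float = 97.5
    speed_threshold_cm_s: float = 1.0
    # mutual information
    mi_shuffles: int = 5000
    mi_alpha: float = 0.01
    mi_min_sessions: int = 1         # single-session run; pooled analyses use 5
    # decoding
    decode_window_ms: float = 20.0
    slide_step_ms: float = 5.0
    r2_min: float = 0.3
    shift_iterations: int = 1000
    error_percentile: float = 97.5
    place_cell_shuffles: int = 50
    run_decode_window_ms: float = 250.0
    # similarity
    similarity_shuffles: int = 1000
    cluster_k: int = 2
    max_mean_rate_hz: float = 5.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.modulation_percentile, self.behavior_percentile,
                  self.error_percentile):
            if not 0 < p < 100:
                raise ValueError("percentiles must lie in (0, 100)")
        for thr in (self.ds_threshold_sd, self.swr_peak_sd, self.swr_sustain_sd):
            if thr <= 0:
                raise ValueError("thresholds must be positive")

    def detection_params(self) -> detection.DetectionParams:
        return detection.DetectionParams(
            ds_band=(self.ds_band_low_hz, self.ds_band_high_hz),
            ds_threshold_sd=self.ds_threshold_sd,
            swr_band=(self.swr_band_low_hz, self.swr_band_high_hz),
            swr_peak_sd=self.swr_peak_sd,
            swr_sustain_sd=self.swr_sustain_sd,
            swr_sustain_ms=self.swr_sustain_ms,
            sync_window_ms=self.sync_window_ms,
            evoked_window_ms=self.evoked_window_ms,
        )

    @classmethod
    def from_file(cls, path: Path) -> "PipelineConfig":
        """Parse ``key = value`` lines ('#' starts a comment)."""
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(cls(), key)
            kwargs[key] = type(current)(json.loads(val)) \
                if not isinstance(current, str) else val
        return cls(**kwargs)

    def to_file(self, path: Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return round(v, ndigits) if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(session_dir: Path, config: PipelineConfig, out_dir: Path) -> Path:
    """Run the full analysis on a session directory; returns the report dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lfp, spikes, behavior, stimuli = dio.read_session(session_dir)
    params = config.detection_params()
    summary: dict = {"skipped": {}}

    # ---- stage 1: detection --------------------------------------------
    @_stage("detection")
    def detect():
        hilus = lfp.channels_labeled("hilus")
        if hilus.size == 0:
            raise ValueError("no hilus channel on this probe")
        hilus_ch = int(hilus[len(hilus) // 2])
        ds = detection.detect_ds(lfp, hilus_ch, params)
        pyr = lfp.channels_labeled("CA1 pyramidal")
        if pyr.size:
            swr = detection.detect_swr(lfp, int(pyr[len(pyr) // 2]), params)
        else:
            swr = EventTable.empty()
            summary["skipped"]["swr_detection"] = "no CA1 pyramidal channels"
            logger.warning("no CA1 pyramidal channels; SPW-R detection skipped")
        return ds, swr

    ds_events, swr_events = detect()
    dio.write_events(EventTable.concat([ds_events, swr_events]), out / "events.tsv")
    summary["detection"] = {"n_ds": len(ds_events), "n_swr": len(swr_events)}

    # ---- stage 2: classification ---------------------------------------
    @_stage("classification")
    def classify():
        if len(ds_events) < 3:
            summary["skipped"]["classification"] = "too few DS events"
            return ds_events
        fiss = lfp.channels_labeled("fissure")
        gran = lfp.channels_labeled("granule")
        c0 = int(fiss[0]) if fiss.size else classification.find_fissure_channel(lfp)
        c1 = int(gran[-1]) if gran.size else min(c0 + 10, lfp.n_channels - 1)
        profiles = classification.compute_csd(
            lfp, ds_events, (c0, c1), config.csd_window_ms
        )
        eps = config.dbscan_eps if config.dbscan_eps > 0 else None
        assign = classification.classify_ds(profiles, eps, config.dbscan_min_samples)
        return classification.apply_labels(ds_events, assign)

    typed = classify()
    events = EventTable.concat([typed, swr_events])
    dio.write_events(events, out / "events_typed.tsv")
    summary["classification"] = {
        k: int(np.sum(events.kind.astype(str) == k))
        for k in ("DS1", "DS2", "DS_unclassified", "SPWR")
    }

    # ---- stage 3: peri-event statistics --------------------------------
    @_stage("perievent")
    def peri():
        clean = exclude_multikind(events, config.multikind_exclusion_s)
        res: dict = {}
        immobility, locomotion = perievent.segment_motion_state(
            behavior, config.speed_threshold_cm_s
        )
        res["immobile_s"] = sum(e - s for s, e in immobility)
        rows = []
        for kind in ("DS1", "DS2", "SPWR"):
            ev = clean.of_kind(kind)
            if len(ev) < 5 or spikes.n_units == 0:
                continue
            res[f"rate_{kind}_hz"] = detection.event_rate(ev, immobility) \
                if res["immobile_s"] > 0 else 0.0
            mod = perievent.modulation_test(
                spikes, ev, config.modulation_shuffles,
                config.modulation_percentile,
                rng=rng_for(config.rng_seed, f"modulation-{kind}"),
                duration=lfp.duration,
            )
            frac = float(np.mean([m.significant for m in mod.values()])) \
                if mod else 0.0
            res[f"modulated_fraction_{kind}"] = frac
            for m in mod.values():
                rows.append((m.unit_id, kind, int(m.significant), m.peak_z,
                             m.peak_bin_time))
        ds2 = clean.of_kind("DS2")
        if len(ds2) >= 5:
            for sig in ("pupil_speed", "facial_motion"):
                ch, fl, thr, _ = perievent.behavior_change_test(
                    behavior, ds2, sig,
                    n_shuffle_draws=config.behavior_shuffle_draws,
                    shift_range_s=config.behavior_shift_s,
                    percentile=config.behavior_percentile,
                    rng=rng_for(config.rng_seed, f"behavior-{sig}"),
                )
                res[f"{sig}_flagged_fraction"] = float(np.mean(fl)) if fl.size else 0.0
        if spikes.n_units:
            hf = perievent.high_firing_peaks(spikes, duration=lfp.duration)
            res["n_high_firing"] = len(hf)
            if len(hf) and len(clean.of_kind("DS2")):
                frac_sync, _ = detection.coincidence(
                    clean.of_kind("DS2"), hf, window_ms=60.0
                )
                res["ds2_high_firing_coincidence"] = frac_sync
        if rows:
            import pandas as pd
            pd.DataFrame(
                rows, columns=["unit_id", "kind", "significant", "peak_z",
                               "peak_bin_ms"]
            ).to_csv(out / "modulation.tsv", sep="\t", index=False)
        if len(stimuli):
            lat, frac_evoked = detection.evoked_latency(
                clean, stimuli, config.evoked_window_ms
            )
            res["evoked_fraction"] = frac_evoked
            res["evoked_latency_ms"] = float(np.nanmean(lat)) \
                if np.any(np.isfinite(lat)) else None
        return res, clean, immobility, locomotion

    peri_res, clean_events, immobility, locomotion = peri()
    summary["perievent"] = peri_res

    # ---- stage 4: mutual information -----------------------------------
    @_stage("mutual_information")
    def mi_stage():
        ds2 = clean_events.of_kind("DS2")
        regions = [r for r in spikes.regions if len(spikes.units_in_region(r)) > 0]
        if len(ds2) < 10 or len(regions) < 2:
            summary["skipped"]["mutual_information"] = "too few DS2 events or regions"
            return {}
        states = {
            r: mutual_info.discretize_counts(spikes, ds2, r) for r in regions
        }
        results = []
        rng = rng_for(config.rng_seed, "mi")
        for i, a in enumerate(regions):
            for b in regions[i + 1:]:
                results.append(
                    mutual_info.mi_significance(
                        states[a], states[b], config.mi_shuffles,
                        config.mi_alpha, rng=rng, region_pair=(a, b),
                    )
                )
        graph, gsum = mutual_info.coupling_graph(
            results, config.mi_min_sessions, config.mi_alpha
        )
        import pandas as pd
        pd.DataFrame(
            [(r.region_pair[0], r.region_pair[1], r.delta_mi_max, r.p_value)
             for r in results],
            columns=["region_a", "region_b", "delta_mi_max", "p_value"],
        ).to_csv(out / "mi_pairs.tsv", sep="\t", index=False)
        return gsum

    summary["mutual_information"] = mi_stage()

    # ---- stage 5: decoding ---------------------------------------------
    @_stage("decoding")
    def decode_stage():
        if lfp.channels_labeled("CA1 pyramidal").size == 0:
            summary["skipped"]["decoding"] = "no CA1 channels"
            logger.warning("decoding skipped: no CA1 channels")
            return {}
        loco_time = sum(e - s for s, e in locomotion)
        if loco_time < 30.0 or spikes.n_units == 0:
            summary["skipped"]["decoding"] = "insufficient locomotion"
            return {}
        res: dict = {}
        pcs = decoding.select_place_cells(
            spikes, behavior, locomotion,
            n_shuffles=config.place_cell_shuffles,
            rng=rng_for(config.rng_seed, "place-cells"),
        )
        res["n_place_cells"] = len(pcs)
        if len(pcs) < 10:
            summary["skipped"]["decoding"] = "too few place cells"
            return res
        curves = decoding.tuning_curves(
            spikes, behavior, locomotion, unit_ids=pcs
        )
        # locomotion decoding error (sanity metric)
        w = config.run_decode_window_ms / 1000.0
        centers = []
        for s, e in locomotion:
            centers.extend(np.arange(s + w, e - w, 1.0))
        centers = np.asarray(centers)
        if centers.size:
            dec, act = decoding.decoding_errors(
                spikes, curves, behavior, centers, window_s=w
            )
            err_cm = np.abs(
                ((dec - act + curves.n_bins // 2) % curves.n_bins)
                - curves.n_bins // 2
            ) * decoding.BIN_CM
            res["median_run_error_cm"] = float(np.median(err_cm))
        # DS2 current-location test
        ds2 = clean_events.of_kind("DS2")
        if len(ds2) >= 20:
            dec, act = decoding.decoding_errors(
                spikes, curves, behavior, ds2.peak_time,
                window_s=config.decode_window_ms / 1000.0,
            )
            prop, flagged, thr, bins = decoding.error_overrepresentation(
                dec, act, curves.n_bins, config.shift_iterations,
                percentile=config.error_percentile,
                rng=rng_for(config.rng_seed, "error-shift"),
            )
            res["ds2_zero_error_proportion"] = float(prop[bins == 0][0])
            res["ds2_zero_error_flagged"] = bool(flagged[bins == 0][0])
            dio.write_matrix(prop, out / "ds2_error_hist.bin",
                             bins=[int(b) for b in bins], threshold=thr)
        # replay slopes over SPW-R windows
        spwr = clean_events.of_kind("SPWR")
        slopes = []
        for t in spwr.peak_time:
            post = decoding.decode_sliding(
                spikes, curves, t - 0.1, t + 0.1,
                window_s=config.decode_window_ms / 1000.0,
                step_s=config.slide_step_ms / 1000.0,
            )
            fit = decoding.fit_trajectory(post)
            if fit.r_squared >= config.r2_min:
                slopes.append(fit.slope)
        res["n_replay_fits"] = len(slopes)
        if slopes:
            res["median_abs_replay_slope_bins_per_step"] = float(
                np.median(np.abs(slopes))
            )
        return res

    summary["decoding"] = decode_stage()

    # ---- stage 6: similarity -------------------------------------------
    @_stage("similarity")
    def similarity_stage():
        ds2 = clean_events.of_kind("DS2")
        if len(ds2) < 10 or spikes.n_units == 0:
            summary["skipped"]["similarity"] = "too few DS2 events"
            return {}
        try:
            pvs = patterns.population_vectors(
                spikes, ds2, max_mean_rate_hz=config.max_mean_rate_hz,
                session_duration=lfp.duration,
            )
        except ValueError as exc:
            summary["skipped"]["similarity"] = str(exc)
            return {}
        sim = patterns.vector_similarity(
            pvs, config.similarity_shuffles,
            rng=rng_for(config.rng_seed, "similarity"),
        )
        order = patterns.cluster_order(pvs, config.cluster_k)
        dio.write_matrix(sim["pearson"], out / "similarity_pearson.bin")
        dio.write_matrix(sim["cosine"], out / "similarity_cosine.bin")
        iu = np.triu_indices(pvs.n_events, k=1)
        return {
            "n_units": pvs.n_units,
            "n_events": pvs.n_events,
            "mean_pearson": float(np.nanmean(sim["pearson"][iu])),
            "mean_cosine": float(np.mean(sim["cosine"][iu])),
            "n_unit_clusters": int(np.max(order["unit_labels"])),
        }

    summary["similarity"] = similarity_stage()

    (out / "summary.json").write_text(
        json.dumps(_round_floats(summary), indent=1, sort_keys=True) + "\n"
    )
    return out
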