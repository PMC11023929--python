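# Methods

This note documents the models and procedures implemented in `dspike`, the
parameters that matter, the generative model behind the synthetic sessions,
and the numerical and design choices made where the methodology was
genuinely open.

## Conventions

Time is seconds (float); every bin is half-open `[start, end)` and events
fall into bins by their peak time. Channel 0 is the most superficial probe
contact; depth in micrometres increases downward. Voltages are millivolts.
All randomness flows from one session-level seed through named substreams
(`rng_for(seed, name)`), one per shuffle procedure, so stages are
individually reproducible regardless of execution order.

## Event detection

DS detection bandpasses the hilus channel to 5–100 Hz and takes local
maxima above `ds_threshold_sd` (default 4.5) times the SD of the filtered
trace; the SD is computed over the whole recording, not only immobility.
The filter is a zero-phase forward–backward Butterworth of order 3 —
zero-phase so the reported peak time is not skewed by group delay. Peak
amplitude and the width at half that amplitude are read from the filtered
trace; note that forward–backward order-3 filtering attenuates a 25 ms
raised-cosine transient by roughly 12 %, so filtered amplitudes sit
slightly below the raw ones (the raw hilus peak is the physical amplitude).
Super-threshold peaks closer than one template width (25 ms) are merged,
keeping the larger, since one DS produces one event.

SPW-R detection bandpasses the CA1 pyramidal channel to 120–180 Hz, takes
the magnitude of the analytic signal as the envelope, and z-scores it.
Excursions above 3 SD lasting at least 25 ms that contain a 5 SD peak
become events — one event per excursion even if several 5 SD peaks occur —
timed at the maximum positive value of the filtered trace within the
excursion.

Cross-probe coincidence matches events greedily by smallest time difference
within a 100 ms window, each event used at most once; the synchrony
fraction is computed against the probe with fewer events (ties resolved to
the first table). Evoked latency is the first DS2 strictly after a
stimulus onset within a configurable window (default 200 ms).

## CSD classification

The CSD estimator is the negated second spatial difference of voltage
across equally spaced channels (sinks negative), with Vaknin padding
(duplicated boundary channels) so the output covers the full channel
range. Inverse (iCSD) estimators add a forward model we do not need: the
classifier only has to separate sink depths, for which the finite
difference is sufficient and fully specified.

Per-event profiles over the fissure-to-granule channel range in a ±25 ms
window are flattened, normalized to unit Euclidean norm (removing
amplitude, keeping shape — the normalization also makes classification
exactly invariant to global LFP scaling), projected onto their first two
principal components, and clustered with DBSCAN. The window default equals
the DS template width: wider windows dilute the profile with event-free
samples and push noise into the second component.

DBSCAN's `eps` defaults to the 95th percentile of the k-distance curve
(k = `min_samples`, default 5). The often-recommended curve "knee"
systematically under-sets `eps` here because DS1 is several-fold rarer
than DS2, so its cluster is sparse and dissolves first; the upper-quantile
rule keeps both clusters connected, and the resulting labels are stable
when `eps` is swept over a wide range (tested at 0.5–3× the automatic
value). The two largest clusters are labelled by the depth of their mean
CSD sink — shallower (outer molecular) = DS1, deeper (middle molecular) =
DS2 — never by cluster enumeration order; an exact depth tie falls back to
cluster order with a logged warning. Points outside both clusters are
`unclustered`. Fewer than two clusters raises a warning and leaves all
events unclustered.

## Peri-event statistics

Per-unit session statistics come from the whole-session rate in 100 ms
bins smoothed with a Gaussian (σ = 5 bins); peri-event rates in 10 ms bins
over ±200 ms are z-scored with that mean and SD. Events with another event
*kind* within 200 ms are excluded before any peri-event analysis. Units
with zero session SD are excluded with a log entry.

The modulation null redraws each peri-event spike uniformly within the
±200 ms window, preserving per-event spike counts. Because the test
statistic (the maximum bin of the event-averaged z-trace) depends only on
the pooled per-bin count, the null is drawn exactly as a multinomial
redistribution of the pooled count — equivalent to per-event redraws and
much cheaper. The observed statistic goes through the identical
pooled-count arithmetic so exact ties compare as ties, and significance
requires strictly exceeding the 99.5th percentile (`numpy` `method=
"higher"`) of shuffled maxima. With the default 100 shuffles the rank
granularity floors the achievable level at 1/101 ≈ 1 %; at 1000 shuffles
the threshold is the 996th order statistic and the exact level is
5/1001 ≈ 0.5 %, which is where the calibration is checked. Power at fixed
5× gain depends strongly on a unit's baseline rate (the signal is extra
spikes ≈ baseline × (gain−1) × kernel integral per event); the acceptance
script characterizes it at a 2 Hz baseline with 200 events, and it falls
steeply for units below ~1 Hz.

Behaviour-change tests subtract a pre-event window mean from a post-event
window mean per event (pupil speed: −290…−85 ms vs −20…+85 ms; facial
motion: −140…−40 ms vs +40…+115 ms; change reported so that an increase
after the event is positive). The null shifts each event by a uniform draw
in ±2 s, pools all shifted changes, and flags events above the pooled
97.5th percentile. Because near-zero shifts keep the windows inside the
event's own response, this null only has power against responses that are
brief relative to the shift range — which the analysis windows (~100 ms)
presuppose; a response sustained for seconds would saturate the null at
its own amplitude and nothing could be flagged.

High-firing peaks are local maxima of the population-average 10 ms-binned
rate above its 99.9th percentile; their coincidence with LFP events uses a
60 ms window. ΔF/F uses an ordinary least-squares cubic polynomial in time
as the baseline B(t) and returns (F − B)/B, raising if B is not strictly
positive; event-aligned standardization uses the preceding 1 s.

## Mutual information

Regional spike counts (pooled over a region's units) in 5 ms bins over
±200 ms around event peaks are discretized into four uniform-count states
by empirical quantile boundaries computed over all trials and bins; counts
exactly on a boundary go to the lower state. For integer counts the
boundaries are typically integers, so the realized state occupancies are
not 25 % each (e.g. for Poisson(2) counts they are ≈ 41/27/18/14 % by
direct pmf arithmetic) — a direct consequence of the tie rule, documented
because it changes state occupancies.

MI is the plug-in estimate per time bin across trials, in bits; the mean
over the −200…−100 ms bins is subtracted (ΔMI). Significance permutes
whole event trials of one region 5000 times (preserving each region's
temporal structure) with `p = (1 + #{null ≥ obs}) / (1 + N)`, so p is
never zero; p < 0.01 is significant. No analytic bias correction is
applied — the trial-shuffle null absorbs the plug-in bias. The coupling
graph draws an edge for significant pairs with at least `min_sessions`
contributing sessions (`MiResult.n_sessions`; the package default for a
single-session run is 1, pooled analyses use 5), weighted by the maximal
ΔMI.

A deterministic event-locked rate modulation produces *no* MI across
trials: both regions' counts are independent Poisson around a shared mean
timecourse, and the trial shuffle preserves exactly that structure. MI
coupling requires trial-to-trial covariability (shared gain fluctuations),
and its detectability grows with the pooled regional rate; at desk scale
(~100 events, ~10 units per region) the per-bin effect is usually below
the shuffle floor, which is why the end-to-end recovery check uses
constructed regions at pooled rates of a few hundred Hz and ~300 trials.

## Bayesian decoding

Tuning curves are spike counts over occupancy per 5 cm bin (24 bins on the
120 cm circular track), restricted to locomotion; counts and occupancy are
smoothed circularly (Gaussian, σ = 1 bin) before division and rates are
floored at 0.01 Hz so the log-likelihood is defined everywhere. Place
cells for decoding are selected by Skaggs spatial information against a
circular spike-shift null (95th percentile) computed on the concatenated
locomotion time base — the inclusion criterion is this package's
documented stand-in, since none is universal; the decoder itself accepts
any unit set.

Decoding accumulates `Σᵢ [nᵢ log(rᵢ(x)τ) − rᵢ(x)τ]` in log space (τ =
20 ms), subtracts the row maximum and normalizes, so each posterior row is
exactly on the simplex; the decoded position is the argmax bin. Note the
posterior is *not* invariant to scaling all tuning curves by a common
constant (the `exp(−c Σᵢ rᵢ(x) τ)` factor is position-dependent); the
correct neighbouring property — a flat-tuning unit never changes the
posterior — holds and is tested.

Decoding-error over-representation: per event, the signed circular
distance between decoded and actual bins; the null circularly shifts each
decoded position by an independent uniform draw in ±60 cm (integer
multiples of the 5 cm bin, i.e. the full circle) 1000 times, taking each
iteration's maximal bin proportion; observed bins above the 97.5th
percentile of those maxima are over-represented. This is a family-wise
construction: under the null, *some* bin is flagged in ≈ 2.5 % of
datasets.

Candidate population events: pooled 1 ms spike counts smoothed with a
21 ms Hanning kernel must exceed the mean MUA over the supplied analysis
intervals (a config flag switches to the whole session); boundaries shrink
inwards to the first/last bin containing a raw spike; durations outside
50 ms–2 s are discarded.

Trajectory slopes: the posterior over a sliding 20 ms / 5 ms grid is fit
by circular–linear regression — a grid search over slopes (default ±3
bins/step in 0.01 steps) with the closed-form best phase per slope
(maximizing the posterior-weighted mean resultant). R² is one minus the
ratio of the weighted circular residual variance at the best slope to the
variance at slope zero; exact resultant ties prefer the smaller |slope|
(the stationary reading). Under this definition a clean stationary
posterior has R² near 1 but a noisy stationary one scores low, so the
R² ≥ 0.3 filter retains mostly genuinely sloped trajectories; the
stationary-vs-replay contrast is therefore computed on unfiltered fits.

## Population patterns

DS2 population vectors are per-unit counts in `[peak − 100 ms, peak +
100 ms)`, max-normalized per unit (making them invariant to scaling any
unit's counts); units above 5 Hz session mean rate or silent in every
window are excluded. Pearson and cosine similarity are computed for all
event pairs; the null independently permutes each unit's event axis
(default 1000 times, the count is not canonical and is exposed in config)
with the +1-corrected p. Ward-linkage agglomerative clustering on
Euclidean distances orders units and events for display and provides flat
labels at a configurable cut (default 2 clusters); `scipy`'s linkage is
deterministic given the input. Stimulus identity is decoded with a
perceptron (fixed max 1000 epochs, tol 1e-3) under stratified 10-fold
cross-validation; the permutation p counts label permutations scoring at
least as well as the observed labels, including the observed arrangement.

## The synthetic generator

The generator defines the study conditions: 600 s sessions; immobility
and locomotion bouts alternating (exponential durations, means 12 s and
8 s, minimum 3 s, ≈ 60 % immobile); events drawn as independent Poisson
processes per kind — 0.3 Hz DS2, 0.05 Hz DS1, 0.3 Hz SPW-R — restricted to
immobility with a 0.3 s margin from bout edges. A minimum separation of
0.25 s is enforced between *all* events, not only across kinds: within-kind
near-coincidences would be merged by the detector and only blur recall
accounting.

**LFP.** Background noise is Gaussian with a 1/f spectrum (SD 0.1 mV per
channel), a 30 % common-mode component, and — importantly — spatial
correlation across channels (Gaussian smoothing, σ = 1.5 contact
spacings). Volume-conducted background is smooth at 50 µm pitch; spatially
white noise would make any second-difference CSD estimator
noise-dominated, i.e. it would misrepresent the physics that makes CSD
analysis possible at all. The DS template is specified in CSD space — a
Gaussian sink (σ = 1 channel) at the target molecular-layer channel with a
deeper Gaussian source (the granule-layer return current) — and integrated
twice to voltage, so the classification ground truth is exact and the deep
(hilus) channels carry the characteristic positive plateau, scaled to
2 mV at the reference hilus channel. The time course is a 25 ms raised
cosine. The SPW-R template is a 150 Hz sinusoid under a 60 ms Hanning
envelope (0.25 mV) on the pyramidal channel with a small negative
sharp-wave deflection on the radiatum channels.

**Spikes.** 100 units: 50 CA1 place cells (Gaussian tuning, σ = 8 cm,
15 Hz peak, preferred positions uniform) and 50 units split across four
extra-hippocampal regions (DG/RSC/TH/LS), baselines uniform 0.5–2 Hz.
Non-place units are event-modulated (probability 0.5 per kind) with
multiplicative gains (DS2 ×5, DS1 ×3, SPW-R ×3) under a ±50 ms Hanning
kernel. Every event carries a strength factor (uniform 1 ± 0.5) shared by
all units it modulates — this trial-to-trial covariability is what makes
regions couple in the MI sense; without it MI would be identically zero by
construction. During SPW-Rs place cells additionally fire along a virtual
trajectory (start uniform, slope 5–15 cm per 20 ms step with random sign,
10 steps, additive Gaussian-profile rate peaking at 80 Hz) — replay is
generated in decoding-step time so the injected slope is directly
comparable with the fitted one. During DS2 place cells reactivate their
field at the animal's *current* position with the same additive form (peak
80 Hz, not scaled by the arousal strength jitter — the content channel and
the global gain are separate things). An earlier multiplicative
formulation of the DS2 reactivation (gain on immobile baselines) left the
current-location signal at the edge of its own null threshold; the
additive form is also the cleaner generative statement of
"current-location coding".

**Behaviour.** Position integrates the speed profile on the circular
track; pupil diameter is a slow mean-reverting (OU) process plus a slow
(1.5 s Hanning) dilation after each DS2; pupil speed and facial motion are
rectified noise plus a *brief* (120 ms boxcar) burst at DS2 onset with the
configured amplitude. The burst is brief deliberately: the ±2 s shift null
only has power against responses confined to the analysis windows (see
above). With the pupil windows, the measured post-minus-pre change of a
120 ms burst is amplitude × 0.085/0.105 ≈ 0.81 × amplitude — the value the
oracle test asserts.

**What the generator does not emulate.** No biophysics (no conductance or
morphology), no theta/gamma rhythms or phase coding, no sleep states, no
probe-geometry realism, no spike-sorting artefacts, no drift or
non-stationarity, no forward/reverse replay asymmetry, and the arousal
covariability is a single scalar per event. Passing tests therefore show
that the *procedures* recover what they are defined to recover under
controlled conditions — not that real recordings will be as clean.

## Problem sizes

The test-suite and acceptance runs use: one 600 s standard session
(detection, decoding, contrast and determinism checks), ten or five
LFP-only 600 s sessions (classification recovery), 1000–2000 simulated
null units × 200 events (modulation calibration), 150–200 repetitions of
the MI and shift nulls at 300–400 shuffles, and constructed 4-region
systems with ~300 trials for MI recovery. These sizes put every Monte-
Carlo band at three binomial SDs or better while keeping a full run in
minutes on one core.

## Known limitations

- The fissure/hilus/pyramidal analysis channels are taken from probe
  labels (with a theta-power helper for guidance); there is no automatic
  channel selection.
- The circular–linear R² definition is one of several in use; absolute R²
  values are not comparable across definitions, only the ≥ 0.3 filter's
  behaviour is.
- The plug-in MI is uncorrected; only ΔMI against the trial-shuffle null
  is interpretable, not raw MI magnitudes.
- With the default 100 modulation shuffles the effective test level
  is ~1 %, not 0.5 % (rank granularity); use ≥ 1000 shuffles when the
  exact level matters.
- `read_session` expects this package's flat-binary + sidecar session
  format; vendor formats (NWB and friends) need a thin conversion step.
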