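# Methods

This note documents the models, defaults and numerical choices behind
`vsdwave`, and what the synthetic benchmarks do and do not establish.

## Coordinate and timing conventions

Pixels are 0-based `(row, col)`, row 0 at the top; physical position is
`x = col·pitch`, `y = row·pitch` with pitch in mm/pixel; frame *k* is at
`k / frame_rate` seconds.  The default field is 100 × 100 pixels at
25 µm/pixel (2.5 mm square) sampled at 200 Hz — the nominal sensor
resolution; the true field of view of the original optics is ambiguous, so
the pitch is configurable and every physical quantity scales through it.
All distances are straight-line polyline arc lengths; no curvature
compensation is applied anywhere.

## The synthetic slice and its kinematic model

The default atlas arranges eight regions in three bands — hippocampus
(CA3, CA1, subiculum), the periallocortical relays in reverse order (mEC,
lEC, perirhinal), and the two Au1 laminae — joined by a snaking
hippocampo-neocortical axis more than 9 mm long.  A separate
lamina-parallel `au1_cortical` axis carries horizontal position within
Au1: next to Au1 the snaking axis passes twice (once through the deep
layers, once via an inter-band connector), which would make nearest-point
projection ambiguous there.

An event is a list of *wavefront branches*.  Each branch activates the
pixels of given regions within an axis interval, with onset time
`t₀ + |d − d₀| / v` (distance `d` along the branch's axis, origin `d₀`,
velocity `v`); a pixel's ground-truth onset is the minimum over branches.
Saltatory spread is expressed as branches rooted at distal jump loci whose
back-propagating side runs at the backfill velocity; the reverberatory
(type 3b) second wave is a second family of branches starting in Au1 at
`t(Au1) + latency − 74 ms` so that it re-enters CA1 exactly at the
configured latency.  The preset delays (25 ms CA1→Au1, 74 ms return, 8 and
17 ms interlaminar) are anchored exactly; the implied return velocity over
the ~5 mm path is ≈ 0.068 m/s, consistent with a slow, monotonic
hippocampopetal wave.

Each active pixel's fluorescence rises as a half-cosine (20 ms default)
and decays exponentially.  The decay half-time default is 0.8 s: the
reverberation criterion requires the neocortical fluorescence to remain
above half its peak when the return wave ignites, and with latencies
anywhere in the admissible 0.42–0.78 s window that requires a half-decay
of at least ≈ 0.8 s.  Amplitudes are set per region as percent ΔF/F of a
20 000-count resting fluorescence (origin 0.14 / 0.16 / 0.12 % for types
1 / 3a / 3b, 0.08–0.10 % elsewhere), matching the reported ranges.  Noise
is white Gaussian at 20 % of the largest origin amplitude (6.4 counts)
plus a 1 %/s multiplicative bleaching trend.  The default cohort is 14
type 1, 11 type 2, 23 type 3a, 7 type 3b and 2 mEC-origin events (57
total), with per-event seeds spawned from one master seed.

What the generator does **not** emulate: biophysical network dynamics,
tissue curvature, wavefront bands of finite width (whole regions
activate), spatially correlated (shot/vignetting) camera noise, and motion.
Passing the recovery benchmarks therefore demonstrates the correctness of
the measurement chain under the stated conditions, not robustness to every
artifact of real optical data.

## Detection chain

Order: background subtraction → linear detrend (fitted on the first 0.5 s,
extrapolated) → 2 × 2 block-mean binning → Savitzky–Golay differentiation
(window 11 frames ≈ 55 ms, order 3), with percent-ΔF/F available on the
un-differentiated branch.  Onsets are first positive crossings of
per-pixel `mean + 2 SD` baseline thresholds on the differentiated signal
(a ΔF/F-thresholding switch is provided), linearly interpolated between
the bracketing frames.

Three numerical choices matter at the margins:

* **Degenerate thresholds.** On noise-free data the baseline SD is exactly
  zero and any positive value crosses; such pixels get a level at 5 % of
  their dynamic range so the crossing still interpolates on the smooth
  flank (amplitude-invariant, so delays are unaffected).
* **Amplitude validation.** A 2 SD level is exceeded by ~2.3 % of Gaussian
  noise samples by construction, so raw first crossings are meaningless at
  realistic noise.  The pipeline accepts a crossing only if the ΔF/F
  branch sustains its own 2 SD level for ≥ 50 ms just after it, anchors the
  onset to the last crossing preceding that sustained rise, and then drops
  spatially isolated onsets (a wavefront is locally coherent; residual
  bleach-drift artifacts are not).
* **Symmetric-window shift.** Zero-phase differentiation sees the rise
  before its centre reaches it, advancing every crossing by a common few
  ms.  All kinematic quantities are differences or slopes and cancel the
  shift; absolute onsets on the differentiated branch carry it.

Reverberation is detected on the *hippocampal region-mean* trace (its
differentiated second crossing after the Au1 onset, within a 0.3–1.0 s
window widened from the observed 0.42–0.78 s range so the observed
extremes are not definitional), provided hippocampus was recruited by the
first wave and the Au1 mean ΔF/F never fell below half its first-wave peak
before the re-entry.  Second-wave pixel onsets are then searched within
±0.25 s of the detected re-entry and must be followed by a smoothed-ΔF/F
rise of ≥ 35 % of the pixel's first-wave peak.

## Velocities, delays, saltations

Velocity is `1/slope` of a Theil–Sen fit of onset versus axis distance
(ordinary least squares available); conduction times are earliest-onset
differences between region masks, in ms.  At 200 Hz the CA1 traverse takes
only ~3 ms, so per-event estimates at default noise scatter considerably;
the calibrated statements are therefore: noise-free single events recover
0.37 / 0.17 / 0.47 m/s and 25 / 74 ms within the reported bands, and at
default noise the *median across a seeded cohort* recovers the CA1
velocities while the backfill velocity is fitted on whole-region pixel
populations (hundreds of pixels per periallocortical region) rather than
on corridor-minimum profiles, whose per-sample jitter exceeds the ~2 ms
intra-limb structure of a 2.5 mm field.

Profile-level saltation detection reports interior local minima of the
onset-vs-distance profile that lead the intervening tissue by
≥ `min_lead_s` across a gap of ≥ `min_jump_mm`, merged per originating
locus, with the backfill limb fitted inside the jump gap.  Defaults are
0.2 mm and 1 ms: the backfill traversal of one relay region at 0.47 m/s
takes ~2 ms on this field, so a larger lead requirement could never fire
on events generated under the model's own kinematics.  At default noise
the profile sprouts spurious small saltations (jitter local minima); locus
recovery and limb fits are exact on noise-free profiles, and the
population fit above is the noise-robust backfill estimator.

## Classification

A pure rule set over the measured features: hippocampal origin with
recruitment confined to CA3/CA1 → type 1; Au1 origin without hippocampal
recruitment → type 2; hippocampal origin with Au1 recruitment → 3a, or 3b
when reverberation is present; everything else — including mEC-origin
events and hippocampal events that stall in subiculum — remains
unclassified.  A region counts as recruited when ≥ 10 % of its pixels have
onsets (the fraction is a package choice, configurable).  On the default
57-event cohort classification is exact at zero noise and ≥ 95 % accurate
at default noise (empirically 100 % at the default master seed).

## LFP morphology

The band-pass is zero-phase via the squared Butterworth magnitude response
applied in the frequency domain (1st-order high-pass at 0.5 Hz — the
gentle corner of AC-coupled acquisition hardware — and 3rd-order low-pass
at 100 Hz).  Two facts force the surrounding choices.  First, a 10 s
record holds only five periods of the high-pass corner, so time-domain
forward-backward filtering leaks realisation-dependent slow edge
transients into the whole trace.  Second, *no* causal-shaped waveform can
dwell above a positive threshold for > 1 s after a true 0.5 Hz high-pass
(a plateau decays with the corner time constant, ~0.3 s), and folding the
event's own energy into the threshold SD caps the achievable dwell near
0.6 s — far below the 1.17 / 1.62 s spans these events show.  The
detection level is therefore `centre + 2 SD` of the *event-free* trace
(samples outside the event window, or a robust MAD estimate), and the
generator designs the *conditioned* waveform directly — negative
deflection plus slow wave (biphasic), or spike, trough and late slow wave
(triphasic), each flanked by shallow guard undershoots — and synthesises
the raw trace by exact inverse filtering, calibrating the lobe layout and
amplitude against the realised level by root finding.  Crossing counting
is segment-based: sub-threshold gaps < 20 ms are bridged and
suprathreshold segments < 100 ms discarded, which is what makes "always
exactly 2 / exactly 4 crossings" a well-defined property in the presence
of any noise at all.  "Line length" is implemented as the first-to-last
crossing time span (the units are seconds); the classical
sum-of-absolute-differences EEG feature is a different quantity and is
deliberately not conflated with it.

Laminar channel pairs use a spike-led waveform (150 µV, 0.25 µV noise,
modelling averaged traces) and onset levels from the plain whole-epoch
`mean + 2 SD` — the event energy places that level on the steep flank,
giving the sub-millisecond onset sharpness the 8 / 17 ms interlaminar
delays require.

## Problem sizes

The default benchmarks run movies of 320–400 frames × 100 × 100 pixels,
cohorts of 57 events, 10 s LFP epochs at 2 kHz, and cohort medians over
~9–20 noise realisations; the full test suite completes in about a minute
on one CPU and the acceptance script in well under one.

## Known limitations

Single-event velocity and return-delay estimates at default noise are
reported but carry substantial scatter (the study conditions sit at the
resolution limit of 5 ms frames over a 2.5 mm field); saltation lists on
noisy profiles contain spurious small entries; the generator's wavefronts
fill whole regions rather than narrow bands; and the LFP morphology
calibration assumes the default analysis settings (band, filter
realisation, level definition) — changing those re-calibrates the
generator automatically but changes the raw waveforms.
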