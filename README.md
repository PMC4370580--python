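# vsdwave

Wavefront kinematics and event taxonomy for voltage-sensitive-dye (VSD)
imaged interictal epileptiform discharges in hippocampal–neocortical brain
slices.

## The problem

In acutely disinhibited slices spanning hippocampus, the parahippocampal
("periallocortical") relays and primary auditory neocortex (Au1), brief
interictal discharges arise, propagate and sometimes reverberate.  Optical
mapping with a voltage-sensitive dye (100 × 100 pixels at 200 Hz) captures
the spatiotemporal wavefront of each event; paired local field potential
(LFP) recordings capture its electrographic signature.  The analysis
questions are where each event starts, how fast and by what route it
spreads, whether neocortical activity re-invades hippocampus, and whether
the surface LFP shape alone can tell hippocampal-origin events from
neocortical ones.

`vsdwave` implements that analysis as a tested, reusable pipeline, together
with a synthetic-data generator that produces movies, atlases and LFP
traces with *analytic* ground truth, so every stage can be validated by
parameter recovery without any wet-lab data.

## Method at a glance

* **Preprocessing** — per-pixel background subtraction, linear detrending
  (fitted on the pre-event baseline), 2 × 2 spatial binning, and a
  Savitzky–Golay differentiation filter (default window 11 frames,
  order 3).
* **Wavefront detection** — the onset of pixel *i* is the first positive
  crossing of a threshold θᵢ = μᵢ + 2σᵢ (baseline mean + 2 SD), with the
  sub-frame crossing time recovered by linear interpolation.  At realistic
  noise, crossings are validated by a sustained suprathreshold ΔF/F
  response, and spatially isolated onsets are discarded.
* **Kinematics** — onset maps are projected onto anatomical axis polylines
  (earliest onset within a 0.2 mm capture corridor); velocity is the
  inverse slope of onset time vs distance, fitted by the median of
  pairwise slopes (Theil–Sen); conduction time between regions is the
  difference of earliest onsets; saltatory "jumps" are distal loci whose
  onset precedes the intervening tissue, with the back-propagating limb
  fitted separately.
* **Event taxonomy** — Type 1 (hippocampal, non-propagating), Type 2
  (Au1-origin, non-propagating), Type 3a (hippocampus → neocortex), Type 3b
  (3a plus a reverberatory return wave 0.42–0.78 s after neocortical
  invasion); anything else (e.g. mEC-origin events) stays unclassified.
* **LFP morphology** — zero-phase 0.5–100 Hz band-pass, then crossings of a
  +2 SD level: biphasic events (neocortical origin) always show 2
  crossings, triphasic spike-and-wave-like events (hippocampal origin)
  always 4; the first-to-last crossing span, peak-to-peak amplitude,
  initial polarity and interlaminar (L2/3 ↔ L5/6) onset delays complete
  the feature set.

Default kinematic presets: CA1 0.37 m/s (propagating) / 0.17 m/s
(non-propagating), CA3 0.04 m/s, periallocortical backfill 0.47 m/s,
perirhinal 0.02 m/s; CA1→Au1 25 ms, Au1→CA1 return 74 ms, interlaminar
8 ms (L2/3→L5) and 17 ms (L5/6→L2/3); biphasic 1.17 s / 42 µV, triphasic
1.62 s / 46 µV.

## Worked example

Simulate one reverberating (Type 3b) event with realistic noise, run the
full per-event analysis, and classify a synthetic triphasic LFP trace:

```python
import vsdwave as vw
from vsdwave.events import characterize_event

atlas = vw.build_region_atlas()
spec = vw.make_event_spec("3b", atlas, reverb_latency_s=0.6)
movie, truth = vw.simulate_event(spec, atlas)
movie = vw.add_noise_and_bleach(movie, seed=42)
rec = characterize_event(movie, atlas)
print(f"event type:        {rec.event_type}")
print(f"origin:            {rec.origin_region} (laminar: {rec.laminar_origin})")
print(f"CA1 -> Au1 delay:  {rec.conduction_times_ms['CA1->Au1_L56']:.1f} ms")
print(f"return delay:      {rec.conduction_times_ms['Au1->CA1_return']:.1f} ms")
print(f"reverb latency:    {rec.reverb_latency_s:.3f} s")
print(f"backfill velocity: {sum(rec.backfill_velocity_m_s.values())/2:.2f} m/s")

trace = vw.bandpass(vw.simulate_lfp("triphasic", seed=1))
res = vw.classify_morphology(trace, vw.LFPShapeParams("triphasic").event_window_s)
print(f"LFP morphology:    {res.morphology} ({res.n_crossings} crossings, "
      f"{res.initial_polarity} first, span {res.line_length_s:.2f} s, "
      f"{res.p2p_uV:.0f} uV p2p)")
```

which prints:

```
event type:        3b
origin:            CA1 (laminar: deep)
CA1 -> Au1 delay:  28.9 ms
return delay:      91.0 ms
reverb latency:    0.616 s
backfill velocity: 0.45 m/s
LFP morphology:    triphasic (4 crossings, positive first, span 1.62 s, 46 uV p2p)
```

The event was generated with a 25 ms hippocampo-neocortical delay, a 74 ms
return delay, a 0.6 s reverberation latency and 0.47 m/s backfill; the
single-event noisy recovery above is within the expected scatter for each
quantity, and noise-free events recover them to sub-frame accuracy.

A command-line interface mirrors the library
(`vsdwave simulate | preprocess | detect | classify | lfp | run-all |
render`); `vsdwave run-all examples/demo_config.yaml` runs a small
end-to-end demonstration.

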