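"""Event taxonomy: origin, recruitment, laminar profile, reverberation.

The four event types are defined by region of initiation and pattern of
propagation:

* **Type 1** -- non-propagating, hippocampal origin, recruitment confined to
  hippocampus (CA3/CA1);
* **Type 2** -- non-propagating, Au1 origin, hippocampus never recruited;
* **Type 3a** -- hippocampal origin propagating through the periallocortical
  relays into Au1;
* **Type 3b** -- a type 3a event whose neocortical activity re-invades
  hippocampus (reverberation) 0.42-0.78 s after the initial invasion.

Events whose origin is neither hippocampal nor in Au1 (e.g. the occasional
mEC-origin discharge) are left ``unclassified`` rather than forced into a
type.  Classification is a pure function of the measured feature record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .core import (AU1_REGIONS, HIPPOCAMPAL_REGIONS, EventRecord, OnsetMap,
                   RegionAtlas, VSDMovie)
from .preprocess import PreprocessConfig, baseline_frames, run_chain, \
    savgol_differentiate
from .synthetic import AU1_AXIS, MAIN_AXIS
from .wavefront import (backfill_velocity, clean_onset_map,
                        compute_threshold_map, conduction_time, detect_onsets,
                        detect_saltation, peak_dff, project_onto_axis,
                        second_onset_map)

__all__ = [
    "AnalysisConfig",
    "find_origin",
    "measure_extent",
    "laminar_origin",
    "detect_reverberation",
    "classify_event",
    "characterize_event",
]


@dataclass
class AnalysisConfig:
    """Everything tunable about per-event analysis."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    axis_name: str = MAIN_AXIS
    corridor_width_mm: float = 0.2
    profile_step_mm: float = 0.05
    recruit_fraction: float = 0.1       # fraction of region pixels with onsets
    reverb_window_s: Tuple[float, float] = (0.3, 1.0)
    min_sustain_s: float = 0.05         # amplitude validation of crossings
    saltation_min_jump_mm: float = 0.2
    saltation_min_lead_s: float = 0.001
    refractory_s: float = 0.1           # before second-crossing search


def find_origin(onset_map: OnsetMap, atlas: RegionAtlas):
    """Origin region, pixel and time of an event.

    The origin time is the earliest finite onset; because wavefronts reach
    many pixels within one frame, the origin pixel is the centroid of all
    pixels within one frame interval of the minimum (rounded to the nearest
    pixel), and the region is the atlas label there.  Deterministic.
    """
    vals = onset_map.onset_s
    if not np.isfinite(vals).any():
        raise ValueError("onset map has no finite onsets")
    t_min = np.nanmin(vals)
    tie = vals <= t_min + 1.0 / onset_map.frame_rate
    rr, cc = np.nonzero(tie)
    r0 = int(round(rr.mean()))
    c0 = int(round(cc.mean()))
    label = int(atlas.label_image[r0, c0])
    region = atlas.label_names.get(label, "background")
    return region, (r0, c0), float(t_min)


def measure_extent(onset_map: OnsetMap, atlas: RegionAtlas,
                   recruit_fraction: float = 0.1,
                   spread_axis: str = None):
    """Recruited regions and per-lamina horizontal spread.

    A region counts as recruited when at least ``recruit_fraction`` of its
    pixels have finite onsets.  Horizontal spread (per Au1 lamina) is the
    extent, along the cortical axis, of finite-onset pixels in the lamina
    mask, in mm; the lamina-parallel Au1 axis is used when the atlas has
    one (the snaking whole-slice axis is ambiguous next to Au1).
    """
    fin = onset_map.finite_mask
    recruited = set()
    for name in atlas.name_to_label:
        m = atlas.mask(name)
        if m.any() and fin[m].mean() >= recruit_fraction:
            recruited.add(name)
    if spread_axis is None:
        spread_axis = AU1_AXIS if AU1_AXIS in atlas.axis_paths else MAIN_AXIS
    spreads = {}
    d, _ = atlas.axis_distance_map(spread_axis)
    for lamina in sorted(AU1_REGIONS):
        if lamina not in atlas.name_to_label:
            continue
        m = atlas.mask(lamina) & fin
        if m.any():
            dv = d[m]
            spreads[lamina] = float(dv.max() - dv.min())
    return frozenset(recruited), spreads


def laminar_origin(onset_map: OnsetMap, atlas: RegionAtlas) -> str:
    """'superficial' if the earliest Au1 onset lies in L2/3, 'deep' if L5/6.

    'n/a' when Au1 shows no onsets at all.
    """
    best, where = np.inf, "n/a"
    for lamina, tag in (("Au1_L23", "superficial"), ("Au1_L56", "deep")):
        if lamina not in atlas.name_to_label:
            continue
        t = onset_map.earliest_in(atlas.mask(lamina))
        if np.isfinite(t) and t < best:
            best, where = t, tag
    return where


def detect_reverberation(dff_movie: VSDMovie, onset_map: OnsetMap,
                         atlas: RegionAtlas,
                         window_s: Tuple[float, float] = (0.3, 1.0),
                         baseline_window_s=(0.0, 0.5),
                         savgol_window: int = 11, savgol_order: int = 3,
                         min_hip_fraction: float = 0.05):
    """Detect a hippocampal re-activation after neocortical invasion.

    Reverberation requires a second upward 2 SD crossing of the (Savitzky-
    Golay differentiated) hippocampal region-mean dF/F after the Au1 onset,
    with latency inside ``window_s``, and the Au1 region-mean dF/F must not
    have decayed below half its first-wave peak at any point before the
    hippocampal re-entry (the return wave re-ignites in still-depolarised
    neocortex, so the criterion is evaluated on the decay preceding it).
    Returns ``(bool, latency_s or None)``; latency is the second
    hippocampal crossing time minus the Au1 onset time.

    The region-mean trace is used rather than individual pixels: averaging
    ~10^3 pixels makes the second crossing unambiguous at realistic noise.
    """
    hip = atlas.mask_any(r for r in HIPPOCAMPAL_REGIONS
                         if r in atlas.name_to_label)
    au1 = atlas.mask_any(r for r in AU1_REGIONS if r in atlas.name_to_label)
    if not hip.any() or not au1.any():
        return False, None
    # a return wave needs a hippocampal first wave to return to
    if onset_map.finite_mask[hip].mean() < min_hip_fraction:
        return False, None
    t_au1 = onset_map.earliest_in(au1)
    if not np.isfinite(t_au1):
        return False, None
    fs = dff_movie.frame_rate
    times = dff_movie.times
    hip_trace = dff_movie.frames[:, hip].mean(axis=1)
    au1_trace = dff_movie.frames[:, au1].mean(axis=1)
    deriv = savgol_differentiate(hip_trace, savgol_window, savgol_order,
                                 sample_rate=fs)
    sl = baseline_frames(dff_movie, baseline_window_s)
    thr = deriv[sl].mean() + 2.0 * deriv[sl].std()
    # floor at 5% of the first-wave derivative peak: a re-entrant wave is
    # comparable to the initial invasion, whereas a near-zero baseline SD
    # (noise-free or quantised data) would otherwise let decay-phase
    # wiggles register as second crossings
    thr = max(thr, 0.05 * float(deriv.max()))
    above = deriv > thr
    # sustained (2-frame) upward crossings of the derivative threshold
    up = np.nonzero(~above[:-2] & above[1:-1] & above[2:])[0] + 1
    # first-wave Au1 peak: within 0.3 s of the Au1 onset (before any
    # re-entrant activity can re-elevate the trace)
    first_wave = (times >= t_au1) & (times <= t_au1 + 0.3)
    if not first_wave.any():
        return False, None
    peak1 = au1_trace[first_wave].max()
    t_peak1 = times[first_wave][au1_trace[first_wave].argmax()]
    for i in up:
        frac = (thr - deriv[i - 1]) / (deriv[i] - deriv[i - 1])
        t_cross = (i - 1 + frac) / fs
        latency = t_cross - t_au1
        if latency < window_s[0]:
            continue
        if latency > window_s[1]:
            break
        between = (times >= t_peak1) & (times <= t_cross)
        if au1_trace[between].min() > 0.5 * peak1:
            return True, float(latency)
    return False, None


def classify_event(origin_region: str, recruited_regions,
                   reverberates: bool) -> str:
    """Map measured features to the four-type taxonomy (pure function)."""
    recruited = frozenset(recruited_regions)
    hip = HIPPOCAMPAL_REGIONS
    if not recruited:
        return "unclassified"
    if origin_region in hip:
        if recruited <= hip:
            return "1"
        if recruited & AU1_REGIONS:
            return "3b" if reverberates else "3a"
        return "unclassified"
    if origin_region in AU1_REGIONS and not (recruited & hip):
        return "2"
    return "unclassified"


def _second_wave_onsets(detect_movie, detect_thr, dff, first_onsets,
                        center_s, cfg: AnalysisConfig,
                        half_window_s: float = 0.25,
                        rise_fraction: float = 0.35):
    """Per-pixel onset of the reverberatory second wave.

    Candidate re-crossings are searched only within +-``half_window_s`` of
    the (robustly detected) re-entry time, and each candidate must be
    followed within 150 ms by a smoothed-dF/F rise of at least
    ``rise_fraction`` of the pixel's first-wave peak -- a genuine return
    wave re-depolarises by roughly half the original amplitude, whereas
    chance derivative crossings show no amplitude rise.  Spatially isolated
    survivors are dropped as usual.
    """
    from scipy.signal import savgol_filter

    fs = detect_movie.frame_rate
    T = detect_movie.n_frames
    start = np.where(np.isfinite(first_onsets.onset_s),
                     np.maximum(first_onsets.onset_s + cfg.refractory_s,
                                center_s - half_window_s), np.nan)
    cand = detect_onsets(detect_movie, detect_thr, search_after_s=start)
    cand.onset_s[cand.onset_s > center_s + half_window_s] = np.nan

    smooth = savgol_filter(dff.frames, cfg.preprocess.savgol_window,
                           cfg.preprocess.savgol_order, axis=0)
    k = max(int(round(0.15 * fs)), 1)
    pad = np.concatenate([smooth, np.repeat(smooth[-1:], k - 1, axis=0)])
    fwd_max = np.max(np.lib.stride_tricks.sliding_window_view(
        pad, k, axis=0), axis=-1)
    ref_end = max(int(np.floor((center_s - half_window_s) * fs)), 1)
    first_peak = smooth[:ref_end].max(axis=0)

    idx = np.clip(np.nan_to_num(cand.onset_s * fs, nan=0).astype(int), 0,
                  T - 1)
    rr, cc = np.indices(idx.shape)
    rise = fwd_max[idx, rr, cc] - smooth[idx, rr, cc]
    valid = np.isfinite(cand.onset_s) & \
        (rise >= rise_fraction * first_peak)
    cand.onset_s[~valid] = np.nan
    return clean_onset_map(cand)


def characterize_event(movie: VSDMovie, atlas: RegionAtlas,
                       config: AnalysisConfig = None,
                       event_id: str = "event",
                       artifacts: Optional[dict] = None) -> EventRecord:
    """Full per-event analysis: preprocess, detect, measure, classify.

    If ``artifacts`` is a dict it is filled with the intermediate products
    (onset map, axis profile, dF/F movie) for export.
    """
    cfg = config or AnalysisConfig()
    filtered, dff = run_chain(movie, cfg.preprocess)
    bw = cfg.preprocess.baseline_window_s
    atlas_b = atlas.rebin(cfg.preprocess.bin_factor)

    thr_filt = compute_threshold_map(filtered, bw)
    thr_dff = compute_threshold_map(dff, bw)
    detect_movie = filtered if cfg.preprocess.threshold_signal == "derivative" \
        else dff
    detect_thr = thr_filt if cfg.preprocess.threshold_signal == "derivative" \
        else thr_dff
    onsets = detect_onsets(detect_movie, detect_thr,
                           validation_movie=dff,
                           validation_threshold_map=thr_dff,
                           min_sustain_s=cfg.min_sustain_s)
    onsets = clean_onset_map(onsets)

    region, xy, t0 = find_origin(onsets, atlas_b)
    recruited, spreads = measure_extent(onsets, atlas_b,
                                        cfg.recruit_fraction)
    lam = laminar_origin(onsets, atlas_b)
    reverb, latency = detect_reverberation(dff, onsets, atlas_b,
                                           cfg.reverb_window_s, bw,
                                           cfg.preprocess.savgol_window,
                                           cfg.preprocess.savgol_order)
    etype = classify_event(region, recruited, reverb)

    conduction = {}
    if {"CA1"} <= recruited and recruited & AU1_REGIONS:
        try:
            conduction["CA1->Au1_L56"] = conduction_time(
                onsets, atlas_b, "CA1", "Au1_L56")
        except ValueError:
            pass
        if reverb:
            au1_mask = atlas_b.mask_any(r for r in AU1_REGIONS
                                        if r in atlas_b.name_to_label)
            t_au1 = onsets.earliest_in(au1_mask)
            second = _second_wave_onsets(detect_movie, detect_thr, dff,
                                         onsets, t_au1 + latency, cfg)
            try:
                conduction["Au1->CA1_return"] = conduction_time(
                    second, atlas_b, "Au1_L56", "CA1")
            except ValueError:
                pass

    profile = project_onto_axis(onsets, atlas_b, cfg.axis_name,
                                cfg.corridor_width_mm, cfg.profile_step_mm)
    salts = detect_saltation(profile, cfg.saltation_min_jump_mm,
                             cfg.saltation_min_lead_s)
    backfill = {}
    if recruited & {"mEC", "lEC"}:
        backfill = backfill_velocity(onsets, atlas_b,
                                     regions=sorted(recruited & {"mEC", "lEC"}),
                                     axis_name=cfg.axis_name)

    peaks = {}
    for r in sorted(recruited):
        try:
            peaks[r] = peak_dff(dff, atlas_b, r)
        except ValueError:
            pass

    if artifacts is not None:
        artifacts.update(onsets=onsets, profile=profile, dff=dff,
                         backfill_velocity_m_s=backfill)

    return EventRecord(
        event_id=event_id, event_type=etype, origin_region=region,
        origin_xy=xy, origin_time_s=t0, recruited_regions=recruited,
        laminar_origin=lam, horizontal_spread_mm=spreads,
        conduction_times_ms=conduction, reverb_latency_s=latency,
        saltations=salts, backfill_velocity_m_s=backfill,
        peak_dff_pct=peaks,
    )
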