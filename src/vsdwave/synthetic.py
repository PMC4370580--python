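"""Synthetic VSD movies, region atlases and LFP traces with known kinematics.

The generator is the test bench for the whole pipeline: every event is built
from an analytic kinematic description (piecewise wavefront branches along
the hippocampo-neocortical axis), so ground-truth onset times exist in
closed form and downstream stages can be validated by parameter recovery.

Default kinematic presets (velocities in m/s, delays in ms):

================================  ======
CA1, propagating events (type 3)    0.37
CA1, non-propagating (type 1)       0.17
CA3 spread                          0.04
periallocortical backfill           0.47
perirhinal spread                   0.02
CA1 focus -> Au1 deep layers       25 ms
Au1 -> CA1 return wave             74 ms
Au1 L2/3 -> L5 (type 2)             8 ms
Au1 L5/6 -> L2/3 (type 3)          17 ms
reverberation latency        0.42-0.78 s
================================  ======

The default field of view is 100 x 100 pixels at 25 um/pixel (2.5 mm square)
sampled at 200 Hz; the anatomical axis snakes through three bands of regions
(hippocampus / periallocortex / Au1) and spans > 9 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq
from skimage.draw import polygon as _sk_polygon

from .core import AxisPath, LFPTrace, OnsetMap, RegionAtlas, VSDMovie

__all__ = [
    "MAIN_AXIS", "AU1_AXIS", "VELOCITY_PRESETS", "DELAY_PRESETS_MS",
    "REVERB_WINDOW_S",
    "DEFAULT_F0", "DEFAULT_NOISE_SD", "DEFAULT_BLEACH_RATE",
    "default_geometry", "build_region_atlas",
    "Branch", "Jump", "EventSpec", "make_event_spec",
    "EventTruth", "SimulatedEvent", "simulate_event", "add_noise_and_bleach",
    "CohortSpec", "simulate_cohort", "iter_cohort",
    "LFPShapeParams", "LaminarPairParams", "simulate_lfp", "simulate_lfp_pair",
]

MAIN_AXIS = "hippocampo_neocortical"
AU1_AXIS = "au1_cortical"

VELOCITY_PRESETS = {
    "ca1_type3": 0.37,       # initial rapid CA1 spread, propagating events
    "ca1_type1": 0.17,       # slow CA1 spread, non-propagating events
    "ca3": 0.04,             # spread toward/through CA3
    "backfill": 0.47,        # post-jump back-propagation toward subiculum
    "perirhinal": 0.02,      # slowing at the perirhinal boundary
    "subiculum": 0.10,       # slowing at the CA1-subiculum border
    "au1_en_passant": 0.30,  # deep-layer horizontal spread within Au1
    "au1_type2": 0.10,       # horizontal spread of Au1-origin events
    "mec_local": 0.05,       # local spread of mEC-origin events
}

DELAY_PRESETS_MS = {
    "ca1_to_au1": 25.0,      # CA1 focus to Au1 deep layers (type 3)
    "au1_return": 74.0,      # Au1 back to CA1 (type 3b return wave)
    "l23_to_l5": 8.0,        # interlaminar, Au1-origin events
    "l56_to_l23": 17.0,      # interlaminar, hippocampus-origin events
}

#: admissible window for reverberation latency (s)
REVERB_WINDOW_S = (0.42, 0.78)

DEFAULT_F0 = 20000.0          # resting fluorescence, camera counts
#: noise default: Gaussian, SD = 20% of the largest origin peak dF/F (0.16%)
DEFAULT_NOISE_SD = 0.2 * 0.0016 * DEFAULT_F0   # = 6.4 counts
DEFAULT_BLEACH_RATE = 0.01    # fractional fluorescence loss per second

_DEFAULT_DURATION_S = {"1": 1.6, "2": 1.6, "3a": 1.6, "3b": 2.0, "other": 1.6}
_DEFAULT_EVENT_DURATION_S = {"1": 0.8, "2": 0.6, "3a": 1.2, "3b": 2.0,
                             "other": 0.6}


# --------------------------------------------------------------------------
# region atlas
# --------------------------------------------------------------------------

def default_geometry() -> dict:
    """Default slice geometry: three region bands joined by one snaking axis.

    Band 1 (top) is hippocampus proper plus subiculum, band 2 the
    periallocortical relays in reverse order, band 3 the two Au1 laminae;
    the hippocampo-neocortical axis runs CA3 -> CA1 -> subiculum -> mEC ->
    lEC -> perirhinal -> Au1 deep layers.
    """
    def rect(r0, r1, c0, c1):
        return [(r0, c0), (r0, c1), (r1, c1), (r1, c0)]

    return {
        "grid": (100, 100),
        "pixel_pitch_mm": 0.025,
        "regions": [
            {"name": "CA3",        "label": 1, "polygon": rect(0, 31, 0, 23)},
            {"name": "CA1",        "label": 2, "polygon": rect(0, 31, 24, 73)},
            {"name": "subiculum",  "label": 3, "polygon": rect(0, 31, 74, 99)},
            {"name": "mEC",        "label": 4, "polygon": rect(34, 65, 64, 99)},
            {"name": "lEC",        "label": 5, "polygon": rect(34, 65, 24, 63)},
            {"name": "perirhinal", "label": 6, "polygon": rect(34, 65, 0, 23)},
            {"name": "Au1_L23",    "label": 7, "polygon": rect(68, 83, 0, 99)},
            {"name": "Au1_L56",    "label": 8, "polygon": rect(84, 99, 0, 99)},
        ],
        "axes": {
            MAIN_AXIS: [(16, 0), (16, 99), (50, 99), (50, 0), (92, 0), (92, 99)],
            # lamina-parallel axis for horizontal position within Au1; kept
            # separate so Au1 pixels never project onto the inter-band
            # connector of the snaking main axis
            AU1_AXIS: [(92, 0), (92, 99)],
        },
    }


def build_region_atlas(geometry_config: dict = None) -> RegionAtlas:
    """Rasterise a geometry config into a :class:`RegionAtlas`.

    The config lists region polygons as (row, col) vertex lists on the pixel
    grid, the pixel pitch, and ordered axis waypoints.  Overlapping polygons
    and axis paths leaving the grid are rejected.
    """
    cfg = geometry_config or default_geometry()
    h, w = cfg["grid"]
    pitch = float(cfg["pixel_pitch_mm"])
    label_image = np.zeros((h, w), dtype=np.int64)
    names: Dict[int, str] = {}
    for reg in cfg["regions"]:
        verts = np.asarray(reg["polygon"], dtype=float)
        rr, cc = _rect_safe_polygon(verts, (h, w))
        if np.any(label_image[rr, cc] != 0):
            clash = {names[l] for l in np.unique(label_image[rr, cc]) if l != 0}
            raise ValueError(
                f"region {reg['name']!r} overlaps {sorted(clash)}")
        label_image[rr, cc] = reg["label"]
        names[int(reg["label"])] = reg["name"]
    axes = {}
    for name, waypoints in cfg["axes"].items():
        pts = np.asarray(waypoints, dtype=float)
        if (pts < -0.5).any() or (pts[:, 0] > h - 0.5).any() or (pts[:, 1] > w - 0.5).any():
            raise ValueError(f"axis {name!r} leaves the pixel grid")
        xy = np.column_stack([pts[:, 1] * pitch, pts[:, 0] * pitch])
        axes[name] = AxisPath(name, xy)
    return RegionAtlas(label_image=label_image, label_names=names,
                       axis_paths=axes, pixel_pitch_mm=pitch)


def _rect_safe_polygon(verts: np.ndarray, shape) -> tuple:
    """Pixel-centre coverage of a polygon given by vertex pixel coordinates.

    Vertices are expanded by half a pixel outward from the polygon centroid
    so that axis-aligned rectangles cover exactly their stated pixel range.
    """
    centroid = verts.mean(axis=0)
    grown = verts + 0.5 * np.sign(verts - centroid)
    return _sk_polygon(grown[:, 0], grown[:, 1], shape=shape)


def _dmap(atlas: RegionAtlas, axis_name: str = MAIN_AXIS) -> np.ndarray:
    """Cached along-axis distance of every atlas pixel."""
    cache = atlas.__dict__.setdefault("_dmap_cache", {})
    if axis_name not in cache:
        d, _off = atlas.axis_distance_map(axis_name)
        cache[axis_name] = d
    return cache[axis_name]


def _axis_spans(atlas: RegionAtlas, axis_name: str = MAIN_AXIS):
    d = _dmap(atlas, axis_name)
    spans = {}
    for lab, name in atlas.label_names.items():
        m = atlas.label_image == lab
        if m.any():
            spans[name] = (float(d[m].min()), float(d[m].max()))
    return spans


# --------------------------------------------------------------------------
# event specification
# --------------------------------------------------------------------------

@dataclass
class Branch:
    """One wavefront branch: onset is t0 + |d - d0| / v inside [d_lo, d_hi].

    ``wave`` distinguishes the primary invasion (1) from the reverberatory
    second wave (2).  ``t0_s`` is relative to the event's origin time.
    ``axis`` overrides the event's axis for this branch (Au1-internal
    branches run along the cortical lamina axis).
    """

    t0_s: float
    d0_mm: float
    velocity_m_s: float
    d_lo_mm: float
    d_hi_mm: float
    regions: frozenset
    wave: int = 1
    axis: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.velocity_m_s > 0:
            raise ValueError("branch velocity must be > 0")
        self.regions = frozenset(self.regions)


@dataclass
class Jump:
    """Ground truth for one saltatory step (times relative to origin)."""

    from_mm: float
    to_mm: float
    time_s: float
    backfill_velocity_m_s: float


@dataclass
class EventSpec:
    """Complete kinematic description of one synthetic interictal event.

    ``event_type`` is one of '1', '2', '3a', '3b' (plus 'other' for the
    occasional mEC-origin events that the classifier must leave
    unclassified).  ``segment_kinematics`` is the branch list realised by
    :func:`simulate_event`; ``jump_list`` records the saltatory steps.
    """

    event_type: str
    origin_region: str
    origin_xy: Tuple[int, int]
    segment_kinematics: List[Branch]
    jump_list: List[Jump] = field(default_factory=list)
    reverb_latency_s: Optional[float] = None
    peak_dff: Dict[str, float] = field(default_factory=dict)
    event_duration_s: float = 0.8
    seed: int = 0
    origin_time_s: float = 0.6
    duration_s: float = 1.6          # movie length
    frame_rate: float = 200.0
    f0_counts: float = DEFAULT_F0
    rise_time_s: float = 0.02
    half_decay_s: float = 0.8
    axis_name: str = MAIN_AXIS
    reverb_window_s: Tuple[float, float] = REVERB_WINDOW_S

    def __post_init__(self) -> None:
        if self.event_type not in {"1", "2", "3a", "3b", "other"}:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if (self.event_type == "3b") != (self.reverb_latency_s is not None):
            raise ValueError("reverb_latency_s must be present iff type 3b")
        if self.reverb_latency_s is not None:
            lo, hi = self.reverb_window_s
            if not lo <= self.reverb_latency_s <= hi:
                raise ValueError(
                    f"reverb latency {self.reverb_latency_s} s outside "
                    f"window [{lo}, {hi}] s")
        if not 0.2 <= self.event_duration_s <= 2.8:
            raise ValueError("event_duration_s must lie in [0.2, 2.8] s")
        for br in self.segment_kinematics:
            if not br.velocity_m_s > 0:
                raise ValueError("all branch velocities must be > 0")


def make_event_spec(event_type: str, atlas: RegionAtlas, *,
                    reverb_latency_s: float = 0.6,
                    origin_col: int = 50,
                    peak_dff: Dict[str, float] = None,
                    jump_delay_s: float = 0.002,
                    ca1_spread_mm: float = 0.5,
                    seed: int = 0, **overrides) -> EventSpec:
    """Build the paper-default kinematic preset for one event type.

    Branch timings are derived from the atlas' own axis spans so the preset
    adapts to any geometry; the CA1 -> Au1 (25 ms) and Au1 -> CA1 (74 ms)
    conduction delays and the laminar offsets (8 / 17 ms) are anchored
    exactly.
    """
    v = VELOCITY_PRESETS
    spans = _axis_spans(atlas, overrides.get("axis_name", MAIN_AXIS))
    required = {"1": ["CA3", "CA1"], "2": ["Au1_L23", "Au1_L56"],
                "other": ["mEC"]}.get(
        event_type, ["CA3", "CA1", "subiculum", "mEC", "lEC", "perirhinal",
                     "Au1_L23", "Au1_L56"])
    missing = [r for r in required if r not in spans]
    if missing:
        raise ValueError(f"atlas is missing regions {missing} required for a "
                         f"type-{event_type} event")

    branches: List[Branch] = []
    jumps: List[Jump] = []
    pitch = atlas.pixel_pitch_mm
    au1_axis = AU1_AXIS if AU1_AXIS in atlas.axis_paths else None
    au1_spans = _axis_spans(atlas, au1_axis) if au1_axis else spans

    def ray(t0, d0, vel, lo, hi, regions, wave=1, axis=None):
        branches.append(Branch(t0, d0, vel, lo, hi, frozenset(regions), wave,
                               axis))

    if event_type in {"1", "3a", "3b"}:
        ca1_lo, ca1_hi = spans["CA1"]
        d0 = ca1_lo                      # CA1/CA2 border focus
        # centre row of CA1 as the nominal origin pixel
        rows = np.nonzero(atlas.mask("CA1").any(axis=1))[0]
        cols = np.nonzero(atlas.mask("CA1").any(axis=0))[0]
        origin_xy = (int(rows.mean()), int(cols.min()))
        ray(0.0, d0, v["ca3"], spans["CA3"][0], d0, {"CA3"})
        if event_type == "1":
            ray(0.0, d0, v["ca1_type1"], d0, d0 + ca1_spread_mm, {"CA1"})
            return EventSpec("1", "CA1", origin_xy, branches,
                             peak_dff=peak_dff or {"CA1": 0.14, "CA3": 0.10},
                             event_duration_s=_DEFAULT_EVENT_DURATION_S["1"],
                             duration_s=_DEFAULT_DURATION_S["1"],
                             seed=seed, **overrides)
        ray(0.0, d0, v["ca1_type3"], ca1_lo, ca1_hi, {"CA1"})
        t_ca1_end = (ca1_hi - d0) / (1000.0 * v["ca1_type3"])
        sub_lo, sub_hi = spans["subiculum"]
        ray(t_ca1_end, ca1_hi, v["subiculum"], sub_lo, sub_hi, {"subiculum"})
        t_sub_end = t_ca1_end + (sub_hi - ca1_hi) / (1000.0 * v["subiculum"])
        # saltatory periallocortical spread: jump to distal mEC, backfill,
        # jump to distal lEC, backfill; slow forward leak into perirhinal
        t_j1 = t_sub_end + jump_delay_s
        mec_lo, mec_hi = spans["mEC"]
        ray(t_j1, mec_hi, v["backfill"], mec_lo, mec_hi, {"mEC"})
        jumps.append(Jump(sub_hi, mec_hi, t_j1, v["backfill"]))
        t_j2 = t_j1 + 2 * jump_delay_s
        lec_lo, lec_hi = spans["lEC"]
        ray(t_j2, lec_hi, v["backfill"], lec_lo, lec_hi, {"lEC"})
        jumps.append(Jump(mec_hi, lec_hi, t_j2, v["backfill"]))
        prh_lo, prh_hi = spans["perirhinal"]
        ray(t_j2, lec_hi, v["perirhinal"], prh_lo, prh_hi, {"perirhinal"})
        # Au1 invasion anchored at the 25 ms overall conduction delay;
        # entry at the periallocortical (low-x) end of the cortical axis
        t_au1 = DELAY_PRESETS_MS["ca1_to_au1"] / 1000.0
        au_lo, au_hi = au1_spans["Au1_L56"]
        ray(t_au1, au_lo, v["au1_en_passant"], au_lo, au_hi, {"Au1_L56"},
            axis=au1_axis)
        a23_lo, a23_hi = au1_spans["Au1_L23"]
        t_l23 = t_au1 + DELAY_PRESETS_MS["l56_to_l23"] / 1000.0
        ray(t_l23, au_lo, v["au1_en_passant"], a23_lo, a23_hi, {"Au1_L23"},
            axis=au1_axis)
        etype = event_type
        if etype == "3b":
            lat = reverb_latency_s
            t_ret0 = t_au1 + lat - DELAY_PRESETS_MS["au1_return"] / 1000.0
            # return velocity set so the wave reaches CA1 exactly 74 ms
            # after re-igniting at the Au1 border of the main axis
            au_main_lo = spans["Au1_L56"][0]
            v_ret = (au_main_lo - ca1_hi) / (DELAY_PRESETS_MS["au1_return"])
            ray(t_ret0, au_main_lo, v_ret, spans["CA3"][0], au_main_lo,
                {"CA1", "CA3", "subiculum", "mEC", "lEC", "perirhinal"},
                wave=2)
            ray(t_ret0, au_lo, v["au1_en_passant"], au_lo, au_hi,
                {"Au1_L56"}, wave=2, axis=au1_axis)
        dff = peak_dff or ({"CA1": 0.16, "CA3": 0.08} if etype == "3a"
                           else {"CA1": 0.12, "CA3": 0.08})
        for r in ("subiculum", "mEC", "lEC", "perirhinal",
                  "Au1_L23", "Au1_L56"):
            dff.setdefault(r, 0.10)
        return EventSpec(etype, "CA1", origin_xy, branches, jumps,
                         reverb_latency_s=(reverb_latency_s if etype == "3b"
                                           else None),
                         peak_dff=dff,
                         event_duration_s=_DEFAULT_EVENT_DURATION_S[etype],
                         duration_s=_DEFAULT_DURATION_S[etype],
                         seed=seed, **overrides)

    if event_type == "2":
        # focus position along the cortical axis; horizontal confinement to
        # 1.5 mm (L2/3) / 1.6 mm (L5/6) around it
        d_o = origin_col * pitch
        ray(0.0, d_o, v["au1_type2"], d_o - 0.75, d_o + 0.75, {"Au1_L23"},
            axis=au1_axis)
        ray(DELAY_PRESETS_MS["l23_to_l5"] / 1000.0, d_o, v["au1_type2"],
            d_o - 0.80, d_o + 0.80, {"Au1_L56"}, axis=au1_axis)
        rows = np.nonzero(atlas.mask("Au1_L23").any(axis=1))[0]
        origin_xy = (int(rows.mean()), int(origin_col))
        return EventSpec("2", "Au1_L23", origin_xy, branches,
                         peak_dff=peak_dff or {"Au1_L23": 0.12,
                                               "Au1_L56": 0.10},
                         event_duration_s=_DEFAULT_EVENT_DURATION_S["2"],
                         duration_s=_DEFAULT_DURATION_S["2"],
                         seed=seed, **overrides)

    # 'other': locally spreading mEC-origin event (left unclassified downstream)
    mec_lo, mec_hi = spans["mEC"]
    d_o = 0.5 * (mec_lo + mec_hi)
    ray(0.0, d_o, v["mec_local"], mec_lo, mec_hi, {"mEC"})
    rows = np.nonzero(atlas.mask("mEC").any(axis=1))[0]
    cols = np.nonzero(atlas.mask("mEC").any(axis=0))[0]
    origin_xy = (int(rows.mean()), int(cols.mean()))
    return EventSpec("other", "mEC", origin_xy, branches,
                     peak_dff=peak_dff or {"mEC": 0.10},
                     event_duration_s=_DEFAULT_EVENT_DURATION_S["other"],
                     duration_s=_DEFAULT_DURATION_S["other"],
                     seed=seed, **overrides)


# --------------------------------------------------------------------------
# movie synthesis
# --------------------------------------------------------------------------

@dataclass
class EventTruth:
    """Analytic ground truth returned alongside every simulated movie."""

    onset: OnsetMap                       # first-wave onset per pixel
    second_onset_s: Optional[np.ndarray]  # reverberatory wave, or None
    spec: EventSpec


@dataclass
class SimulatedEvent:
    event_id: str
    movie: VSDMovie
    spec: EventSpec
    truth: EventTruth


def _branch_onsets(spec: EventSpec, atlas: RegionAtlas, wave: int) -> np.ndarray:
    onset = np.full(atlas.shape, np.inf)
    eps = 1e-9
    for br in spec.segment_kinematics:
        if br.wave != wave:
            continue
        missing = [r for r in br.regions if r not in atlas.name_to_label]
        if missing:
            raise ValueError(f"event references regions absent from atlas: "
                             f"{missing}")
        d = _dmap(atlas, br.axis or spec.axis_name)
        m = atlas.mask_any(br.regions)
        m &= (d >= br.d_lo_mm - eps) & (d <= br.d_hi_mm + eps)
        t = spec.origin_time_s + br.t0_s + \
            np.abs(d - br.d0_mm) / (1000.0 * br.velocity_m_s)
        onset[m] = np.minimum(onset[m], t[m])
    onset[np.isinf(onset)] = np.nan
    return onset


def _waveform(t: np.ndarray, onset: np.ndarray, rise: float,
              half_decay: float) -> np.ndarray:
    """Normalised fluorescence time course: half-cosine rise, exp decay.

    ``t`` has shape (T,), ``onset`` shape (P,); returns (T, P).  The onset
    is hard (exactly zero before it), so the analytic onset time is also
    the first suprathreshold instant at any positive threshold.
    """
    u = t[:, None] - onset[None, :]
    out = np.zeros_like(u)
    rising = (u >= 0) & (u < rise)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * u[rising] / rise))
    decaying = u >= rise
    out[decaying] = np.exp2(-(u[decaying] - rise) / half_decay)
    return out


def simulate_event(spec: EventSpec, atlas: RegionAtlas):
    """Render one event spec into a noise-free movie plus analytic truth.

    Every pixel's fluorescence rises (half-cosine, ``rise_time_s``) at its
    ground-truth onset time and decays exponentially; type 3b events add the
    reverberatory second wave (pointwise maximum of the two waves).
    Amplitudes are scaled per region to ``spec.peak_dff`` percent of the
    resting fluorescence ``f0_counts``.
    """
    onset1 = _branch_onsets(spec, atlas, wave=1)
    onset2 = _branch_onsets(spec, atlas, wave=2)
    has_wave2 = np.isfinite(onset2).any()

    amp_pct = np.zeros(atlas.shape)
    for region, pct in spec.peak_dff.items():
        if region not in atlas.name_to_label:
            raise ValueError(f"peak_dff references region {region!r} absent "
                             f"from atlas")
        amp_pct[atlas.mask(region)] = pct

    n_frames = int(round(spec.duration_s * spec.frame_rate))
    t = np.arange(n_frames) / spec.frame_rate
    frames = np.full((n_frames,) + atlas.shape, spec.f0_counts, dtype=np.float64)

    active = np.isfinite(onset1)
    if active.any():
        s = _waveform(t, onset1[active], spec.rise_time_s, spec.half_decay_s)
        if has_wave2:
            o2 = onset2[active]
            fin2 = np.isfinite(o2)
            if fin2.any():
                s2 = _waveform(t, o2[fin2], spec.rise_time_s,
                               spec.half_decay_s)
                s[:, fin2] = np.maximum(s[:, fin2], s2)
        frames[:, active] += spec.f0_counts * (amp_pct[active] / 100.0) * s

    movie = VSDMovie(frames.astype(np.float32), frame_rate=spec.frame_rate,
                     pixel_pitch_mm=atlas.pixel_pitch_mm,
                     meta={"event_type": spec.event_type,
                           "origin_region": spec.origin_region})
    truth = EventTruth(
        onset=OnsetMap(onset1, atlas.pixel_pitch_mm, spec.frame_rate,
                       meta={"event_type": spec.event_type}),
        second_onset_s=onset2 if has_wave2 else None,
        spec=spec,
    )
    return movie, truth


def add_noise_and_bleach(movie: VSDMovie,
                         noise_sd: float = DEFAULT_NOISE_SD,
                         bleach_rate: float = DEFAULT_BLEACH_RATE,
                         seed: int = 0) -> VSDMovie:
    """Multiplicative exponential bleaching plus additive Gaussian noise.

    Frame-t fluorescence is scaled by exp(-bleach_rate * t) before
    independent per-pixel/frame noise of the given SD (camera counts) is
    added.  Deterministic for a fixed seed; the identity when both are zero.
    """
    frames = movie.frames.astype(np.float64)
    if bleach_rate != 0:
        frames = frames * np.exp(-bleach_rate * movie.times)[:, None, None]
    if noise_sd != 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return movie.with_frames(frames.astype(movie.frames.dtype))


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Composition and noise conditions of a simulated event cohort.

    The default composition mirrors the reported 57-event study: 14 type 1,
    11 type 2, 23 type 3a, 7 type 3b and 2 mEC-origin events.
    """

    n_type1: int = 14
    n_type2: int = 11
    n_type3a: int = 23
    n_type3b: int = 7
    n_other: int = 2
    master_seed: int = 7
    noise_sd: float = DEFAULT_NOISE_SD
    bleach_rate: float = DEFAULT_BLEACH_RATE

    def __post_init__(self) -> None:
        for n in (self.n_type1, self.n_type2, self.n_type3a, self.n_type3b,
                  self.n_other):
            if n < 0:
                raise ValueError("cohort counts must be >= 0")

    @property
    def total(self) -> int:
        return (self.n_type1 + self.n_type2 + self.n_type3a + self.n_type3b
                + self.n_other)


def iter_cohort(cohort: CohortSpec, atlas: RegionAtlas):
    """Yield :class:`SimulatedEvent`s one at a time (memory-friendly).

    Per-event randomness (reverberation latency, type-2 focus position,
    amplitude jitter, noise realisation) derives reproducibly from the
    master seed via spawned seed sequences.
    """
    order = (["1"] * cohort.n_type1 + ["2"] * cohort.n_type2 +
             ["3a"] * cohort.n_type3a + ["3b"] * cohort.n_type3b +
             ["other"] * cohort.n_other)
    for i, etype in enumerate(order):
        ss = np.random.SeedSequence(cohort.master_seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        kwargs = {"seed": int(rng.integers(2 ** 31))}
        if etype == "3b":
            kwargs["reverb_latency_s"] = float(rng.uniform(*REVERB_WINDOW_S))
        if etype == "2":
            kwargs["origin_col"] = int(rng.integers(40, 61))
        spec = make_event_spec(etype, atlas, **kwargs)
        # mild amplitude variability around the per-type defaults
        jitter = float(np.clip(1.0 + rng.normal(0.0, 0.1), 0.6, 1.4))
        spec.peak_dff = {k: v * jitter for k, v in spec.peak_dff.items()}
        movie, truth = simulate_event(spec, atlas)
        if cohort.noise_sd != 0 or cohort.bleach_rate != 0:
            movie = add_noise_and_bleach(movie, cohort.noise_sd,
                                         cohort.bleach_rate, seed=spec.seed)
        yield SimulatedEvent(f"ev{i:03d}", movie, spec, truth)


def simulate_cohort(cohort: CohortSpec, atlas: RegionAtlas) -> list:
    """Materialised cohort with exactly the requested composition."""
    return list(iter_cohort(cohort, atlas))


# --------------------------------------------------------------------------
# LFP synthesis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LFPShapeParams:
    """Shape parameters of a synthetic pial LFP event.

    ``span_s`` is the target first-to-last +2 SD crossing span measured on
    the band-passed trace; the generator calibrates its lobe layout and
    amplitude scale so the measured span and peak-to-peak hit the targets
    under the default analysis (0.5-100 Hz zero-phase band-pass, robust
    +2 SD level).  ``noise_sd_uV`` models baseline microelectrode noise in
    the raw (pre-filter) trace.
    """

    morphology: str = "biphasic"      # 'biphasic' | 'triphasic'
    span_s: float = None              # default 1.17 (bi) / 1.62 (tri)
    p2p_uV: float = None              # default 42 (bi) / 46 (tri)
    sample_rate: float = 2000.0
    epoch_s: float = 10.0
    event_time_s: float = 3.0
    noise_sd_uV: float = 1.5

    def __post_init__(self) -> None:
        if self.morphology not in ("biphasic", "triphasic"):
            raise ValueError("morphology must be 'biphasic' or 'triphasic'")
        if self.span_s is None:
            object.__setattr__(self, "span_s",
                               1.17 if self.morphology == "biphasic" else 1.62)
        if self.p2p_uV is None:
            object.__setattr__(self, "p2p_uV",
                               42.0 if self.morphology == "biphasic" else 46.0)

    @property
    def event_window_s(self):
        """Analysis window bracketing the event (for crossing counts)."""
        return (self.event_time_s - 0.2, self.event_time_s + 2.8)


def _hann_lobe(t: np.ndarray, t0: float, width: float, amp: float):
    u = (t - t0) / width
    out = np.zeros_like(t)
    m = (u >= 0) & (u <= 1)
    out[m] = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * u[m]))
    return out


def _tukey_lobe(t: np.ndarray, t0: float, width: float, amp: float,
                taper: float = 0.2):
    u = (t - t0) / width
    out = np.zeros_like(t)
    m = (u >= 0) & (u <= 1)
    x = u[m]
    y = np.ones_like(x)
    y[x < taper] = 0.5 * (1 - np.cos(np.pi * x[x < taper] / taper))
    y[x > 1 - taper] = 0.5 * (1 - np.cos(np.pi * (1 - x[x > 1 - taper]) / taper))
    out[m] = amp * y
    return out


def _target_waveform(p: LFPShapeParams, knob: float) -> np.ndarray:
    """The *conditioned* (post-band-pass) waveform the trace must show.

    Biphasic: a short negative deflection then one wide flat-topped positive
    slow wave (width = knob).  Triphasic: a narrow positive spike, an
    adjacent trough, and a second positive slow wave whose position
    (= knob) sets the first-to-last crossing span.  Amplitudes are unit
    peak-to-peak; the generator synthesises the raw trace by exact inverse
    filtering, so the standard 0.5-100 Hz conditioning reproduces this
    shape rather than tilting it (a >1 s wave cannot survive any 0.5 Hz
    high-pass unless the raw trace pre-compensates the attenuation, exactly
    as the tissue's large slow potentials are attenuated by AC coupling).
    """
    n = int(round(p.epoch_s * p.sample_rate))
    t = np.arange(n) / p.sample_rate
    te = p.event_time_s
    # shallow guard undershoots flank each slow wave so the trace transits
    # the detection-level zone decisively instead of hovering within noise
    # of it (slow extracellular waves typically undershoot their baseline)
    if p.morphology == "biphasic":
        return (_hann_lobe(t, te, 0.25, -0.40)
                + _tukey_lobe(t, te + 0.27, knob, 0.60)
                + _hann_lobe(t, te + 0.22 + knob, 0.70, -0.12))
    return (_hann_lobe(t, te, 0.20, 0.61)
            + _hann_lobe(t, te + 0.20, 0.60, -0.39)
            + _hann_lobe(t, te + knob - 0.30, 0.35, -0.10)
            + _tukey_lobe(t, te + knob, 0.50, 0.35)
            + _hann_lobe(t, te + knob + 0.45, 0.70, -0.10))


def _raw_from_target(z: np.ndarray, sample_rate: float) -> np.ndarray:
    """Raw trace whose band-passed version equals ``z`` (zero-mean) exactly.

    Divides by the zero-phase band gain wherever it is numerically
    invertible; the DC bin is unrecoverable through a high-pass, so ``z``
    is mean-subtracted first and the reconstruction is then bin-exact.
    """
    from .lfp import _band_gain
    z = z - z.mean()
    gain = _band_gain(len(z), sample_rate)
    inv = np.where(gain > 1e-4, 1.0 / np.maximum(gain, 1e-12), 0.0)
    return np.fft.irfft(np.fft.rfft(z) * inv, n=len(z))


_N_CALIB_SEEDS = 10


@lru_cache(maxsize=32)
def _calibrate(p: LFPShapeParams):
    """(knob, scale): layout and amplitude hitting span and p2p targets.

    Iterates between (a) root-finding the layout knob so the conditioned
    waveform crosses the *realised* detection level over exactly ``span_s``
    and (b) rescaling so the expected noisy peak-to-peak inside the event
    window equals ``p2p_uV``; the level and the peak-to-peak noise
    inflation are estimated over a fixed set of internal calibration seeds,
    so the result is deterministic.
    """
    from .lfp import bandpass, _crossing_times, _threshold_level

    n = int(round(p.epoch_s * p.sample_rate))
    t = np.arange(n) / p.sample_rate
    lo_w, hi_w = p.event_window_s
    wsel = (t >= lo_w) & (t <= hi_w)
    lo, hi = (0.7, 2.4) if p.morphology == "biphasic" else (0.75, 2.4)

    def filt(y):
        return bandpass(LFPTrace(y, p.sample_rate)).samples_uV

    def conditioned(knob, scale):
        z = _target_waveform(p, knob) * scale
        return z - z.mean()

    def find_knob(level, inflation):
        scale = p.p2p_uV - inflation          # unit-p2p target waveform
        def span_err(k):
            z = conditioned(k, scale)
            times = _crossing_times(z, level, p.sample_rate)
            times = times[(times >= lo_w) & (times <= hi_w)]
            return (times[-1] - times[0] if len(times) >= 2 else 0.0) - p.span_s
        return float(brentq(span_err, lo, hi, xtol=1e-4))

    def estimate(knob, scale):
        clean = conditioned(knob, scale)
        infl, lvl = [], []
        for s in range(100, 100 + _N_CALIB_SEEDS):
            y = clean + filt(np.random.default_rng(s).normal(
                0.0, p.noise_sd_uV, n))
            infl.append((y[wsel].max() - y[wsel].min())
                        - (clean[wsel].max() - clean[wsel].min()))
            lvl.append(_threshold_level(LFPTrace(y, p.sample_rate),
                                        exclude_window_s=p.event_window_s))
        return float(np.mean(infl)), float(np.mean(lvl))

    level = 2.0 * filt(np.random.default_rng(0).normal(
        0.0, p.noise_sd_uV, n)).std()
    inflation = 0.0
    for _ in range(8):
        knob = find_knob(level, inflation)
        new_infl, new_level = estimate(knob, p.p2p_uV - inflation)
        if abs(new_level - level) < 0.005 * max(level, 1e-9) and \
                abs(new_infl - inflation) < 0.02:
            inflation, level = new_infl, new_level
            break
        inflation, level = new_infl, new_level
    knob = find_knob(level, inflation)
    return knob, p.p2p_uV - inflation


def simulate_lfp(morphology: str = "biphasic",
                 params: LFPShapeParams = None, seed: int = 1,
                 channel_label: str = "pia") -> LFPTrace:
    """One synthetic (raw, unfiltered) pial LFP trace at 2 kHz.

    After the standard 0.5-100 Hz conditioning the biphasic default shows
    an initial negative-going deflection, exactly 2 crossings of the +2 SD
    level spanning 1.17 s, and 42 uV peak-to-peak; the triphasic default an
    initial positive deflection, 4 crossings spanning 1.62 s, and 46 uV.
    The raw trace is the exact inverse-filtered target waveform plus white
    baseline noise.  Zero-amplitude parameters give a flat (noise-only)
    trace.
    """
    p = params or LFPShapeParams(morphology=morphology)
    if p.morphology != morphology:
        raise ValueError("params.morphology does not match requested "
                         "morphology")
    n = int(round(p.epoch_s * p.sample_rate))
    if p.p2p_uV == 0:
        y = np.zeros(n)
    else:
        knob, scale = _calibrate(p)
        y = _raw_from_target(_target_waveform(p, knob) * scale,
                             p.sample_rate)
    if p.noise_sd_uV > 0:
        y = y + np.random.default_rng(seed).normal(0.0, p.noise_sd_uV, n)
    return LFPTrace(y, p.sample_rate, channel_label)


@dataclass(frozen=True)
class LaminarPairParams:
    """Paired laminar (L2/3 vs L5/6) channel generator parameters.

    Laminar micropipette recordings show much sharper discharge onsets and
    larger amplitudes than the pial surface channel, so the pair generator
    uses a spike-led waveform; the low noise default reflects the averaged
    traces on which interlaminar delays are read out.
    """

    p2p_uV: float = 150.0
    sample_rate: float = 2000.0
    epoch_s: float = 10.0
    event_time_s: float = 3.0
    noise_sd_uV: float = 0.25
    spike_width_s: float = 0.15


def simulate_lfp_pair(preset: str = "type2", params: LaminarPairParams = None,
                      seed: int = 3, delay_ms: float = None):
    """Paired laminar LFP channels with the preset interlaminar offset.

    ``'type2'``: Au1-origin events -- L2/3 leads L5/6 by 8 ms.
    ``'type3'``: hippocampus-origin events -- L5/6 leads L2/3 by 17 ms.
    Returns ``(leading, lagging)`` raw traces; each channel gets an
    independent noise realisation derived from ``seed``.
    """
    if preset == "type2":
        labels = ("L2/3", "L5/6")
        default_delay = DELAY_PRESETS_MS["l23_to_l5"]
    elif preset == "type3":
        labels = ("L5/6", "L2/3")
        default_delay = DELAY_PRESETS_MS["l56_to_l23"]
    else:
        raise ValueError("preset must be 'type2' or 'type3'")
    delay_ms = default_delay if delay_ms is None else delay_ms
    p = params or LaminarPairParams()
    n = int(round(p.epoch_s * p.sample_rate))
    t = np.arange(n) / p.sample_rate
    te = p.event_time_s
    w = p.spike_width_s
    proto = (_hann_lobe(t, te, w, 0.62 * p.p2p_uV)
             + _hann_lobe(t, te + w, 3 * w, -0.38 * p.p2p_uV))
    shift = int(round(delay_ms / 1000.0 * p.sample_rate))
    lag = np.zeros_like(proto)
    if 0 <= shift < n:
        lag[shift:] = proto[: n - shift]
    else:
        raise ValueError("delay exceeds the epoch")
    rngs = [np.random.default_rng(c)
            for c in np.random.SeedSequence(seed).spawn(2)]
    if p.noise_sd_uV > 0:
        lead_y = proto + rngs[0].normal(0.0, p.noise_sd_uV, n)
        lag_y = lag + rngs[1].normal(0.0, p.noise_sd_uV, n)
    else:
        lead_y, lag_y = proto, lag
    return (LFPTrace(lead_y, p.sample_rate, labels[0]),
            LFPTrace(lag_y, p.sample_rate, labels[1]))
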