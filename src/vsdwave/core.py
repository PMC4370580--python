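"""Core in-memory containers shared by every stage of the pipeline.

The containers are deliberately thin: plain dataclasses around numpy arrays
plus the sampling metadata (frame rate, pixel pitch) that every kinematic
quantity depends on.  Conventions, fixed once for the whole package:

* pixel coordinates are 0-based ``(row, col)`` with row 0 at the top;
* physical position of pixel ``(r, c)`` is ``x = c * pixel_pitch_mm``,
  ``y = r * pixel_pitch_mm`` (millimetres);
* frame ``k`` of a movie is at time ``k / frame_rate`` seconds;
* onset maps use NaN for pixels that never became suprathreshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "VSDMovie",
    "AxisPath",
    "RegionAtlas",
    "OnsetMap",
    "AxisProfile",
    "Saltation",
    "VelocityFit",
    "LFPTrace",
    "EventRecord",
    "HIPPOCAMPAL_REGIONS",
    "AU1_REGIONS",
]

#: atlas labels counted as hippocampus proper (subiculum is periallocortex)
HIPPOCAMPAL_REGIONS = frozenset({"CA3", "CA1"})
#: atlas labels forming primary auditory neocortex
AU1_REGIONS = frozenset({"Au1_L23", "Au1_L56"})


@dataclass
class VSDMovie:
    """A time-ordered stack of fluorescence frames.

    ``frames`` has shape (T, H, W).  On disk movies are 16-bit grayscale
    TIFF stacks; in memory they are real-valued so that preprocessing can
    operate without quantisation.
    """

    frames: np.ndarray
    frame_rate: float = 200.0
    pixel_pitch_mm: float = 0.025
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(
                f"movie frames must be a (T, H, W) stack with T >= 1, "
                f"got shape {self.frames.shape}"
            )
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Timestamp of every frame in seconds (frame k at k / frame_rate)."""
        return np.arange(self.n_frames) / self.frame_rate

    def with_frames(self, frames: np.ndarray, **updates) -> "VSDMovie":
        """Copy of this movie with new frame data (metadata preserved)."""
        new = replace(self, frames=frames)
        for k, v in updates.items():
            setattr(new, k, v)
        return new


@dataclass
class AxisPath:
    """An ordered anatomical polyline with cumulative arc length in mm.

    ``xy_mm`` is an (N, 2) array of (x, y) waypoints in millimetres.
    """

    name: str
    xy_mm: np.ndarray

    def __post_init__(self) -> None:
        self.xy_mm = np.asarray(self.xy_mm, dtype=float)
        if self.xy_mm.ndim != 2 or self.xy_mm.shape[1] != 2 or len(self.xy_mm) < 2:
            raise ValueError("axis path needs an (N>=2, 2) waypoint array")
        seg = np.linalg.norm(np.diff(self.xy_mm, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("axis path has coincident consecutive waypoints")
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def cum_mm(self) -> np.ndarray:
        """Cumulative distance at each waypoint (strictly increasing)."""
        return self._cum

    @property
    def length_mm(self) -> float:
        return float(self._cum[-1])

    def sample(self, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
        """Evenly spaced points along the polyline.

        Returns ``(distances, points)`` with distances shape (M,) and points
        shape (M, 2); the final waypoint is always included.
        """
        d = np.arange(0.0, self.length_mm, step_mm)
        if d[-1] < self.length_mm:
            d = np.append(d, self.length_mm)
        x = np.interp(d, self._cum, self.xy_mm[:, 0])
        y = np.interp(d, self._cum, self.xy_mm[:, 1])
        return d, np.column_stack([x, y])

    def project(self, points_xy_mm: np.ndarray, step_mm: float = 0.0125):
        """Arc-length coordinate of the nearest polyline point for each query.

        Returns ``(distance_mm, offset_mm)``: the along-axis coordinate and
        the perpendicular distance to the path.  Straight-line (chord)
        geometry throughout -- no curvature compensation.
        """
        pts = np.asarray(points_xy_mm, dtype=float)
        d, samp = self.sample(step_mm)
        # (Q, M) pairwise distances; fine for the ~1e4 x ~1e3 sizes used here
        diff = pts[:, None, :] - samp[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        idx = dist.argmin(axis=1)
        return d[idx], dist[np.arange(len(pts)), idx]


@dataclass
class RegionAtlas:
    """Labeled pixel map of anatomical regions plus named axis paths.

    ``label_image`` holds one integer label per pixel (0 = background);
    ``label_names`` maps label -> region name.
    """

    label_image: np.ndarray
    label_names: Dict[int, str]
    axis_paths: Dict[str, AxisPath]
    pixel_pitch_mm: float = 0.025

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValueError("label_image must be 2-D")
        present = set(np.unique(self.label_image)) - {0}
        unknown = present - set(self.label_names)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} present in image but missing "
                             f"from label_names")

    @property
    def shape(self) -> tuple:
        return self.label_image.shape

    @property
    def name_to_label(self) -> Dict[str, int]:
        return {v: k for k, v in self.label_names.items()}

    def mask(self, region: str) -> np.ndarray:
        """Boolean mask of one region by name."""
        try:
            lab = self.name_to_label[region]
        except KeyError:
            raise KeyError(f"region {region!r} not in atlas "
                           f"(have {sorted(self.name_to_label)})") from None
        return self.label_image == lab

    def mask_any(self, regions) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for r in regions:
            m |= self.mask(r)
        return m

    def pixel_xy_mm(self) -> np.ndarray:
        """(H*W, 2) physical (x, y) coordinates of every pixel centre."""
        h, w = self.shape
        rr, cc = np.mgrid[0:h, 0:w]
        return np.column_stack([cc.ravel() * self.pixel_pitch_mm,
                                rr.ravel() * self.pixel_pitch_mm])

    def axis_distance_map(self, axis_name: str):
        """Along-axis distance (mm) and perpendicular offset for every pixel."""
        path = self.axis_paths[axis_name]
        d, off = path.project(self.pixel_xy_mm())
        return d.reshape(self.shape), off.reshape(self.shape)

    def rebin(self, factor: int) -> "RegionAtlas":
        """Atlas on the grid produced by ``factor`` x ``factor`` binning.

        Each block takes its majority label (ties resolved toward a
        non-background label, then the smaller id, so the result is
        deterministic).  Physical axis paths are unchanged: they live in mm.
        """
        if factor == 1:
            return self
        h, w = self.shape
        hh, ww = h // factor, w // factor
        blocks = self.label_image[: hh * factor, : ww * factor]
        blocks = blocks.reshape(hh, factor, ww, factor).transpose(0, 2, 1, 3)
        blocks = blocks.reshape(hh, ww, factor * factor)
        out = np.zeros((hh, ww), dtype=self.label_image.dtype)
        labels = np.unique(blocks)
        counts = np.stack([(blocks == lab).sum(axis=2) for lab in labels], axis=2)
        # background loses ties: halve its count weight by subtracting 0.5
        weight = counts.astype(float)
        weight[:, :, labels == 0] -= 0.5
        out = labels[np.argmax(weight, axis=2)]
        return RegionAtlas(
            label_image=out,
            label_names=dict(self.label_names),
            axis_paths=dict(self.axis_paths),
            pixel_pitch_mm=self.pixel_pitch_mm * factor,
        )


@dataclass
class OnsetMap:
    """Per-pixel first-suprathreshold-crossing time in seconds.

    NaN marks pixels that never crossed.  ``threshold_map`` is the per-pixel
    level (baseline mean + 2 SD) the crossings were measured against.
    """

    onset_s: np.ndarray
    pixel_pitch_mm: float
    frame_rate: float = 200.0
    threshold_map: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        if self.onset_s.ndim != 2:
            raise ValueError("onset map must be 2-D")

    @property
    def shape(self) -> tuple:
        return self.onset_s.shape

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.onset_s)

    def earliest_in(self, mask: np.ndarray) -> float:
        vals = self.onset_s[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return float("nan")
        return float(vals.min())


@dataclass
class AxisProfile:
    """Earliest onset as a function of arc length along a named axis."""

    axis_name: str
    distance_mm: np.ndarray
    onset_s: np.ndarray
    corridor_width_mm: float

    def __post_init__(self) -> None:
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        if self.distance_mm.shape != self.onset_s.shape:
            raise ValueError("distance and onset arrays must match")
        if np.any(np.diff(self.distance_mm) <= 0):
            raise ValueError("profile distances must be strictly increasing")

    def finite(self) -> tuple[np.ndarray, np.ndarray]:
        m = np.isfinite(self.onset_s)
        return self.distance_mm[m], self.onset_s[m]


@dataclass
class Saltation:
    """One discontinuous ('jump') propagation step along an axis profile."""

    jump_from_mm: float
    jump_to_mm: float
    time_s: float
    backfill_velocity_m_s: float

    def __post_init__(self) -> None:
        if not self.jump_to_mm > self.jump_from_mm:
            raise ValueError("jump_to_mm must exceed jump_from_mm")


@dataclass
class VelocityFit:
    """Propagation-velocity estimate with its fit diagnostics."""

    velocity_m_s: float          # sign encodes direction along the axis
    slope_s_per_mm: float
    intercept_s: float
    n_samples: int
    method: str
    infinite: bool = False       # zero-slope (simultaneous onset) flag


@dataclass
class LFPTrace:
    """One field-potential channel in microvolts."""

    samples_uV: np.ndarray
    sample_rate: float = 2000.0
    channel_label: str = "pia"

    def __post_init__(self) -> None:
        self.samples_uV = np.asarray(self.samples_uV, dtype=float)
        if self.samples_uV.ndim != 1:
            raise ValueError("LFP trace must be 1-D")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        if not np.all(np.isfinite(self.samples_uV)):
            raise ValueError("LFP trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples_uV)) / self.sample_rate


@dataclass
class EventRecord:
    """One classified interictal event and everything measured about it."""

    event_id: str
    event_type: str = "unclassified"     # '1' | '2' | '3a' | '3b' | 'unclassified'
    origin_region: str = ""
    origin_xy: tuple = (0, 0)
    origin_time_s: float = float("nan")
    recruited_regions: frozenset = frozenset()
    laminar_origin: str = "n/a"          # 'superficial' | 'deep' | 'n/a'
    horizontal_spread_mm: Dict[str, float] = field(default_factory=dict)
    conduction_times_ms: Dict[str, float] = field(default_factory=dict)
    reverb_latency_s: Optional[float] = None
    saltations: List[Saltation] = field(default_factory=list)
    backfill_velocity_m_s: Dict[str, float] = field(default_factory=dict)
    peak_dff_pct: Dict[str, float] = field(default_factory=dict)
    status: str = "ok"
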