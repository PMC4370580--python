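"""Readers and writers for every on-disk artifact.

Formats are deliberately plain: multi-page 16-bit grayscale TIFF for movies,
single-page 16-bit TIFF for atlas label images, 32-bit float TIFF (NaN =
never active) for onset maps, CSV for tables and LFP traces, and a JSON
sidecar carrying sampling metadata next to each TIFF.

Sidecar convention: for ``movie.tif`` the sidecar is ``movie.json`` (same
stem, ``.json`` suffix).  All read/write pairs are lossless round trips on
valid inputs: integer data bit-exact, floats to >= 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import AxisPath, LFPTrace, OnsetMap, RegionAtlas, VSDMovie

__all__ = [
    "read_movie", "write_movie",
    "read_atlas", "write_atlas",
    "read_onset_map", "write_onset_map",
    "export_pointcloud",
    "read_lfp", "write_lfp",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _check_grayscale(path: Path) -> None:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(
                f"{path} is not a grayscale TIFF "
                f"(samples per pixel = {page.samplesperpixel})"
            )


def write_movie(movie: VSDMovie, path) -> Path:
    """Write a movie as a multi-page 16-bit grayscale TIFF plus JSON sidecar.

    Real-valued frames are rounded and clipped to the uint16 range; integer
    frames round-trip bit-exactly.
    """
    path = Path(path)
    frames = np.clip(np.rint(movie.frames), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, frames.astype(np.uint16), photometric="minisblack")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "kind": "vsd_movie",
        "frame_rate_hz": movie.frame_rate,
        "pixel_pitch_mm": movie.pixel_pitch_mm,
        "n_frames": int(movie.n_frames),
        "meta": _jsonable(movie.meta),
    }, indent=1))
    return path


def read_movie(path) -> VSDMovie:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"movie sidecar not found: expected {sidecar} next to {path}")
    _check_grayscale(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"{path} does not contain a (T, H, W) grayscale stack")
    info = json.loads(sidecar.read_text())
    return VSDMovie(
        frames=frames,
        frame_rate=float(info["frame_rate_hz"]),
        pixel_pitch_mm=float(info["pixel_pitch_mm"]),
        meta=info.get("meta", {}),
    )


def write_atlas(atlas: RegionAtlas, path) -> Path:
    """Write the label image as 16-bit TIFF with a JSON sidecar for names/axes."""
    path = Path(path)
    tifffile.imwrite(path, atlas.label_image.astype(np.uint16),
                     photometric="minisblack")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "kind": "region_atlas",
        "pixel_pitch_mm": atlas.pixel_pitch_mm,
        "label_names": {str(k): v for k, v in atlas.label_names.items()},
        "axis_paths": {name: p.xy_mm.tolist()
                       for name, p in atlas.axis_paths.items()},
    }, indent=1))
    return path


def read_atlas(path) -> RegionAtlas:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"atlas sidecar not found: expected {sidecar} next to {path}")
    _check_grayscale(path)
    label_image = tifffile.imread(path)
    info = json.loads(sidecar.read_text())
    # RegionAtlas validates that all labels present in the image are named
    return RegionAtlas(
        label_image=label_image.astype(np.int64),
        label_names={int(k): v for k, v in info["label_names"].items()},
        axis_paths={name: AxisPath(name, np.asarray(pts))
                    for name, pts in info["axis_paths"].items()},
        pixel_pitch_mm=float(info["pixel_pitch_mm"]),
    )


def write_onset_map(onset_map: OnsetMap, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, onset_map.onset_s.astype(np.float32),
                     photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps({
        "kind": "onset_map",
        "pixel_pitch_mm": onset_map.pixel_pitch_mm,
        "frame_rate_hz": onset_map.frame_rate,
        "meta": _jsonable(onset_map.meta),
    }, indent=1))
    return path


def read_onset_map(path) -> OnsetMap:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"onset-map sidecar not found: expected {sidecar} next to {path}")
    info = json.loads(sidecar.read_text())
    return OnsetMap(
        onset_s=tifffile.imread(path).astype(float),
        pixel_pitch_mm=float(info["pixel_pitch_mm"]),
        frame_rate=float(info["frame_rate_hz"]),
        meta=info.get("meta", {}),
    )


def export_pointcloud(onset_map: OnsetMap, path) -> Path:
    """Write the wavefront as (x_mm, y_mm, t_s) rows, one per active pixel.

    Coordinates are pixel index times pixel pitch; an all-NaN map yields an
    empty file with a header only.
    """
    path = Path(path)
    rr, cc = np.nonzero(onset_map.finite_mask)
    df = pd.DataFrame({
        "x_mm": cc * onset_map.pixel_pitch_mm,
        "y_mm": rr * onset_map.pixel_pitch_mm,
        "t_s": onset_map.onset_s[rr, cc],
    })
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def write_lfp(trace: LFPTrace, path) -> Path:
    """Two-column CSV (time_s, value_uV)."""
    path = Path(path)
    pd.DataFrame({
        "time_s": trace.times,
        "value_uV": trace.samples_uV,
    }).to_csv(path, index=False, float_format="%.9g")
    return path


def read_lfp(path, channel_label: str = "pia") -> LFPTrace:
    df = pd.read_csv(path)
    if not {"time_s", "value_uV"} <= set(df.columns):
        raise ValueError(f"{path} is not a (time_s, value_uV) LFP CSV")
    dt = np.diff(df["time_s"].to_numpy())
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValueError(f"{path} has a non-increasing time column")
    return LFPTrace(
        samples_uV=df["value_uV"].to_numpy(dtype=float),
        sample_rate=1.0 / float(np.median(dt)),
        channel_label=channel_label,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
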