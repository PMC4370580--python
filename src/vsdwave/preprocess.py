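"""Per-pixel conditioning chain for VSD movies.

Order of operations, fixed for the whole pipeline:

    background_subtract -> detrend -> spatial_bin -> savgol_differentiate

which yields the "filtered" (rate-of-change) signal used for wavefront
detection; ``to_dff`` converts the un-differentiated branch to percent
fluorescence change for amplitude measurements.

The baseline window (default: the first 0.5 s of the epoch) defines the
"background"/non-epileptiform reference for subtraction, detrending and,
downstream, the 2 SD detection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core import VSDMovie

__all__ = [
    "PreprocessConfig",
    "baseline_frames",
    "background_subtract",
    "detrend",
    "spatial_bin",
    "savgol_differentiate",
    "to_dff",
    "run_chain",
]


@dataclass
class PreprocessConfig:
    """Tunable parameters of the conditioning chain.

    ``baseline_window_s`` is a (start, stop) interval in seconds that must
    precede event activity.  The Savitzky-Golay window is in frames, must be
    odd and larger than the polynomial order.
    """

    baseline_window_s: tuple = (0.0, 0.5)
    savgol_window: int = 11
    savgol_order: int = 3
    bin_factor: int = 2
    threshold_signal: str = "derivative"   # 'derivative' | 'dff'

    def __post_init__(self) -> None:
        if self.savgol_window % 2 != 1 or self.savgol_window <= self.savgol_order:
            raise ValueError("savgol_window must be odd and > savgol_order")
        lo, hi = self.baseline_window_s
        if not hi > lo:
            raise ValueError("baseline window must be a non-empty interval")
        if self.bin_factor < 1:
            raise ValueError("bin_factor must be >= 1")
        if self.threshold_signal not in ("derivative", "dff"):
            raise ValueError("threshold_signal must be 'derivative' or 'dff'")


def baseline_frames(movie: VSDMovie, baseline_window_s) -> slice:
    """Frame slice covered by a (start, stop) baseline interval in seconds."""
    lo, hi = baseline_window_s
    i0 = int(np.ceil(lo * movie.frame_rate))
    i1 = int(np.floor(hi * movie.frame_rate))
    i1 = min(i1, movie.n_frames)
    if i1 - i0 < 1:
        raise ValueError(
            f"baseline window {baseline_window_s} s contains no frames at "
            f"{movie.frame_rate} Hz")
    return slice(i0, i1)


def background_subtract(movie: VSDMovie, baseline_window_s=(0.0, 0.5)) -> VSDMovie:
    """Subtract each pixel's baseline-window mean."""
    sl = baseline_frames(movie, baseline_window_s)
    f0 = movie.frames[sl].mean(axis=0)
    return movie.with_frames(movie.frames - f0[None])


def detrend(movie: VSDMovie, baseline_window_s=(0.0, 0.5)) -> VSDMovie:
    """Remove each pixel's linear trend.

    The trend (slope + intercept) is fitted by least squares over the
    baseline window only and extrapolated across the whole movie, so a slow
    bleaching drift is removed without flattening the event itself.
    """
    sl = baseline_frames(movie, baseline_window_s)
    if sl.stop - sl.start < 2:
        raise ValueError("detrend needs at least 2 baseline frames")
    t = movie.times
    tb = t[sl]
    flat = movie.frames.reshape(movie.n_frames, -1)
    # least-squares line per pixel, closed form on the baseline window
    coef = np.polynomial.polynomial.polyfit(tb, flat[sl], deg=1)
    trend = coef[0][None, :] + t[:, None] * coef[1][None, :]
    out = (flat - trend).reshape(movie.shape)
    return movie.with_frames(out)


def spatial_bin(movie: VSDMovie, bin_factor: int = 2) -> VSDMovie:
    """Non-overlapping block means ('post-filtering' at bin_factor^2 pixels).

    Output height/width are floor(H/f), floor(W/f); trailing rows/cols that
    do not fill a block are dropped.  The pixel pitch scales by the factor.
    """
    f = int(bin_factor)
    if f < 1:
        raise ValueError("bin_factor must be >= 1")
    if f == 1:
        return movie
    T, H, W = movie.shape
    hh, ww = H // f, W // f
    x = movie.frames[:, : hh * f, : ww * f]
    x = x.reshape(T, hh, f, ww, f).mean(axis=(2, 4))
    return movie.with_frames(x, pixel_pitch_mm=movie.pixel_pitch_mm * f)


def savgol_differentiate(data, window: int = 11, order: int = 3,
                         sample_rate: float = None):
    """Savitzky-Golay first-derivative estimate, in units per second.

    Accepts a :class:`VSDMovie` (differentiates along time) or a plain 1-D
    trace (``sample_rate`` then required).  Each sample gets the derivative
    of the local least-squares polynomial; edges use the polynomial fitted
    on the truncated window.
    """
    if isinstance(data, VSDMovie):
        out = savgol_filter(data.frames, window, order, deriv=1,
                            delta=1.0 / data.frame_rate, axis=0, mode="interp")
        return data.with_frames(out)
    if sample_rate is None:
        raise ValueError("sample_rate required for array input")
    arr = np.asarray(data, dtype=float)
    return savgol_filter(arr, window, order, deriv=1,
                         delta=1.0 / sample_rate, axis=0, mode="interp")


def to_dff(movie: VSDMovie, baseline_window_s=(0.0, 0.5)) -> VSDMovie:
    """Percent fluorescence change: 100 * (F - F0) / F0.

    F0 is the per-pixel baseline-window mean; any pixel with F0 <= 0 makes
    the baseline invalid.
    """
    sl = baseline_frames(movie, baseline_window_s)
    f0 = movie.frames[sl].mean(axis=0)
    if np.any(f0 <= 0):
        n = int((f0 <= 0).sum())
        raise ValueError(
            f"invalid baseline: {n} pixel(s) have baseline mean <= 0")
    return movie.with_frames(100.0 * (movie.frames - f0[None]) / f0[None])


def run_chain(movie: VSDMovie, config: PreprocessConfig = None):
    """Full conditioning chain.

    Returns ``(filtered, dff)``: the Savitzky-Golay differentiated movie on
    the binned grid and the percent-dF/F movie on the same grid (the
    un-differentiated branch).  Both are deterministic and shape-stable.
    """
    cfg = config or PreprocessConfig()
    bw = cfg.baseline_window_s
    bs = background_subtract(movie, bw)
    dt = detrend(bs, bw)
    binned = spatial_bin(dt, cfg.bin_factor)
    filtered = savgol_differentiate(binned, cfg.savgol_window, cfg.savgol_order)
    # dF/F needs the raw F0: bin the raw movie, then normalise the detrended
    # branch by the binned baseline mean
    raw_binned = spatial_bin(movie, cfg.bin_factor)
    sl = baseline_frames(raw_binned, bw)
    f0 = raw_binned.frames[sl].mean(axis=0)
    if np.any(f0 <= 0):
        raise ValueError("invalid baseline: binned baseline mean <= 0")
    dff = binned.with_frames(100.0 * binned.frames / f0[None])
    return filtered, dff
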