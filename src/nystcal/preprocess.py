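"""Signal cleaning, smoothing and differentiation.

Three steps prepare an uncalibrated recording for segmentation:

1. short tracking gaps (<= 25 ms) are filled with cubic splines fitted on
   flanking valid samples;
2. blink artifacts are removed by invalidating 75 ms on either side of any
   remaining gap;
3. position is smoothed and eye speed estimated with a Savitzky-Golay
   (local-polynomial) filter applied independently to each maximal valid
   segment, so blink edges never leak into the velocity estimate.

Speed stays in arbitrary units/s — nothing here requires a calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from .config import PipelineConfig
from .io import GazeRecording

# valid samples consulted on each side of a gap when fitting the spline
_SPLINE_FLANK = 10


def _invalid_runs(valid: np.ndarray):
    """Maximal runs of invalid samples as (start, stop) half-open pairs."""
    inv = ~valid
    if not inv.any():
        return []
    d = np.diff(inv.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if inv[0]:
        starts.insert(0, 0)
    if inv[-1]:
        stops.append(len(valid))
    return list(zip(starts, stops))


def _valid_runs(valid: np.ndarray):
    return _invalid_runs(~valid)


def interpolate_gaps(rec: GazeRecording, max_gap_ms: float = 25.0) -> GazeRecording:
    """Fill tracking gaps of at most ``max_gap_ms`` with cubic splines.

    Splines are fitted per axis on up to ten valid samples flanking each
    side of the gap (not-a-knot boundary, so polynomials up to cubic are
    reproduced exactly).  Longer gaps, and gaps touching the start or end of
    the recording, are left invalid.  Valid samples are never altered.
    """
    if max_gap_ms <= 0:
        raise ValueError("max_gap_ms must be > 0")
    out = rec.copy()
    t = out.t_ms
    for start, stop in _invalid_runs(rec.valid):
        if start == 0 or stop == rec.n:
            continue  # no flank on one side: cannot interpolate
        gap_ms = t[stop] - t[start - 1] - rec.dt_ms
        if gap_ms > max_gap_ms + 1e-9:
            continue
        lo = start
        left_idx = []
        while lo > 0 and rec.valid[lo - 1] and len(left_idx) < _SPLINE_FLANK:
            lo -= 1
            left_idx.append(lo)
        hi = stop
        right_idx = []
        while hi < rec.n and rec.valid[hi] and len(right_idx) < _SPLINE_FLANK:
            right_idx.append(hi)
            hi += 1
        knots = np.array(sorted(left_idx) + right_idx)
        if len(knots) < 4:
            continue  # not enough support for a cubic
        for arr in (out.x, out.y):
            cs = CubicSpline(t[knots], arr[knots])
            arr[start:stop] = cs(t[start:stop])
        out.valid[start:stop] = True
    return out


def trim_blinks(rec: GazeRecording, pad_ms: float = 75.0) -> GazeRecording:
    """Invalidate ``pad_ms`` on either side of every remaining gap.

    Removes the position spikes that trackers produce around blinks.  Pads
    from neighbouring gaps merge; pads are clipped at the recording
    boundaries.  Idempotent: samples invalidated here are tagged as pads on
    the recording, so re-application dilates only the genuine gaps.
    """
    if pad_ms <= 0:
        raise ValueError("pad_ms must be > 0")
    out = rec.copy()
    pad = int(round(pad_ms * rec.rate / 1000.0))
    prior_pad = (
        rec.artifact_pad
        if rec.artifact_pad is not None
        else np.zeros(rec.n, dtype=bool)
    )
    core = ~rec.valid & ~prior_pad  # tracker gaps, not earlier padding
    mask = rec.valid | prior_pad
    for start, stop in _invalid_runs(~core):
        mask[max(0, start - pad):min(rec.n, stop + pad)] = False
    out.valid = mask
    out.artifact_pad = ~mask & ~core
    return out


@dataclass
class FilteredSignal:
    """Smoothed position and per-axis speed in arbitrary units.

    ``speed`` is the per-sample detection speed: by default the absolute
    speed of the primary (highest-variance) axis, optionally the 2-D
    magnitude of MAD-rescaled per-axis speeds.  Speed is NaN wherever the
    sample is invalid or the filter could not be applied.
    """

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    valid: np.ndarray
    rate: float
    primary: str  # "x" | "y"
    units: str = "raw"

    @property
    def n(self) -> int:
        return len(self.t_ms)

    def position(self, axis: Optional[str] = None) -> np.ndarray:
        axis = axis or self.primary
        return self.x if axis == "x" else self.y

    def copy(self) -> "FilteredSignal":
        return FilteredSignal(
            self.t_ms.copy(), self.x.copy(), self.y.copy(),
            self.vx.copy(), self.vy.copy(), self.speed.copy(),
            self.valid.copy(), self.rate, self.primary, self.units,
        )


def _axis_sd(values: np.ndarray, valid: np.ndarray) -> float:
    v = values[valid]
    return float(np.std(v)) if len(v) >= 2 else 0.0


def primary_axis_of(x, y, valid) -> str:
    """Axis with the larger valid-sample position standard deviation.

    Ties go to horizontal.  Raises on an all-invalid signal.
    """
    if np.count_nonzero(valid) < 2:
        raise ValueError("need >= 2 valid samples to choose the primary axis")
    return "y" if _axis_sd(np.asarray(y), valid) > _axis_sd(np.asarray(x), valid) else "x"


def _mad(a: np.ndarray) -> float:
    m = np.nanmedian(a)
    return float(np.nanmedian(np.abs(a - m)))


def filter_and_differentiate(
    rec: GazeRecording, config: Optional[PipelineConfig] = None
) -> FilteredSignal:
    """Smooth position and estimate per-sample eye speed.

    A Savitzky-Golay filter (default order 3, 21 samples at 1000 Hz, window
    scaled with rate) smooths each axis and its first derivative on every
    maximal valid segment separately.  Segments shorter than the window are
    passed through unsmoothed with speed masked.
    """
    config = config or PipelineConfig()
    window = config.sg_window(rec.rate)
    order = config.sg_polyorder
    n = rec.n
    x_s = rec.x.astype(float).copy()
    y_s = rec.y.astype(float).copy()
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    for start, stop in _valid_runs(rec.valid):
        seg = slice(start, stop)
        if stop - start < window:
            continue  # too short to filter: positions untouched, speed masked
        for pos, vel in ((x_s, vx), (y_s, vy)):
            raw = pos[seg].copy()
            pos[seg] = savgol_filter(raw, window, order, deriv=0)
            vel[seg] = savgol_filter(
                raw, window, order, deriv=1, delta=1.0 / rec.rate
            )
    invalid = ~rec.valid
    vx[invalid] = np.nan
    vy[invalid] = np.nan
    primary = primary_axis_of(x_s, y_s, rec.valid)
    if config.speed_mode == "primary":
        speed = np.abs(vx if primary == "x" else vy)
    else:
        sx = _mad(vx) or 1.0
        sy = _mad(vy) or 1.0
        speed = np.hypot(vx / sx, vy / sy)
    speed[invalid] = np.nan
    return FilteredSignal(
        t_ms=rec.t_ms.copy(), x=x_s, y=y_s, vx=vx, vy=vy, speed=speed,
        valid=rec.valid.copy(), rate=rec.rate, primary=primary, units=rec.units,
    )


def preprocess(rec: GazeRecording, config: Optional[PipelineConfig] = None) -> FilteredSignal:
    """Full cleaning chain: interpolate short gaps, trim blinks, filter."""
    config = config or PipelineConfig()
    rec = interpolate_gaps(rec, config.max_gap_ms)
    rec = trim_blinks(rec, config.blink_pad_ms)
    return filter_and_differentiate(rec, config)
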