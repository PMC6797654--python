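"""Adaptive foveation detection and per-target point of regard.

For each complete nystagmus cycle the algorithm searches, one sample at a
time, every window lasting 10% of the cycle's total slow-phase duration and
keeps the one with the lowest mean eye speed (in arbitrary units).  No
velocity or position threshold is imposed — the criterion is entirely
relative, so it adapts per cycle and works on uncalibrated data.  Windows
may extend up to one window-length past the closing boundary peak of a
cycle, to catch foveations that straddle cycle boundaries (common in
pendular waveforms); windows shorter than 7 ms are disregarded.

The point of regard for a calibration target is the per-coordinate median
position over all samples of all foveations detected while that target was
displayed — robust to outliers and biased toward the slowest samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .preprocess import FilteredSignal
from .segmentation import Cycle, CycleSet, PhaseLabels


class FoveationError(ValueError):
    """Raised when a point of regard cannot be computed for a target."""


@dataclass
class FoveationInterval:
    """The lowest-mean-speed window of one cycle (half-open sample range)."""

    cycle_id: int
    start: int
    end: int
    duration_ms: float
    mean_x: float
    mean_y: float
    mean_speed: float

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.end)


@dataclass
class PointOfRegard:
    """Median foveation position for one calibration target."""

    target_id: int
    x_raw: float
    y_raw: float
    n_foveations: int
    target_x_deg: float = np.nan
    target_y_deg: float = np.nan


def window_length(
    cycle: Cycle,
    labels: PhaseLabels,
    rate: float,
    config: Optional[PipelineConfig] = None,
) -> int:
    """Foveation window length for a cycle, in samples.

    10% (``foveation_fraction``) of the total slow-phase duration within the
    cycle — summed over all slow runs, since a cycle may contain several —
    rounded to the nearest whole sample (minimum 1).  Returns 0 for a cycle
    with no slow samples.
    """
    config = config or PipelineConfig()
    n_slow = int(np.count_nonzero(labels.slow[cycle.start : cycle.end]))
    if n_slow == 0:
        return 0
    return max(1, int(round(config.foveation_fraction * n_slow)))


def detect_foveations(
    fs: FilteredSignal,
    cycles: CycleSet,
    labels: PhaseLabels,
    config: Optional[PipelineConfig] = None,
) -> List[FoveationInterval]:
    """Lowest-mean-speed window per complete cycle.

    Candidate windows start at every sample from the cycle's opening peak,
    contain only slow-labelled valid samples (hence lie within a single slow
    run), and end no later than one window-length past the closing peak.
    Samples past the boundary that are claimed by a cycle's window become
    unavailable to the next cycle.  Ties in mean speed go to the earliest
    window.  Cycles whose window would be shorter than ``min_foveation_ms``
    contribute nothing.
    """
    config = config or PipelineConfig()
    n = fs.n
    eligible = labels.slow & fs.valid & np.isfinite(fs.speed)
    s = np.where(eligible, np.nan_to_num(fs.speed, nan=0.0), 0.0)
    cs_speed = np.concatenate([[0.0], np.cumsum(s)])
    cs_ok = np.concatenate([[0], np.cumsum(eligible.astype(np.int64))])

    out: List[FoveationInterval] = []
    reserved = 0  # first index available to the current cycle's search
    for i, cyc in enumerate(cycles):
        if not cyc.complete:
            continue
        L = window_length(cyc, labels, fs.rate, config)
        dur_ms = L * 1000.0 / fs.rate
        if L == 0 or dur_ms < config.min_foveation_ms:
            continue
        first = max(cyc.start, reserved)
        last = min(cyc.end, n - L)  # window end <= cyc.end + L
        if last < first:
            continue
        starts = np.arange(first, last + 1)
        ok = (cs_ok[starts + L] - cs_ok[starts]) == L
        if not ok.any():
            continue
        means = (cs_speed[starts + L] - cs_speed[starts]) / L
        means[~ok] = np.inf
        j = int(np.argmin(means))  # argmin takes the first: earliest wins ties
        w0 = int(starts[j])
        w1 = w0 + L
        out.append(
            FoveationInterval(
                cycle_id=i,
                start=w0,
                end=w1,
                duration_ms=dur_ms,
                mean_x=float(fs.x[w0:w1].mean()),
                mean_y=float(fs.y[w0:w1].mean()),
                mean_speed=float(means[j]),
            )
        )
        reserved = w1
    return out


def point_of_regard(
    foveations: Sequence[FoveationInterval],
    fs: FilteredSignal,
    interval_ms: tuple,
    skip_initial_ms: float = 300.0,
    target_id: int = 0,
    target_deg: tuple = (np.nan, np.nan),
) -> PointOfRegard:
    """Median gaze position over all foveations inside a target interval.

    Only foveations lying entirely within ``[start + skip_initial_ms, end]``
    contribute.  The median is taken per coordinate over all samples of all
    contributing windows.  Raises :class:`FoveationError` when no foveation
    falls in the interval — calibration cannot proceed for that target.
    """
    start_ms, end_ms = interval_ms
    lo = start_ms + skip_initial_ms
    idx: List[np.ndarray] = []
    count = 0
    for f in foveations:
        t0 = fs.t_ms[f.start]
        t1 = fs.t_ms[f.end - 1]
        if t0 >= lo and t1 <= end_ms:
            idx.append(f.indices)
            count += 1
    if count == 0:
        raise FoveationError(
            f"no foveations detected for target {target_id} "
            f"in [{start_ms:g}, {end_ms:g}] ms"
        )
    sel = np.concatenate(idx)
    return PointOfRegard(
        target_id=target_id,
        x_raw=float(np.median(fs.x[sel])),
        y_raw=float(np.median(fs.y[sel])),
        n_foveations=count,
        target_x_deg=float(target_deg[0]),
        target_y_deg=float(target_deg[1]),
    )


def foveation_table(
    foveations: Sequence[FoveationInterval], fs: FilteredSignal
) -> pd.DataFrame:
    """Per-foveation report: cycle, timing, mean position and speed."""
    return pd.DataFrame(
        [
            {
                "cycle_id": f.cycle_id,
                "start_ms": fs.t_ms[f.start],
                "end_ms": fs.t_ms[f.end - 1] + 1000.0 / fs.rate,
                "duration_ms": f.duration_ms,
                "mean_x": f.mean_x,
                "mean_y": f.mean_y,
                "mean_speed": f.mean_speed,
            }
            for f in foveations
        ],
        columns=[
            "cycle_id", "start_ms", "end_ms", "duration_ms",
            "mean_x", "mean_y", "mean_speed",
        ],
    )
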