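"""Post-calibration waveform quantification and method comparison.

Once a recording is calibrated into degrees, the classic fixed-threshold
foveation criterion (speed < 4 deg/s for >= 7 ms, optionally within a
+/-0.5 deg position band) becomes applicable, and the waveform can be
quantified by amplitude, frequency and their product, the nystagmus
intensity.  The nonselective control method — the median of the entire
trace, quick phases included — is implemented here for comparison with the
foveation-based point of regard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import CalibrationModel, apply_calibration
from .config import PipelineConfig
from .foveation import FoveationInterval, PointOfRegard
from .io import GazeRecording
from .preprocess import FilteredSignal, filter_and_differentiate
from .segmentation import CycleSet


def calibrate_signal(
    model: CalibrationModel,
    rec: GazeRecording,
    config: Optional[PipelineConfig] = None,
) -> FilteredSignal:
    """Apply a calibration and re-derive speed in deg/s.

    Positions are mapped per axis through the fitted polynomial and the
    same smoothing/differentiation filter is rerun on the degree-scale
    signal, so classic thresholding uses speeds consistent with detection.
    """
    cal = apply_calibration(model, rec)
    return filter_and_differentiate(cal, config)


@dataclass
class WaveformMetrics:
    """Amplitude (deg), frequency (Hz) and intensity = amplitude x frequency."""

    amplitude_deg: float
    frequency_hz: float
    n_cycles: int

    @property
    def intensity_deg_s(self) -> float:
        return self.amplitude_deg * self.frequency_hz


def nystagmus_metrics(cal_fs: FilteredSignal, cycles: CycleSet) -> WaveformMetrics:
    """Waveform amplitude, frequency and intensity from calibrated cycles.

    Amplitude is the median over cycles of peak-to-trough primary-axis
    position; frequency is the cycle count over the spanned duration.
    Raises on zero cycles.
    """
    if len(cycles) == 0:
        raise ValueError("no cycles: cannot compute waveform metrics")
    z = cal_fs.position()
    amps = [float(np.ptp(z[c.start : c.end + 1])) for c in cycles]
    span_s = (cal_fs.t_ms[cycles[-1].end] - cal_fs.t_ms[cycles[0].start]) / 1000.0
    return WaveformMetrics(
        amplitude_deg=float(np.median(amps)),
        frequency_hz=len(cycles) / span_s,
        n_cycles=len(cycles),
    )


def classic_foveation_detect(
    cal_fs: FilteredSignal,
    v_thresh_deg_s: float = 4.0,
    min_dur_ms: float = 7.0,
    pos_window_deg: Optional[float] = None,
) -> List[FoveationInterval]:
    """Classic fixed-threshold foveation detection on a calibrated signal.

    Maximal valid runs with 2-D speed below ``v_thresh_deg_s`` and duration
    at least ``min_dur_ms``.  With ``pos_window_deg`` set, runs whose mean
    position deviates from the median of run means by more than the window
    (Euclidean) are rejected — the classical requirement that successive
    foveations lie within +/-0.5 deg of one another.
    """
    speed = np.hypot(cal_fs.vx, cal_fs.vy)
    ok = cal_fs.valid & np.isfinite(speed) & (speed < v_thresh_deg_s)
    min_len = max(1, int(round(min_dur_ms * cal_fs.rate / 1000.0)))
    runs = []
    d = np.diff(ok.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if len(ok) and ok[0]:
        starts.insert(0, 0)
    if len(ok) and ok[-1]:
        stops.append(len(ok))
    for a, b in zip(starts, stops):
        if b - a >= min_len:
            runs.append((a, b))
    if pos_window_deg is not None and runs:
        mx = np.array([cal_fs.x[a:b].mean() for a, b in runs])
        my = np.array([cal_fs.y[a:b].mean() for a, b in runs])
        dev = np.hypot(mx - np.median(mx), my - np.median(my))
        runs = [r for r, dv in zip(runs, dev) if dv <= pos_window_deg]
    out = []
    for i, (a, b) in enumerate(runs):
        sp = speed[a:b]
        out.append(
            FoveationInterval(
                cycle_id=i,
                start=a,
                end=b,
                duration_ms=(b - a) * 1000.0 / cal_fs.rate,
                mean_x=float(cal_fs.x[a:b].mean()),
                mean_y=float(cal_fs.y[a:b].mean()),
                mean_speed=float(np.nanmean(sp)),
            )
        )
    return out


def nonselective_por(
    rec: GazeRecording,
    interval_ms: Tuple[float, float],
    skip_initial_ms: float = 300.0,
    target_id: int = 0,
    target_deg: Tuple[float, float] = (np.nan, np.nan),
) -> PointOfRegard:
    """Control method: median of every valid sample in the interval.

    No segmentation is consulted — quick phases are included, which biases
    the estimate away from the foveation position on asymmetric waveforms.
    """
    start_ms, end_ms = interval_ms
    lo = start_ms + skip_initial_ms
    sel = (rec.t_ms >= lo) & (rec.t_ms <= end_ms) & rec.valid
    if not sel.any():
        raise ValueError(f"no valid samples for target {target_id} in interval")
    return PointOfRegard(
        target_id=target_id,
        x_raw=float(np.median(rec.x[sel])),
        y_raw=float(np.median(rec.y[sel])),
        n_foveations=0,
        target_x_deg=float(target_deg[0]),
        target_y_deg=float(target_deg[1]),
    )


def compare_methods(
    algorithmic: Sequence[PointOfRegard],
    nonselective: Sequence[PointOfRegard],
    reference: Sequence[PointOfRegard],
    model: CalibrationModel,
    amplitude_deg: float,
) -> pd.DataFrame:
    """Per-target error table for both methods against a reference.

    Each point of regard is mapped into degrees through ``model``; errors
    are Euclidean distances, reported both in degrees and as a percentage
    of the median nystagmus amplitude, with a difference column
    (nonselective - algorithmic; positive means the foveation-based method
    was more accurate).
    """
    if len(reference) != len(algorithmic) or len(reference) != len(nonselective):
        raise ValueError("method POR lists must align with the reference")

    def err(p: PointOfRegard, r: PointOfRegard) -> float:
        px, py = model.predict(p.x_raw, p.y_raw)
        rx, ry = model.predict(r.x_raw, r.y_raw)
        return float(np.hypot(px - rx, py - ry))

    rows = []
    for a, nsel, r in zip(algorithmic, nonselective, reference):
        e_alg = err(a, r)
        e_non = err(nsel, r)
        rows.append(
            {
                "target_id": r.target_id,
                "nonselective_err_deg": e_non,
                "nonselective_err_pct": 100.0 * e_non / amplitude_deg,
                "algorithmic_err_deg": e_alg,
                "algorithmic_err_pct": 100.0 * e_alg / amplitude_deg,
                "difference_deg": e_non - e_alg,
            }
        )
    return pd.DataFrame(rows)
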