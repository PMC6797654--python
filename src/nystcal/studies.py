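"""Simulation studies: recovery of the point of regard against ground truth.

These runners quantify, on seeded synthetic sessions, how accurately the
foveation-based method and the nonselective (whole-trace median) control
recover the true fixation positions.  Errors are expressed in degrees by
mapping raw points of regard back through the simulator's known transform —
the simulator's ground truth plays the role of the expert hand-marking
that real validation would require.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .config import PipelineConfig
from .metrics import nonselective_por
from .pipeline import segment_recording, session_pors
from .simulator import RawTransform, WaveformSpec, simulate_session


def session_por_errors(
    spec: WaveformSpec,
    seed: int,
    config: Optional[PipelineConfig] = None,
    transform: Optional[RawTransform] = None,
) -> Tuple[float, float]:
    """Mean per-target POR error (deg) for both methods on one session.

    Returns ``(algorithmic_err, nonselective_err)``, each the mean over the
    five calibration targets of the Euclidean distance between the
    recovered point of regard (expressed in true degrees through the
    inverse of the simulator's raw transform) and the true target position.
    """
    rec, truth = simulate_session(spec, seed=seed, transform=transform)
    result = segment_recording(rec, config)
    pors = session_pors(result, truth.manifest)
    alg, non = [], []
    for por, tgt in zip(pors, truth.manifest.targets):
        xd, yd = truth.transform.inverse(por.x_raw, por.y_raw)
        alg.append(float(np.hypot(xd - tgt.x_deg, yd - tgt.y_deg)))
        nsel = nonselective_por(
            rec, (tgt.start_ms, tgt.end_ms), truth.manifest.skip_initial_ms
        )
        xd, yd = truth.transform.inverse(nsel.x_raw, nsel.y_raw)
        non.append(float(np.hypot(xd - tgt.x_deg, yd - tgt.y_deg)))
    return float(np.mean(alg)), float(np.mean(non))


def por_recovery_study(
    seeds,
    amplitudes=(2.0, 4.0, 8.0),
    frequencies=(2.0, 3.0, 5.0),
    config: Optional[PipelineConfig] = None,
):
    """POR errors over seeded jerk sessions cycling an amplitude/frequency grid.

    Returns a list of ``(amplitude, algorithmic_err, nonselective_err)``.
    """
    combos = [(a, f) for a in amplitudes for f in frequencies]
    out = []
    for i, seed in enumerate(seeds):
        A, f = combos[i % len(combos)]
        spec = WaveformSpec(amplitude_deg=A, frequency_hz=f)
        alg, non = session_por_errors(spec, seed, config)
        out.append((A, alg, non))
    return out


def amplitude_sweep_study(
    amplitudes,
    seeds_per_amplitude,
    frequency_hz: float = 3.0,
    config: Optional[PipelineConfig] = None,
):
    """Error-versus-amplitude sweep at fixed frequency and noise.

    Returns ``(slope_algorithmic, slope_nonselective)`` — least-squares
    slopes of mean session error against amplitude — plus the raw records.
    """
    records = []
    for A in amplitudes:
        for seed in seeds_per_amplitude:
            spec = WaveformSpec(amplitude_deg=float(A), frequency_hz=frequency_hz)
            alg, non = session_por_errors(spec, int(seed) + int(A) * 1009, config)
            records.append((float(A), alg, non))
    arr = np.array(records)
    slope_alg = np.polyfit(arr[:, 0], arr[:, 1], 1)[0]
    slope_non = np.polyfit(arr[:, 0], arr[:, 2], 1)[0]
    return float(slope_alg), float(slope_non), records


def pendular_side_counts(
    seed: int,
    amplitude_deg: float = 2.0,
    frequency_hz: float = 3.0,
    config: Optional[PipelineConfig] = None,
) -> Tuple[int, int]:
    """Counts of foveations on the peak side vs the trough side of a
    simulated pure pendular (sine) session."""
    spec = WaveformSpec(
        kind="pendular", amplitude_deg=amplitude_deg, frequency_hz=frequency_hz
    )
    rec, truth = simulate_session(spec, seed=seed)
    result = segment_recording(rec, config)
    peak = trough = 0
    for f in result.foveations:
        m = float(truth.x_deg[f.start:f.end].mean())
        for (a, b), tgt in zip(truth.target_slices, truth.manifest.targets):
            if a <= f.start < b:
                d = m - tgt.x_deg
                if d > 0.5 * amplitude_deg:
                    peak += 1
                elif d < -0.5 * amplitude_deg:
                    trough += 1
    return peak, trough
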