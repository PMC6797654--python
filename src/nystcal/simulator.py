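"""Synthetic infantile-nystagmus calibration sessions with ground truth.

Generates 1000 Hz uncalibrated recordings of the standard five-point
calibration protocol (targets at +/-5 deg horizontally and +/-3 deg
vertically, 10 s each) for three waveform families:

* ``jerk`` — an accelerating exponential slow phase drifting off target,
  ended by a minimum-jerk quick phase back onto it (accelerating slow phases
  are the defining feature of the condition);
* ``jerk_extended_foveation`` — the same with a stationary plateau on target
  prepended to each slow phase;
* ``pendular`` — a pure sine about the target.

The degree-scale signal is corrupted with white Gaussian noise, blink gaps
(invalid runs with 20 ms position spikes at the edges, to exercise blink
trimming), and an unknown affine map to raw tracker units — per-axis gain
and offset plus a rotation of the calibration field, the situation the
calibration's cross-talk term exists for.  Everything is seeded and
bit-reproducible, and the generator returns the exact ground truth (true
gaze, cycle boundaries, quick phases, and per-cycle lowest-true-speed
foveation windows) that a hand-marking expert would otherwise provide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .io import GazeRecording, SessionManifest, TargetEpoch

FIVE_POINT_GRID = ((0.0, 0.0), (-5.0, 0.0), (5.0, 0.0), (0.0, -3.0), (0.0, 3.0))


@dataclass
class WaveformSpec:
    """Parameters of one synthetic nystagmus waveform.

    ``direction`` names the quick-phase (beat) direction: a right-beating
    jerk drifts leftward during the slow phase and snaps back rightward.
    ``slow_phase_tau_s`` is the exponential time constant of the
    accelerating slow phase; None defaults to half the slow-phase duration.
    ``overshoot_frac`` adds hypermetric quick phases (excluded from default
    sessions).
    """

    kind: str = "jerk"
    amplitude_deg: float = 4.0
    frequency_hz: float = 3.0
    slow_phase_tau_s: Optional[float] = None
    quick_phase_ms: float = 30.0
    extended_foveation_ms: float = 60.0
    direction: str = "right-beating"
    noise_sd_deg: float = 0.05
    overshoot_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("jerk", "jerk_extended_foveation", "pendular"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        if self.amplitude_deg <= 0:
            raise ValueError("amplitude must be > 0")
        if not 0.5 <= self.frequency_hz <= 10.0:
            raise ValueError("frequency must lie in [0.5, 10] Hz")
        period_ms = 1000.0 / self.frequency_hz
        occupied = self.quick_phase_ms + (
            self.extended_foveation_ms if self.kind == "jerk_extended_foveation" else 0.0
        )
        if self.kind != "pendular" and occupied >= period_ms:
            raise ValueError("quick phase (+ plateau) must be shorter than the cycle")
        if self.direction not in ("left-beating", "right-beating"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class RawTransform:
    """Unknown degrees-to-raw-units map: rotation, per-axis gain, offset.

    raw = diag(gain) @ R(rotation) @ deg + offset.  The rotation models a
    head tilt of the calibration field; gains are in units/deg.
    """

    gain_x: float = 30.0
    gain_y: float = 25.0
    offset_x: float = 150.0
    offset_y: float = -90.0
    rotation_deg: float = 3.0

    def __post_init__(self) -> None:
        if self.gain_x == 0 or self.gain_y == 0:
            raise ValueError("gains must be nonzero")

    def _rot(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def apply(self, x_deg, y_deg) -> Tuple[np.ndarray, np.ndarray]:
        R = self._rot()
        xr = self.gain_x * (R[0, 0] * x_deg + R[0, 1] * y_deg) + self.offset_x
        yr = self.gain_y * (R[1, 0] * x_deg + R[1, 1] * y_deg) + self.offset_y
        return xr, yr

    def inverse(self, x_raw, y_raw) -> Tuple[np.ndarray, np.ndarray]:
        R = self._rot()
        u = (np.asarray(x_raw) - self.offset_x) / self.gain_x
        v = (np.asarray(y_raw) - self.offset_y) / self.gain_y
        return R[0, 0] * u + R[1, 0] * v, R[0, 1] * u + R[1, 1] * v


@dataclass
class CycleFragment:
    """One noiseless cycle in degrees with its ground-truth intervals
    (sample indices relative to the fragment start)."""

    x_deg: np.ndarray
    speed_deg: np.ndarray  # signed horizontal velocity, deg/s
    slow: Tuple[int, int]
    quick: Optional[Tuple[int, int]]
    foveation: Tuple[int, int]


def _min_jerk(u: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk position profile p(u) on [0,1] and its derivative."""
    return 10 * u**3 - 15 * u**4 + 6 * u**5, 30 * u**2 - 60 * u**3 + 30 * u**4


def _true_foveation(speed: np.ndarray, slow: Tuple[int, int], frac: float = 0.10):
    """Exhaustive lowest-mean-|speed| window of length frac*slow within slow."""
    a, b = slow
    n_slow = b - a
    L = max(1, int(round(frac * n_slow)))
    sp = np.abs(speed[a:b])
    cs = np.concatenate([[0.0], np.cumsum(sp)])
    means = (cs[L:] - cs[:-L]) / L
    j = int(np.argmin(means))
    return a + j, a + j + L


def simulate_cycle(
    spec: WaveformSpec,
    fixation_deg: Tuple[float, float] = (0.0, 0.0),
    rate: float = 1000.0,
) -> CycleFragment:
    """Generate one noiseless cycle of the requested waveform.

    The jerk slow phase is the accelerating exponential
    ``x(t) = x_f + s*A*(exp(t/tau) - 1)/(exp(T_s/tau) - 1)`` with s the
    drift sign, returned to the fixation point by a minimum-jerk quick
    phase.  The true foveation is the lowest-mean-true-speed window lasting
    10% of the slow-phase duration, found by exhaustive search.
    """
    x_f = float(fixation_deg[0])
    A = spec.amplitude_deg
    n_T = int(round(rate / spec.frequency_hz))

    if spec.kind == "pendular":
        t = np.arange(n_T) / rate
        w = 2 * np.pi * spec.frequency_hz
        x = x_f + A * np.sin(w * t)
        v = A * w * np.cos(w * t)
        slow = (0, n_T)
        frag = CycleFragment(x, v, slow, None, _true_foveation(v, slow))
        return frag

    s = -1.0 if spec.direction == "right-beating" else 1.0
    n_q = max(2, int(round(spec.quick_phase_ms * rate / 1000.0)))
    n_e = (
        int(round(spec.extended_foveation_ms * rate / 1000.0))
        if spec.kind == "jerk_extended_foveation"
        else 0
    )
    n_s = n_T - n_q - n_e
    if n_s < 2:
        raise ValueError("slow phase too short for these parameters")
    T_s = n_s / rate
    tau = spec.slow_phase_tau_s if spec.slow_phase_tau_s is not None else T_s / 2.0
    if tau <= 0:
        raise ValueError("slow-phase time constant must be > 0 (monotone drift)")

    x = np.empty(n_T)
    v = np.empty(n_T)
    # plateau: stationary on target
    x[:n_e] = x_f
    v[:n_e] = 0.0
    # accelerating slow phase
    t = np.arange(n_s) / rate
    denom = np.expm1(T_s / tau)
    x[n_e : n_e + n_s] = x_f + s * A * np.expm1(t / tau) / denom
    v[n_e : n_e + n_s] = s * A * np.exp(t / tau) / (tau * denom)
    # minimum-jerk quick phase back to the fixation point
    x_off = x_f + s * A * np.expm1(T_s / tau) / denom  # = x_f + s*A
    q0 = n_e + n_s
    T_q = n_q / rate
    if spec.overshoot_frac > 0:
        # hypermetric: overshoot past the target, then correct, within T_q
        x_over = x_f - s * spec.overshoot_frac * A
        n1 = max(2, int(round(0.6 * n_q)))
        n2 = n_q - n1
        u1 = np.arange(n1) / n1
        p1, dp1 = _min_jerk(u1)
        x[q0 : q0 + n1] = x_off + (x_over - x_off) * p1
        v[q0 : q0 + n1] = (x_over - x_off) * dp1 / (n1 / rate)
        u2 = np.arange(n2) / max(n2, 1)
        p2, dp2 = _min_jerk(u2)
        x[q0 + n1 :] = x_over + (x_f - x_over) * p2
        v[q0 + n1 :] = (x_f - x_over) * dp2 / (max(n2, 1) / rate)
    else:
        # u starts at 0 so the full excursion x_f + s*A is attained exactly
        u = np.arange(n_q) / n_q
        p, dp = _min_jerk(u)
        x[q0:] = x_off + (x_f - x_off) * p
        v[q0:] = (x_f - x_off) * dp / T_q

    slow = (0, n_e + n_s)  # plateau + drift are both slow phase
    quick = (q0, n_T)
    return CycleFragment(x, v, slow, quick, _true_foveation(v, slow))


@dataclass
class GroundTruth:
    """Sample-exact truth for a simulated session.

    ``x_deg``/``y_deg`` are the noiseless true gaze; intervals are half-open
    sample-index pairs.  ``cycle_bounds`` holds the start index of every
    generated cycle plus the final end.  ``foveations`` are the per-cycle
    lowest-true-speed windows — each has lower mean true speed than any
    other same-length slow-phase window in its cycle, by exhaustive search.
    """

    x_deg: np.ndarray
    y_deg: np.ndarray
    speed_deg: np.ndarray
    cycle_bounds: np.ndarray
    foveations: List[Tuple[int, int]]
    quick_phases: List[Tuple[int, int]]
    blink_intervals: List[Tuple[int, int]]
    target_slices: List[Tuple[int, int]]
    transform: RawTransform
    manifest: SessionManifest

    def to_json(self, path) -> None:
        doc = {
            "cycle_bounds": self.cycle_bounds.tolist(),
            "foveations": [list(f) for f in self.foveations],
            "quick_phases": [list(q) for q in self.quick_phases],
            "blink_intervals": [list(b) for b in self.blink_intervals],
            "target_slices": [list(t) for t in self.target_slices],
            "transform": {
                "gain_x": self.transform.gain_x,
                "gain_y": self.transform.gain_y,
                "offset_x": self.transform.offset_x,
                "offset_y": self.transform.offset_y,
                "rotation_deg": self.transform.rotation_deg,
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")


def default_manifest(
    grid: Sequence[Tuple[float, float]] = FIVE_POINT_GRID,
    dwell_ms: float = 10000.0,
    skip_initial_ms: float = 300.0,
) -> SessionManifest:
    """The five-point protocol: targets at +/-5 deg H and +/-3 deg V, 10 s each."""
    targets = [
        TargetEpoch(x, y, i * dwell_ms, (i + 1) * dwell_ms)
        for i, (x, y) in enumerate(grid)
    ]
    return SessionManifest(targets, skip_initial_ms=skip_initial_ms, dwell_ms=dwell_ms)


_BLINK_SPIKE_DEG = 3.0
_BLINK_EDGE_MS = 20.0


def simulate_session(
    spec: Union[WaveformSpec, Sequence[WaveformSpec]],
    manifest: Optional[SessionManifest] = None,
    transform: Optional[RawTransform] = None,
    seed: int = 0,
    rate: float = 1000.0,
    blinks_per_target: int = 1,
) -> Tuple[GazeRecording, GroundTruth]:
    """Simulate a full uncalibrated calibration session.

    ``spec`` may be a single waveform for all targets or one per target
    (waveform intensity can change with gaze angle).  Returns the raw-unit
    recording and the ground truth.  Fully deterministic for a fixed seed.
    """
    manifest = manifest or default_manifest()
    transform = transform or RawTransform()
    n_targets = len(manifest.targets)
    specs = list(spec) if isinstance(spec, (list, tuple)) else [spec] * n_targets
    if len(specs) != n_targets:
        raise ValueError("need one waveform spec per manifest target")
    rng = np.random.default_rng(seed)

    x_parts, y_parts = [], []
    cycle_starts: List[int] = []
    foveations: List[Tuple[int, int]] = []
    quick_phases: List[Tuple[int, int]] = []
    target_slices: List[Tuple[int, int]] = []
    speed_parts = []
    offset = 0
    last_end = 0
    for tgt, sp in zip(manifest.targets, specs):
        n_tgt = int(round((tgt.end_ms - tgt.start_ms) * rate / 1000.0))
        frag = simulate_cycle(sp, (tgt.x_deg, tgt.y_deg), rate)
        n_cyc = len(frag.x_deg)
        reps = int(np.ceil(n_tgt / n_cyc))
        x_t = np.tile(frag.x_deg, reps)[:n_tgt]
        v_t = np.tile(frag.speed_deg, reps)[:n_tgt]
        for r in range(reps):
            base = offset + r * n_cyc
            if r * n_cyc >= n_tgt:
                break
            cycle_starts.append(base)
            f0, f1 = frag.foveation
            if r * n_cyc + f1 <= n_tgt:
                foveations.append((base + f0, base + f1))
            if frag.quick is not None:
                q0, q1 = frag.quick
                if r * n_cyc + q1 <= n_tgt:
                    quick_phases.append((base + q0, base + q1))
        x_parts.append(x_t)
        y_parts.append(np.full(n_tgt, tgt.y_deg))
        speed_parts.append(v_t)
        target_slices.append((offset, offset + n_tgt))
        offset += n_tgt
        last_end = offset

    x_true = np.concatenate(x_parts)
    y_true = np.concatenate(y_parts)
    speed_true = np.concatenate(speed_parts)
    n = len(x_true)
    t_ms = np.arange(n) * 1000.0 / rate

    # measured signal: truth + white Gaussian noise in degrees
    noise_sds = np.concatenate(
        [
            np.full(b - a, specs[i].noise_sd_deg)
            for i, (a, b) in enumerate(target_slices)
        ]
    )
    x_meas = x_true + rng.standard_normal(n) * noise_sds
    y_meas = y_true + rng.standard_normal(n) * noise_sds

    # blinks: invalid runs with position spikes on both edges
    valid = np.ones(n, dtype=bool)
    blink_intervals: List[Tuple[int, int]] = []
    n_edge = int(round(_BLINK_EDGE_MS * rate / 1000.0))
    for a, b in target_slices:
        for _ in range(blinks_per_target):
            dur = int(round(rng.uniform(100, 200) * rate / 1000.0))
            t0 = int(rng.uniform(a + 1500, b - 1500 - dur))
            valid[t0 : t0 + dur] = False
            blink_intervals.append((t0, t0 + dur))
            ramp = np.linspace(0.0, _BLINK_SPIKE_DEG, n_edge)
            x_meas[t0 - n_edge : t0] += ramp
            y_meas[t0 - n_edge : t0] -= ramp
            x_meas[t0 + dur : t0 + dur + n_edge] += ramp[::-1]
            y_meas[t0 + dur : t0 + dur + n_edge] -= ramp[::-1]

    x_raw, y_raw = transform.apply(x_meas, y_meas)
    rec = GazeRecording(t_ms, x_raw, y_raw, valid, rate=rate)
    truth = GroundTruth(
        x_deg=x_true,
        y_deg=y_true,
        speed_deg=speed_true,
        cycle_bounds=np.array(cycle_starts + [last_end], dtype=int),
        foveations=foveations,
        quick_phases=quick_phases,
        blink_intervals=blink_intervals,
        target_slices=target_slices,
        transform=transform,
        manifest=manifest,
    )
    return rec, truth
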