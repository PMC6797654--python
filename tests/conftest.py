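import numpy as np
import pytest

from nystcal import (
    GazeRecording,
    PipelineConfig,
    SessionManifest,
    TargetEpoch,
    WaveformSpec,
    simulate_session,
)


@pytest.fixture
def cfg():
    return PipelineConfig()


def make_recording(x, y=None, valid=None, rate=1000.0):
    """Build a recording from plain arrays with uniform timestamps."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    y = np.zeros(n) if y is None else np.asarray(y, dtype=float)
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    t = np.arange(n) * 1000.0 / rate
    return GazeRecording(t, x, y, valid, rate=rate)


@pytest.fixture
def recording_factory():
    return make_recording


def single_target_session(spec, seed=0, dwell_ms=10000.0, blinks=0, fixation=(0.0, 0.0)):
    """One continuous fixation on a single target, no target transitions."""
    man = SessionManifest([TargetEpoch(fixation[0], fixation[1], 0.0, dwell_ms)])
    return simulate_session(spec, manifest=man, seed=seed, blinks_per_target=blinks)


@pytest.fixture
def single_target():
    return single_target_session


@pytest.fixture(scope="session")
def jerk_session():
    """A full five-target jerk calibration session with default study settings."""
    rec, truth = simulate_session(WaveformSpec(amplitude_deg=4.0, frequency_hz=3.0), seed=7)
    return rec, truth


def brute_force_foveations(fs, cycles, labels, fraction=0.10, min_ms=7.0):
    """Independent exhaustive-search oracle for foveation detection.

    Enumerates every candidate window by explicit loops, recomputing the
    window length, the slow/valid constraint, the one-window-past-the-peak
    extension, and the hand-off of reserved samples to the next cycle.
    """
    slow_ok = labels.slow & fs.valid & np.isfinite(fs.speed)
    out = []
    reserved = 0
    for ci, cyc in enumerate(cycles):
        if not cyc.complete:
            continue
        n_slow = int(slow_ok[cyc.start:cyc.end].sum())
        if n_slow == 0:
            continue
        L = max(1, round(fraction * n_slow))
        if L * 1000.0 / fs.rate < min_ms:
            continue
        best = None
        for p in range(max(cyc.start, reserved), cyc.end + 1):
            if p + L > fs.n:
                break
            if not slow_ok[p:p + L].all():
                continue
            m = float(np.mean(fs.speed[p:p + L]))
            if best is None or m < best[1]:
                best = (p, m)
        if best is None:
            continue
        out.append((ci, best[0], best[0] + L))
        reserved = best[0] + L
    return out


@pytest.fixture
def foveation_oracle():
    return brute_force_foveations
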