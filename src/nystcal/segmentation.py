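"""Cycle splitting and quick/slow-phase labelling on uncalibrated signals.

Everything here is scale-free: cycle boundaries come from peaks of the
primary-axis position signal (minimum separation and prominence derived from
the signal's own dominant frequency and amplitude spread), and quick phases
(saccades) are detected from robust statistics of the speed signal, so no
precalibrated degrees are needed and the output is invariant under any
positive rescaling of the raw units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.signal import find_peaks

from .config import PipelineConfig
from .preprocess import FilteredSignal, primary_axis_of

# per-sample phase labels
SLOW, QUICK, INVALID = 0, 1, 2


def primary_axis(fs: FilteredSignal) -> str:
    """Nystagmus axis: the one with the larger position standard deviation."""
    return primary_axis_of(fs.x, fs.y, fs.valid)


@dataclass
class Cycle:
    """One nystagmus cycle: samples [start, end) between successive boundary
    peaks; ``peak`` is the interior turning point; ``complete`` is False iff
    any sample in [start, end] is invalid."""

    start: int
    peak: int
    end: int
    complete: bool


@dataclass
class CycleSet:
    """Ordered, contiguous, non-overlapping cycles of a waveform."""

    cycles: List[Cycle] = field(default_factory=list)
    dominant_freq_hz: Optional[float] = None
    inverted: bool = False  # peaks found on the sign-flipped signal

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    def __getitem__(self, i):
        return self.cycles[i]

    @property
    def boundaries(self) -> np.ndarray:
        if not self.cycles:
            return np.array([], dtype=int)
        return np.array([c.start for c in self.cycles] + [self.cycles[-1].end])


def complete_cycles(cycles: CycleSet) -> CycleSet:
    """Subset of cycles free of blinks/gaps, order preserved."""
    return CycleSet(
        [c for c in cycles if c.complete],
        dominant_freq_hz=cycles.dominant_freq_hz,
        inverted=cycles.inverted,
    )


def _fill_invalid(z: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly bridge invalid samples so peak finding sees a finite signal."""
    if valid.all():
        return z
    out = z.copy()
    idx = np.arange(len(z))
    out[~valid] = np.interp(idx[~valid], idx[valid], z[valid])
    return out


def dominant_frequency(
    z: np.ndarray, valid: np.ndarray, rate: float,
    f_lo: float = 0.5, f_hi: float = 10.0,
) -> Optional[float]:
    """Dominant oscillation frequency from the autocorrelation peak.

    Searched over lags corresponding to ``f_lo``–``f_hi`` Hz; returns None
    when the signal is too short or has no autocorrelation peak (e.g. a
    constant trace).
    """
    z = _fill_invalid(z, valid)
    z = z - z.mean()
    n = len(z)
    lag_min = max(1, int(np.floor(rate / f_hi)))
    lag_max = int(np.ceil(rate / f_lo))
    if n < 2 * lag_min + 2 or np.allclose(z, 0):
        return None
    lag_max = min(lag_max, n - 2)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(z, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[: n]
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    window = ac[lag_min : lag_max + 1]
    if len(window) == 0:
        return None
    # first local maximum above a weak correlation floor, else global argmax
    peaks, _ = find_peaks(window, height=0.1)
    lag = lag_min + (peaks[0] if len(peaks) else int(np.argmax(window)))
    if ac[lag] <= 0.05:
        return None
    return rate / lag


def _local_speed(fs: FilteredSignal, idx: np.ndarray, half_ms: float = 5.0) -> float:
    """Mean detection speed in small windows around the given indices."""
    half = max(1, int(round(half_ms * fs.rate / 1000.0)))
    vals = []
    for i in idx:
        w = fs.speed[max(0, i - half): i + half + 1]
        w = w[np.isfinite(w)]
        if len(w):
            vals.append(w.mean())
    return float(np.mean(vals)) if vals else np.inf


def _find_boundary_peaks(z, prominence, distance):
    peaks, _ = find_peaks(z, prominence=prominence, distance=distance)
    return peaks


def split_cycles(
    fs: FilteredSignal,
    axis: Optional[str] = None,
    config: Optional[PipelineConfig] = None,
) -> CycleSet:
    """Split the waveform into cycles at successive position peaks.

    Peak criteria are derived from the signal itself: minimum separation of
    half the dominant period and minimum prominence of 0.2x the inter-quartile
    range of position, so the result is unchanged by any positive affine
    rescaling of the raw units.  In ``auto`` polarity the sign (peaks vs
    troughs) with the smaller local speed at its peaks is used, placing cycle
    boundaries on the foveating side of the waveform.  Samples before the
    first and after the last peak belong to no cycle.  Fewer than two peaks
    yield an empty :class:`CycleSet`.
    """
    config = config or PipelineConfig()
    axis = axis or primary_axis(fs)
    z_raw = fs.position(axis)
    z = _fill_invalid(z_raw, fs.valid)

    f_lo, f_hi = config.freq_search_hz
    f_hat = dominant_frequency(z_raw, fs.valid, fs.rate, f_lo, f_hi)
    if f_hat is None:
        return CycleSet([])
    distance = max(1, int(round(config.peak_min_separation_periods / f_hat * fs.rate)))
    zv = z_raw[fs.valid]
    q75, q25 = np.percentile(zv, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return CycleSet([])
    prominence = config.peak_prominence_frac * iqr

    if config.peak_polarity == "normal":
        peaks, inverted = _find_boundary_peaks(z, prominence, distance), False
    elif config.peak_polarity == "inverted":
        peaks, inverted = _find_boundary_peaks(-z, prominence, distance), True
    else:  # auto: pick the polarity whose peaks sit on the slower samples
        p_up = _find_boundary_peaks(z, prominence, distance)
        p_dn = _find_boundary_peaks(-z, prominence, distance)
        if len(p_dn) < 2:
            peaks, inverted = p_up, False
        elif len(p_up) < 2:
            peaks, inverted = p_dn, True
        else:
            s_up = _local_speed(fs, p_up)
            s_dn = _local_speed(fs, p_dn)
            if s_dn < s_up:
                peaks, inverted = p_dn, True
            else:
                peaks, inverted = p_up, False

    if len(peaks) < 2:
        return CycleSet([], dominant_freq_hz=f_hat, inverted=inverted)

    sign = -1.0 if inverted else 1.0
    cycles = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        interior = int(a + np.argmin(sign * z[a:b])) if b > a + 1 else int(a)
        complete = bool(fs.valid[a : b + 1].all())
        cycles.append(Cycle(int(a), interior, int(b), complete))
    return CycleSet(cycles, dominant_freq_hz=f_hat, inverted=inverted)


@dataclass
class PhaseLabels:
    """Per-sample quick/slow/invalid labels; an exact partition."""

    labels: np.ndarray  # int8, values SLOW/QUICK/INVALID

    @property
    def slow(self) -> np.ndarray:
        return self.labels == SLOW

    @property
    def quick(self) -> np.ndarray:
        return self.labels == QUICK

    @property
    def invalid(self) -> np.ndarray:
        return self.labels == INVALID

    def counts(self) -> dict:
        return {
            "slow": int(np.count_nonzero(self.slow)),
            "quick": int(np.count_nonzero(self.quick)),
            "invalid": int(np.count_nonzero(self.invalid)),
        }


def _runs_of(mask: np.ndarray):
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if len(mask) and mask[0]:
        starts.insert(0, 0)
    if len(mask) and mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def detect_quick_phases(
    fs: FilteredSignal, config: Optional[PipelineConfig] = None
) -> PhaseLabels:
    """Label quick phases (saccades) from robust speed statistics.

    A sample is a saccade candidate when its detection speed exceeds
    ``median(speed) + k * MAD(speed)`` (k = 6 by default) — a unit-free
    criterion, as required for uncalibrated data.  Candidate runs closer
    than ``saccade_merge_ms`` merge; runs shorter than ``min_saccade_ms``
    are discarded; surviving runs grow outward to the nearest local speed
    minimum.  Slow phases are all valid samples where no saccade is
    occurring.
    """
    config = config or PipelineConfig()
    s = fs.speed
    n = fs.n
    labels = np.zeros(n, dtype=np.int8)
    masked = ~fs.valid | ~np.isfinite(s)
    labels[masked] = INVALID
    finite = s[~masked]
    if len(finite) == 0:
        return PhaseLabels(labels)
    med = float(np.median(finite))
    mad = float(np.median(np.abs(finite - med)))
    thresh = med + config.saccade_k * mad
    cand = np.zeros(n, dtype=bool)
    cand[~masked] = s[~masked] > thresh

    merge = int(round(config.saccade_merge_ms * fs.rate / 1000.0))
    runs = _runs_of(cand)
    merged = []
    for run in runs:
        if merged:
            gap = slice(merged[-1][1], run[0])
            joinable = (
                run[0] - merged[-1][1] < merge
                and not masked[gap].any()
                # speed returning to the slow (below-median) level between
                # candidates means they are separate events, not one saccade
                and np.min(s[gap]) >= med
            )
        else:
            joinable = False
        if joinable:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    min_len = int(round(config.min_saccade_ms * fs.rate / 1000.0))
    for start, stop in merged:
        if stop - start < min_len:
            continue
        # extend to the surrounding local speed minima; stop early once speed
        # falls below the median — unambiguously slow-phase territory
        while (
            start > 0
            and not masked[start - 1]
            and med <= s[start - 1] < s[start]
        ):
            start -= 1
        while stop < n and not masked[stop] and med <= s[stop] < s[stop - 1]:
            stop += 1
        labels[start:stop] = np.where(
            labels[start:stop] == INVALID, INVALID, QUICK
        )
    return PhaseLabels(labels)
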