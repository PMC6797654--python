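"""Pipeline configuration.

All tunable constants of the calibration pipeline live here, each defaulting
to the value of the protocol it implements: gaps of at most 25 ms are
interpolated, 75 ms is removed on either side of remaining gaps, foveation
windows span 10% of the slow-phase duration of a cycle with a 7 ms floor,
recordings with less than 85% capture are flagged, and the classic
post-calibration foveation criterion is 4 deg/s within a +/-0.5 deg position
band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


@dataclass
class PipelineConfig:
    """Constants controlling every stage of the nystagmus pipeline.

    Durations are in milliseconds unless the name says otherwise.
    """

    # preprocessing
    max_gap_ms: float = 25.0
    blink_pad_ms: float = 75.0
    sg_polyorder: int = 3
    sg_window_samples_1khz: int = 21
    speed_mode: str = "primary"  # "primary" | "magnitude"

    # cycle splitting (scale-free peak detection)
    peak_prominence_frac: float = 0.2
    peak_min_separation_periods: float = 0.5
    freq_search_hz: Tuple[float, float] = (0.5, 10.0)
    peak_polarity: str = "auto"  # "auto" | "normal" | "inverted"

    # quick-phase (saccade) detection, scale-free
    saccade_k: float = 6.0
    saccade_merge_ms: float = 10.0
    min_saccade_ms: float = 10.0

    # foveation detection
    foveation_fraction: float = 0.10
    min_foveation_ms: float = 7.0

    # session protocol / quality
    skip_initial_ms: float = 300.0
    capture_threshold: float = 0.85

    # classic fixed-threshold foveation criterion (post-calibration)
    classic_velocity_thresh_deg_s: float = 4.0
    classic_position_window_deg: float = 0.5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        durations = (
            self.max_gap_ms,
            self.blink_pad_ms,
            self.min_foveation_ms,
            self.saccade_merge_ms,
            self.min_saccade_ms,
        )
        if any(d <= 0 for d in durations):
            raise ValueError("all durations must be > 0")
        if not 0.0 < self.foveation_fraction < 1.0:
            raise ValueError("foveation_fraction must lie in (0, 1)")
        if not 0.0 < self.capture_threshold <= 1.0:
            raise ValueError("capture_threshold must lie in (0, 1]")
        if self.speed_mode not in ("primary", "magnitude"):
            raise ValueError(f"unknown speed_mode {self.speed_mode!r}")
        if self.peak_polarity not in ("auto", "normal", "inverted"):
            raise ValueError(f"unknown peak_polarity {self.peak_polarity!r}")
        if self.sg_polyorder < 1 or self.sg_window_samples_1khz <= self.sg_polyorder:
            raise ValueError("filter window must exceed polynomial order")
        lo, hi = self.freq_search_hz
        if not 0 < lo < hi:
            raise ValueError("freq_search_hz must be an increasing positive pair")

    def sg_window(self, rate: float) -> int:
        """Filter window in samples, scaled from the 1000 Hz default and forced odd."""
        w = int(round(self.sg_window_samples_1khz * rate / 1000.0))
        if w % 2 == 0:
            w += 1
        return max(w, self.sg_polyorder + 2 + ((self.sg_polyorder + 2) % 2 == 0))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["freq_search_hz"] = list(self.freq_search_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "freq_search_hz" in d:
            d["freq_search_hz"] = tuple(d["freq_search_hz"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
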