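"""End-to-end orchestration: recording + manifest -> fitted calibration.

Ties the stages together (clean -> filter -> split cycles -> label phases ->
detect foveations -> per-target point of regard -> polynomial fit) and keeps
a run log with the per-stage counts that make silent mis-segmentation
visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import List, Optional, Tuple

import numpy as np

from . import foveation as fov
from . import preprocess as pre
from . import segmentation as seg
from .calibration import CalibrationModel, fit_calibration
from .config import PipelineConfig
from .io import GazeRecording, SessionManifest, check_capture


@dataclass
class StageRecord:
    """One pipeline stage: name, parameters used, and result counts."""

    stage: str
    params: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )


@dataclass
class RunLog:
    """Ordered stage records for one pipeline run."""

    records: List[StageRecord] = field(default_factory=list)

    def add(self, stage: str, params: Optional[dict] = None, **counts) -> None:
        self.records.append(StageRecord(stage, params or {}, counts))

    def __iter__(self):
        return iter(self.records)

    def format(self) -> str:
        lines = []
        for r in self.records:
            cnt = ", ".join(f"{k}={v}" for k, v in r.counts.items())
            lines.append(f"[{r.stage}] {cnt}")
        return "\n".join(lines)


@dataclass
class SegmentationResult:
    """Everything the segmentation stack produced for one recording."""

    fs: pre.FilteredSignal
    cycles: seg.CycleSet
    complete: seg.CycleSet
    labels: seg.PhaseLabels
    foveations: List[fov.FoveationInterval]
    log: RunLog


def segment_recording(
    rec: GazeRecording, config: Optional[PipelineConfig] = None
) -> SegmentationResult:
    """Run cleaning, filtering, cycle splitting, phase labelling and
    foveation detection on one recording."""
    config = config or PipelineConfig()
    log = RunLog()

    report = check_capture(rec, config.capture_threshold)
    log.add(
        "capture_check",
        {"threshold": config.capture_threshold},
        valid=report.n_valid,
        total=report.n_total,
        passed=int(report.passed),
    )

    filled = pre.interpolate_gaps(rec, config.max_gap_ms)
    log.add(
        "interpolate_gaps",
        {"max_gap_ms": config.max_gap_ms},
        gaps_filled=int(np.count_nonzero(filled.valid) - np.count_nonzero(rec.valid)),
    )
    trimmed = pre.trim_blinks(filled, config.blink_pad_ms)
    log.add(
        "trim_blinks",
        {"pad_ms": config.blink_pad_ms},
        samples_trimmed=int(
            np.count_nonzero(filled.valid) - np.count_nonzero(trimmed.valid)
        ),
    )
    fs = pre.filter_and_differentiate(trimmed, config)
    log.add(
        "filter",
        {"window": config.sg_window(rec.rate), "order": config.sg_polyorder},
        primary_axis=fs.primary,
    )

    cycles = seg.split_cycles(fs, config=config)
    ccycles = seg.complete_cycles(cycles)
    log.add(
        "split_cycles",
        {"dominant_freq_hz": cycles.dominant_freq_hz, "inverted": cycles.inverted},
        cycles=len(cycles),
        complete=len(ccycles),
    )
    labels = seg.detect_quick_phases(fs, config)
    log.add("detect_quick_phases", {"k": config.saccade_k}, **labels.counts())

    fovs = fov.detect_foveations(fs, cycles, labels, config)
    log.add(
        "detect_foveations",
        {"fraction": config.foveation_fraction, "floor_ms": config.min_foveation_ms},
        foveations=len(fovs),
    )
    return SegmentationResult(fs, cycles, ccycles, labels, fovs, log)


def session_pors(
    result: SegmentationResult, manifest: SessionManifest
) -> List[fov.PointOfRegard]:
    """Foveation-based point of regard for every manifest target."""
    pors = []
    for i, tgt in enumerate(manifest.targets):
        pors.append(
            fov.point_of_regard(
                result.foveations,
                result.fs,
                (tgt.start_ms, tgt.end_ms),
                skip_initial_ms=manifest.skip_initial_ms,
                target_id=i,
                target_deg=(tgt.x_deg, tgt.y_deg),
            )
        )
    return pors


def calibrate_session(
    rec: GazeRecording,
    manifest: SessionManifest,
    config: Optional[PipelineConfig] = None,
    order: str = "linear_xtalk",
) -> Tuple[CalibrationModel, List[fov.PointOfRegard], SegmentationResult]:
    """Full calibration: recording + manifest -> fitted raw-to-degrees model."""
    config = config or PipelineConfig()
    manifest.check_fit_geometry()
    result = segment_recording(rec, config)
    pors = session_pors(result, manifest)
    model = fit_calibration(pors, order=order)
    result.log.add(
        "fit_calibration",
        {"order": order},
        targets=len(pors),
        max_residual_deg=float(np.max(model.residuals_deg)),
    )
    return model, pors, result


def recording_por(
    rec: GazeRecording,
    config: Optional[PipelineConfig] = None,
    skip_initial_ms: float = 300.0,
) -> Tuple[float, float, int]:
    """Foveation-based point of regard of a whole single-target recording.

    Returns ``(x_raw, y_raw, n_foveations)``; used for drift correction.
    """
    config = config or PipelineConfig()
    result = segment_recording(rec, config)
    try:
        por = fov.point_of_regard(
            result.foveations,
            result.fs,
            (rec.t_ms[0], rec.t_ms[-1]),
            skip_initial_ms=skip_initial_ms,
        )
    except fov.FoveationError:
        return np.nan, np.nan, 0
    return por.x_raw, por.y_raw, por.n_foveations
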