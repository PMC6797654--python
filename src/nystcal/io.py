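"""Reading and writing gaze recordings, session manifests and calibration files.

Uncalibrated recordings are per-sample streams of timestamp (ms), horizontal
and vertical position in arbitrary tracker units, and a validity flag.  Two
text dialects are supported: a simple delimited format (header row
``t_ms,x,y,valid``; ``valid`` optional) and a minimal EyeLink-ASC sample
subset (whitespace-delimited ``t x y pupil`` lines plus blink events; all
other lines ignored).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationModel

MIN_RATE_HZ = 200.0

PathLike = Union[str, Path]


class GazeDataError(ValueError):
    """Raised for unparseable, non-monotonic, non-uniform or under-sampled data."""


class CalibrationFileError(ValueError):
    """Raised for corrupt or version-mismatched calibration files."""


@dataclass
class GazeRecording:
    """An uncalibrated monocular gaze recording.

    Positions are in arbitrary tracker units (or degrees after calibration,
    see ``units``).  Samples flagged invalid carry no positional meaning and
    are excluded from every downstream statistic.
    """

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate: float
    units: str = "raw"
    # samples invalidated by blink-pad trimming rather than by the tracker;
    # kept separate so trimming is idempotent
    artifact_pad: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t_ms)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise GazeDataError("sample arrays must have equal length")

    @property
    def n(self) -> int:
        return len(self.t_ms)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate

    def validate(self) -> None:
        if self.n == 0:
            raise GazeDataError("empty recording")
        dt = np.diff(self.t_ms)
        if self.n > 1 and np.any(dt <= 0):
            raise GazeDataError("timestamps must be strictly increasing")
        nominal = 1000.0 / self.rate
        if self.n > 1 and np.any(np.abs(dt - nominal) > 0.1 * nominal):
            raise GazeDataError(
                "inter-sample interval deviates more than 10% from 1/rate"
            )
        if self.rate < MIN_RATE_HZ:
            raise GazeDataError(
                f"sampling rate {self.rate:g} Hz below the {MIN_RATE_HZ:g} Hz minimum "
                "needed to resolve quick-phase dynamics"
            )
        v = self.valid
        if np.any(~np.isfinite(self.x[v])) or np.any(~np.isfinite(self.y[v])):
            raise GazeDataError("non-finite position at a sample flagged valid")

    def copy(self) -> "GazeRecording":
        pad = None if self.artifact_pad is None else self.artifact_pad.copy()
        return GazeRecording(
            self.t_ms.copy(), self.x.copy(), self.y.copy(),
            self.valid.copy(), self.rate, self.units, pad,
        )


@dataclass
class TargetEpoch:
    """One calibration target: true screen position (deg) and display interval."""

    x_deg: float
    y_deg: float
    start_ms: float
    end_ms: float


@dataclass
class SessionManifest:
    """Per-target truth for a calibration session.

    Defaults mirror the standard protocol: five targets shown 10 s each with
    the first 300 ms at each fixation point excluded from analysis.
    """

    targets: List[TargetEpoch]
    skip_initial_ms: float = 300.0
    dwell_ms: float = 10000.0

    def __post_init__(self) -> None:
        ivals = sorted((t.start_ms, t.end_ms) for t in self.targets)
        for (s0, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError("target intervals overlap")

    def check_fit_geometry(self) -> None:
        xs = {t.x_deg for t in self.targets}
        ys = {t.y_deg for t in self.targets}
        if len(xs) < 2 or len(ys) < 2:
            raise ValueError(
                "need >= 2 distinct horizontal and vertical target positions "
                "for a two-dimensional calibration"
            )


@dataclass
class CaptureReport:
    """Data-quality summary: fraction of valid samples and pass flag."""

    n_valid: int
    n_total: int
    capture: float
    passed: bool


def _infer_rate(t_ms: np.ndarray) -> float:
    if len(t_ms) < 2:
        raise GazeDataError("cannot infer sampling rate from fewer than 2 samples")
    dt = float(np.median(np.diff(t_ms)))
    if dt <= 0:
        raise GazeDataError("timestamps must be strictly increasing")
    return 1000.0 / dt


def read_recording(path: PathLike, format: str = "csv") -> GazeRecording:
    """Read an uncalibrated recording from ``csv`` (or TSV) or ``asc-subset``.

    Missing positions and tracker-flagged losses become ``valid=False``.
    Raises :class:`GazeDataError` on unparseable files, non-monotonic
    timestamps, or sampling rates below 200 Hz.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format in ("asc", "asc-subset"):
        return _read_asc(path)
    raise ValueError(f"unsupported format {format!r}")


def _read_csv(path: Path) -> GazeRecording:
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GazeDataError(f"unparseable file {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    missing = [c for c in ("t_ms", "x", "y") if c not in cols]
    if missing:
        raise GazeDataError(f"missing columns {missing} in {path}")
    t = pd.to_numeric(df[cols["t_ms"]], errors="coerce").to_numpy(float)
    x = pd.to_numeric(df[cols["x"]], errors="coerce").to_numpy(float)
    y = pd.to_numeric(df[cols["y"]], errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(t)):
        raise GazeDataError("non-numeric timestamp")
    if "valid" in cols:
        valid = _parse_valid(df[cols["valid"]])
    else:
        valid = np.ones(len(t), dtype=bool)
    valid &= np.isfinite(x) & np.isfinite(y)
    rec = GazeRecording(t, x, y, valid, rate=_infer_rate(t))
    rec.validate()
    return rec


def _parse_valid(col: pd.Series) -> np.ndarray:
    s = col.astype(str).str.strip().str.lower()
    return (~s.isin(("0", "false", "f", "no"))).to_numpy()


_ASC_SAMPLE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s+(\S+)\s+(\S+)\s+(\S+)")


def _read_asc(path: Path) -> GazeRecording:
    t_list: List[float] = []
    x_list: List[float] = []
    y_list: List[float] = []
    v_list: List[bool] = []
    blink_ivals: List[tuple] = []
    with open(path) as fh:
        for line in fh:
            m = _ASC_SAMPLE.match(line)
            if m:
                t_list.append(float(m.group(1)))
                xs, ys = m.group(2), m.group(3)
                ok = xs != "." and ys != "."
                x_list.append(float(xs) if ok else np.nan)
                y_list.append(float(ys) if ok else np.nan)
                v_list.append(ok)
            elif line.startswith("EBLINK"):
                parts = line.split()
                if len(parts) >= 4:
                    blink_ivals.append((float(parts[2]), float(parts[3])))
    if not t_list:
        raise GazeDataError(f"no SAMPLE lines found in {path}")
    t = np.array(t_list)
    x = np.array(x_list)
    y = np.array(y_list)
    valid = np.array(v_list)
    for s, e in blink_ivals:
        valid &= ~((t >= s) & (t <= e))
    rec = GazeRecording(t, x, y, valid, rate=_infer_rate(t))
    rec.validate()
    return rec


def write_recording(rec: GazeRecording, path: PathLike) -> None:
    """Write a recording as CSV (``t_ms,x,y,valid``); invalid samples keep
    their stored positions unless non-finite, which are written empty."""
    df = pd.DataFrame(
        {
            "t_ms": rec.t_ms,
            "x": rec.x,
            "y": rec.y,
            "valid": rec.valid.astype(int),
        }
    )
    df.to_csv(path, index=False)


def check_capture(rec: GazeRecording, threshold: float = 0.85) -> CaptureReport:
    """Fraction of valid samples; advisory pass flag at the 85% default.

    Poor capture was a participant-exclusion rule, not an algorithm gate, so
    a failing recording only triggers a warning.
    """
    if rec.n == 0:
        raise GazeDataError("empty recording")
    n_valid = int(np.count_nonzero(rec.valid))
    capture = n_valid / rec.n
    passed = capture >= threshold
    if not passed:
        warnings.warn(
            f"poor data capture: {capture:.1%} valid (< {threshold:.0%})",
            stacklevel=2,
        )
    return CaptureReport(n_valid, rec.n, capture, passed)


# --- session manifests -----------------------------------------------------

def write_manifest(manifest: SessionManifest, path: PathLike) -> None:
    doc = {
        "skip_initial_ms": manifest.skip_initial_ms,
        "dwell_ms": manifest.dwell_ms,
        "targets": [
            {
                "x_deg": t.x_deg,
                "y_deg": t.y_deg,
                "start_ms": t.start_ms,
                "end_ms": t.end_ms,
            }
            for t in manifest.targets
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path: PathLike) -> SessionManifest:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "targets" not in doc:
        raise ValueError(f"manifest {path} lacks a 'targets' list")
    targets = [
        TargetEpoch(
            float(t["x_deg"]), float(t["y_deg"]),
            float(t["start_ms"]), float(t["end_ms"]),
        )
        for t in doc["targets"]
    ]
    return SessionManifest(
        targets,
        skip_initial_ms=float(doc.get("skip_initial_ms", 300.0)),
        dwell_ms=float(doc.get("dwell_ms", 10000.0)),
    )


# --- calibration files -----------------------------------------------------

CALIBRATION_FILE_VERSION = 1


def write_calibration(model: CalibrationModel, path: PathLike) -> None:
    """Serialize a fitted calibration to structured JSON text.

    Round trips are lossless: coefficients are written with full ``repr``
    precision, and explicit zeros (e.g. a zero cross-talk term) survive.
    """
    doc = {
        "version": CALIBRATION_FILE_VERSION,
        "fitted_at": datetime.now(timezone.utc).isoformat(),
        "order": model.order,
        "terms": list(model.terms),
        "axes": {
            "x": {"coeffs": [float(c) for c in model.coef_x]},
            "y": {"coeffs": [float(c) for c in model.coef_y]},
        },
        "targets_deg": [[float(a), float(b)] for a, b in model.targets_deg],
        "residuals_deg": [float(r) for r in model.residuals_deg],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_calibration(path: PathLike) -> CalibrationModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CalibrationFileError(f"corrupt calibration file {path}: {exc}")
    if doc.get("version") != CALIBRATION_FILE_VERSION:
        raise CalibrationFileError(
            f"calibration file version {doc.get('version')!r} unsupported"
        )
    try:
        terms = list(doc["terms"])
        cx = np.array(doc["axes"]["x"]["coeffs"], dtype=float)
        cy = np.array(doc["axes"]["y"]["coeffs"], dtype=float)
        targets = np.array(doc["targets_deg"], dtype=float)
        residuals = np.array(doc["residuals_deg"], dtype=float)
        order = doc["order"]
    except KeyError as exc:
        raise CalibrationFileError(f"calibration file missing block: {exc}")
    if len(cx) != len(terms) or len(cy) != len(terms):
        raise CalibrationFileError("coefficient count does not match term list")
    return CalibrationModel(
        order=order, terms=terms, coef_x=cx, coef_y=cy,
        targets_deg=targets, residuals_deg=residuals,
    )
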