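"""Raw-units-to-degrees calibration from foveation-based points of regard.

Each axis is fitted independently by ordinary least squares against the known
target positions in degrees.  The default model is linear in both raw axes
with a cross-talk term,

    x_deg = a0 + a1*x_raw + a2*y_raw      (and likewise for y_deg),

so any affine map of the screen — per-axis gain, offset, and rotation of the
calibration field from head tilt — is recovered exactly.  A quadratic model
(adding x^2, y^2, xy) is available when at least six targets were shown.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

_TERMS = {
    "linear_xtalk": ("1", "x", "y"),
    "quadratic": ("1", "x", "y", "x^2", "y^2", "xy"),
}


class CalibrationError(ValueError):
    """Raised for degenerate designs or unusable calibration inputs."""


def _design(terms: Sequence[str], x: np.ndarray, y: np.ndarray) -> np.ndarray:
    cols = {
        "1": np.ones_like(x),
        "x": x,
        "y": y,
        "x^2": x * x,
        "y^2": y * y,
        "xy": x * y,
    }
    return np.column_stack([cols[t] for t in terms])


@dataclass
class CalibrationModel:
    """Per-axis polynomial coefficients mapping raw tracker units to degrees."""

    order: str
    terms: Sequence[str]
    coef_x: np.ndarray
    coef_y: np.ndarray
    targets_deg: np.ndarray  # (n_targets, 2)
    residuals_deg: np.ndarray  # (n_targets,) Euclidean, deg

    def predict(self, x_raw, y_raw):
        """Map raw coordinates to degrees; returns (x_deg, y_deg) arrays."""
        x_raw = np.asarray(x_raw, dtype=float)
        y_raw = np.asarray(y_raw, dtype=float)
        A = _design(self.terms, np.atleast_1d(x_raw), np.atleast_1d(y_raw))
        xd = A @ self.coef_x
        yd = A @ self.coef_y
        if np.ndim(x_raw) == 0:
            return float(xd[0]), float(yd[0])
        return xd, yd

    def with_offset(self, dx_deg: float, dy_deg: float) -> "CalibrationModel":
        """A copy translated by (dx, dy) degrees; only intercepts change."""
        cx = self.coef_x.copy()
        cy = self.coef_y.copy()
        i = list(self.terms).index("1")
        cx[i] += dx_deg
        cy[i] += dy_deg
        return replace(self, coef_x=cx, coef_y=cy)


def fit_calibration(pors, order: str = "linear_xtalk") -> CalibrationModel:
    """Fit the raw-to-degrees map from per-target points of regard.

    ``pors`` is a sequence of objects with ``x_raw``, ``y_raw``,
    ``target_x_deg``, ``target_y_deg`` attributes (or 4-tuples in that
    order).  Requires >= 3 targets for the linear cross-talk model and >= 6
    for the quadratic one; raises :class:`CalibrationError` on
    rank-deficient designs (identical points of regard, collinear targets).
    """
    if order not in _TERMS:
        raise ValueError(f"unknown model order {order!r}")
    terms = _TERMS[order]
    rows = []
    for p in pors:
        if hasattr(p, "x_raw"):
            rows.append((p.x_raw, p.y_raw, p.target_x_deg, p.target_y_deg))
        else:
            rows.append(tuple(p))
    data = np.array(rows, dtype=float)
    if data.shape[0] < len(terms):
        raise CalibrationError(
            f"{order} model needs >= {len(terms)} targets, got {data.shape[0]}"
        )
    xr, yr, xd, yd = data.T
    A = _design(terms, xr, yr)
    rank = np.linalg.matrix_rank(A)
    if rank < len(terms):
        raise CalibrationError(
            "rank-deficient calibration design (identical points of regard "
            "or collinear targets)"
        )
    coef_x, *_ = np.linalg.lstsq(A, xd, rcond=None)
    coef_y, *_ = np.linalg.lstsq(A, yd, rcond=None)
    pred_x = A @ coef_x
    pred_y = A @ coef_y
    residuals = np.hypot(pred_x - xd, pred_y - yd)
    return CalibrationModel(
        order=order,
        terms=terms,
        coef_x=coef_x,
        coef_y=coef_y,
        targets_deg=np.column_stack([xd, yd]),
        residuals_deg=residuals,
    )


def apply_calibration(model: CalibrationModel, rec):
    """Apply a fitted calibration to a recording or filtered signal.

    Returns an object of the same type with positions in degrees; the
    validity mask and timestamps are untouched.  Each output axis uses its
    own coefficient vector, i.e. the transformation is applied to the
    horizontal and vertical axes separately.
    """
    out = rec.copy()
    xd, yd = model.predict(rec.x, rec.y)
    out.x = xd
    out.y = yd
    if hasattr(out, "units"):
        out.units = "deg"
    return out


def drift_correct(model, rec, target_deg, config=None):
    """Re-anchor a calibration from a single-target fixation recording.

    Runs the foveation pipeline on ``rec``, takes the foveation-based point
    of regard, and composes a pure translation with ``model`` so that the
    POR maps exactly onto ``target_deg``.  All gain and cross-talk
    coefficients are unchanged — only the intercepts move.
    """
    from .pipeline import recording_por  # deferred: pipeline imports this module

    por_x, por_y, n_fov = recording_por(rec, config=config)
    if n_fov == 0:
        raise CalibrationError("no foveations detected in drift recording")
    pred_x, pred_y = model.predict(por_x, por_y)
    return model.with_offset(target_deg[0] - pred_x, target_deg[1] - pred_y)
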