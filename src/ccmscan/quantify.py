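"""Calibration: dilution ladder, linear-range selection, LOD, back-calculation.

Calibration standards are measured on a descending 1:2 ladder (20 uM down
to 0.08 uM, nine levels by default).  A compound's linear range is the
longest contiguous run of at least five ladder levels whose ordinary
least-squares response-vs-concentration fit reaches r^2 > 0.95; its limit
of detection is the lowest level at which the peak is still detected with
every higher level also detected (so detection is monotone from the top
of the ladder down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "CalibrationLadder",
    "CalibrationModel",
    "make_ladder",
    "fit_linear_range",
    "call_lod",
    "quantify_sample",
]


@dataclass(frozen=True)
class CalibrationLadder:
    """Geometric dilution series, top concentration downward."""

    levels: tuple[float, ...]  # exact uM, descending
    labels: tuple[float, ...]  # 2-significant-figure display labels

    def __len__(self) -> int:
        return len(self.levels)


def _snap_label(x: float) -> float:
    """Pretty a dilution label the way a bench protocol writes it.

    One decimal in [0.2, 1), two decimals below 0.2 and (to keep 1.25 and
    2.5 intact) above 1; half-up via Decimal so 0.075 -> 0.08.
    """
    places = Decimal("0.1") if 0.2 <= x < 1 else Decimal("0.01")
    return float(Decimal(repr(x)).quantize(places, rounding=ROUND_HALF_UP))


def make_ladder(
    top_uM: float = 20.0, factor: float = 2.0, floor_uM: float = 0.08
) -> CalibrationLadder:
    """Build a 1:factor dilution ladder from ``top_uM`` down to the floor.

    Levels are the exact geometric series top / factor^k; display labels
    follow the bench convention of halving the previous *label* and
    rounding it prettily (20, 10, 5, 2.5, 1.25, 0.6, 0.3, 0.15, 0.08 for
    the defaults).  The floor cut compares labels, so a printed floor of
    0.08 uM admits the exact ninth level 20 / 2^8 = 0.078125 uM.
    """
    if not (top_uM >= floor_uM > 0) or factor <= 1:
        raise ValueError("require top > floor > 0 and factor > 1")
    levels: list[float] = []
    labels: list[float] = []
    c = float(top_uM)
    label = _snap_label(c)
    while label >= floor_uM * (1 - 1e-9):
        levels.append(c)
        labels.append(label)
        c /= factor
        label = _snap_label(label / factor)
    return CalibrationLadder(tuple(levels), tuple(labels))


FitStatus = Literal["ok", "insufficient_points", "nonlinear"]


@dataclass
class CalibrationModel:
    """Per-compound calibration curve over its selected linear range."""

    entry_name: str
    polarity: str
    points: list[tuple[float, float]]  # (nominal uM, response) of detected levels
    status: FitStatus
    selected: list[tuple[float, float]] = field(default_factory=list)
    slope: float = float("nan")
    intercept: float = float("nan")
    r2: float = float("nan")
    lod_uM: float | None = None
    weighting: str = "none"

    @property
    def range_uM(self) -> tuple[float, float] | None:
        if not self.selected:
            return None
        concs = [c for c, _ in self.selected]
        return (min(concs), max(concs))


def _ols(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None):
    if weights is None:
        res = _sps.linregress(x, y)
        return res.slope, res.intercept, res.rvalue**2
    w = np.asarray(weights, float)
    sw = w.sum()
    xm, ym = (w * x).sum() / sw, (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    sxy = (w * (x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    sst = (w * (y - ym) ** 2).sum()
    r2 = 1.0 - (w * resid**2).sum() / sst if sst > 0 else float("nan")
    return slope, intercept, r2


def fit_linear_range(
    points: Sequence[tuple[float, float]],
    entry_name: str = "",
    polarity: str = "",
    min_points: int = 5,
    r2_min: float = 0.95,
    weighting: Literal["none", "1/x"] = "none",
) -> CalibrationModel:
    """Select the linear calibration range and fit it by OLS.

    ``points`` are (nominal concentration, response) for the *detected*
    ladder levels.  Among all contiguous runs of the concentration-sorted
    points with length >= ``min_points``, the longest whose unweighted OLS
    fit has r^2 strictly greater than ``r2_min`` is selected; ties go to
    the run containing the lower concentrations (noise at the bottom is
    preferable to saturation bias at the top).  Status is
    ``insufficient_points`` with fewer than ``min_points`` detections and
    ``nonlinear`` when no run passes.
    """
    pts = sorted((float(c), float(r)) for c, r in points)
    model = CalibrationModel(entry_name, polarity, pts, "insufficient_points",
                             weighting=weighting)
    if len(pts) < min_points:
        return model
    x_all = np.array([c for c, _ in pts])
    y_all = np.array([r for _, r in pts])
    best: tuple[int, int, int] | None = None  # (length, -start, start) maximize
    best_fit = None
    n = len(pts)
    for length in range(n, min_points - 1, -1):
        for start in range(0, n - length + 1):  # low concentrations first
            x = x_all[start : start + length]
            y = y_all[start : start + length]
            w = 1.0 / x if weighting == "1/x" else None
            slope, intercept, r2 = _ols(x, y, w)
            if r2 > r2_min:
                best = (length, start, start + length)
                best_fit = (slope, intercept, r2)
                break
        if best is not None:
            break
    if best is None:
        model.status = "nonlinear"
        return model
    length, start, stop = best
    model.status = "ok"
    model.selected = pts[start:stop]
    model.slope, model.intercept, model.r2 = best_fit
    return model


def call_lod(
    detections: Sequence[tuple[float, bool]],
) -> float | None:
    """Lowest continuously-detected ladder level (monotone detection rule).

    ``detections`` pairs each ladder level (uM) with whether the peak was
    detected there (status matched at the configured S/N).  Scanning from
    the top of the ladder down, the LOD is the lowest level before the
    first failure; ``None`` when even the top level is undetected —
    rendered as a dash in reports, matching the panel convention.
    """
    ordered = sorted(detections, key=lambda d: -d[0])
    lod: float | None = None
    for level, detected in ordered:
        if not detected:
            break
        lod = level
    return lod


def quantify_sample(
    area: float, model: CalibrationModel
) -> tuple[float, Literal["ok", "below_range", "above_range"]]:
    """Back-calculate a concentration from a response area.

    Returns (concentration uM, flag); the flag marks responses outside
    the selected linear range's response span.
    """
    if model.status != "ok":
        raise ValueError(f"calibration for {model.entry_name} has status {model.status}")
    if not model.slope > 0:
        raise ValueError(f"non-positive calibration slope for {model.entry_name}")
    conc = (area - model.intercept) / model.slope
    responses = [r for _, r in model.selected]
    flag: Literal["ok", "below_range", "above_range"] = "ok"
    if area < min(responses):
        flag = "below_range"
    elif area > max(responses):
        flag = "above_range"
    return conc, flag
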