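"""Stable-isotope-dilution normalization and pooled-QC diagnostics.

Every analyte response is divided by the response of its assigned U-13C
internal standard (IS) in the same sample and polarity, which cancels any
per-sample multiplicative factor (extraction volume, injection, source
drift) common to analyte and IS.  IS channels are first screened for
stable detection (coefficient of variation below 22% across samples);
pooled-QC injections interleaved through the run provide per-metabolite
precision (CV) and drift (slope vs injection order) metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .panel import Panel

__all__ = [
    "SampleMatrix",
    "ISStabilityReport",
    "peaks_to_matrix",
    "is_stability",
    "normalize",
    "qc_drift",
    "estimate_prep_factors",
]

IS_CV_THRESHOLD = 22.0  # percent; stable-detection screen for IS channels


@dataclass
class SampleMatrix:
    """Samples x metabolites response matrix with sample metadata.

    ``data``: responses (raw areas or IS ratios), NaN = missing;
    ``sample_meta``: per-sample role, group and acquisition order;
    ``column_polarity``: ionization mode each column was measured in;
    ``normalized``: whether values are IS ratios.
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame
    column_polarity: dict[str, str] = field(default_factory=dict)
    normalized: bool = False
    is_source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.sample_meta.index):
            raise ValueError("data and sample_meta must share the sample index")
        vals = self.data.to_numpy(float)
        if np.nanmin(vals, initial=0) < 0:
            raise ValueError("responses must be >= 0 or missing")

    def subset(self, role: str) -> "SampleMatrix":
        keep = self.sample_meta["role"] == role
        return SampleMatrix(
            self.data[keep], self.sample_meta[keep], self.column_polarity,
            self.normalized, self.is_source,
        )


def peaks_to_matrix(peaks: pd.DataFrame, samples: pd.DataFrame) -> SampleMatrix:
    """Pivot an extraction table (one row per sample x entry) to a matrix.

    Non-detected entries become missing.  ``samples`` is the per-sample
    metadata frame of the originating :class:`~ccmscan.ms_io.FeatureTable`.
    """
    det = peaks[peaks["status"] == "matched"]
    wide = det.pivot_table(index="sample_id", columns="entry", values="area",
                           aggfunc="first")
    wide = wide.reindex(samples.index)
    wide.columns.name = None
    pol = dict(peaks.drop_duplicates("entry").set_index("entry")["polarity"])
    return SampleMatrix(wide, samples.copy(), pol)


@dataclass
class ISStabilityReport:
    """Per-IS detection stability across samples."""

    table: pd.DataFrame  # index IS name; columns mean_area, cv_pct, passed, reason
    threshold_pct: float = IS_CV_THRESHOLD

    def passed(self, name: str) -> bool:
        return bool(self.table.loc[name, "passed"])


def is_stability(
    matrix: SampleMatrix, panel: Panel, threshold_pct: float = IS_CV_THRESHOLD
) -> ISStabilityReport:
    """Screen internal-standard channels for stable detection.

    The metric is the coefficient of variation (sample SD over mean,
    percent) of the IS area across all samples; an IS passes when its CV
    is strictly below ``threshold_pct``.  Requires >= 3 samples per IS.
    Internal standards not measured in this run (e.g. acquired in the
    other polarity) are not reported.
    """
    rows = []
    for ist in panel.internal_standards:
        if ist.name not in matrix.data.columns:
            continue
        areas = matrix.data[ist.name].dropna()
        if len(areas) < 3:
            rows.append((ist.name, np.nan, np.nan, False, "fewer than 3 samples"))
            continue
        mean = float(areas.mean())
        if mean == 0:
            rows.append((ist.name, 0.0, np.nan, False, "zero mean signal"))
            continue
        cv = float(areas.std(ddof=1) / mean * 100.0)
        rows.append((ist.name, mean, cv, cv < threshold_pct, ""))
    table = pd.DataFrame(
        rows, columns=["is_name", "mean_area", "cv_pct", "passed", "reason"]
    ).set_index("is_name")
    return ISStabilityReport(table, threshold_pct)


def normalize(
    matrix: SampleMatrix, panel: Panel, *, force: bool = False,
    stability: ISStabilityReport | None = None,
) -> SampleMatrix:
    """Divide each analyte column by its assigned IS area per sample.

    The IS is resolved through the panel assignment map in the column's
    own polarity (falling back to the nearest-RT IS when the panel has
    none).  Analytes with no IS available in their polarity pass through
    unchanged and are flagged ``unnormalizable`` in ``is_source``.  A
    missing IS area in a sample makes the analyte missing in that sample.
    Unless ``force``, IS channels failing the stability screen raise.
    """
    if stability is None:
        stability = is_stability(matrix, panel)
    out = matrix.data.copy()
    source: dict[str, str] = {}
    for col in matrix.data.columns:
        if col not in panel or panel[col].is_internal_standard:
            continue
        pol = matrix.column_polarity.get(col, "+")
        assignment = panel.is_assignment(col, pol)  # type: ignore[arg-type]
        if assignment.internal_standard is None:
            source[col] = "unnormalizable"
            continue
        is_name = assignment.internal_standard.name
        if is_name not in matrix.data.columns:
            source[col] = "unnormalizable"
            continue
        is_areas = matrix.data[is_name]
        if (is_areas.fillna(0) == 0).all():
            raise ValueError(f"internal standard {is_name} has all-zero areas")
        if is_name in stability.table.index and not stability.passed(is_name):
            if not force:
                raise ValueError(
                    f"internal standard {is_name} failed the stability screen "
                    f"({stability.table.loc[is_name, 'reason'] or 'CV over threshold'}); "
                    "pass force=True to normalize anyway"
                )
        out[col] = matrix.data[col] / is_areas.replace(0, np.nan)
        source[col] = assignment.source
    return SampleMatrix(out, matrix.sample_meta.copy(), dict(matrix.column_polarity),
                        normalized=True, is_source=source)


def qc_drift(matrix: SampleMatrix) -> pd.DataFrame:
    """Per-metabolite precision and drift over the pooled-QC injections.

    Returns a frame indexed by metabolite with ``cv_pct`` (CV across QC
    injections) and ``drift_pct_per_injection`` (OLS slope of response vs
    acquisition order, as percent of the QC mean).  Requires >= 3 QCs.
    """
    qc = matrix.subset("QC")
    if len(qc.data) < 3:
        raise ValueError(f"need >= 3 QC injections, have {len(qc.data)}")
    order = qc.sample_meta["order"].to_numpy(float)
    rows = []
    for col in qc.data.columns:
        vals = qc.data[col].to_numpy(float)
        ok = np.isfinite(vals)
        if ok.sum() < 3:
            rows.append((col, np.nan, np.nan, int(ok.sum())))
            continue
        v, o = vals[ok], order[ok]
        mean = v.mean()
        cv = float(v.std(ddof=1) / mean * 100.0) if mean > 0 else np.nan
        if np.ptp(o) > 0 and mean > 0:
            slope = _sps.linregress(o, v).slope
            drift = float(slope / mean * 100.0)
        else:
            drift = np.nan
        rows.append((col, cv, drift, int(ok.sum())))
    return pd.DataFrame(
        rows, columns=["metabolite", "cv_pct", "drift_pct_per_injection", "n_qc"]
    ).set_index("metabolite")


def estimate_prep_factors(matrix: SampleMatrix, panel: Panel) -> pd.Series:
    """Per-sample preparation scale factors from the IS channels.

    The IS is spiked at a constant nominal amount, so within one IS
    channel the ratio of a sample's area to the channel median estimates
    that sample's multiplicative preparation/injection factor; the median
    over IS channels robustifies it.  Used to put raw areas of study
    samples back on the calibration scale before back-calculation.
    """
    is_cols = [e.name for e in panel.internal_standards if e.name in matrix.data.columns]
    if not is_cols:
        raise ValueError("no internal-standard columns in matrix")
    sub = matrix.data[is_cols]
    rel = sub / sub.median(axis=0)
    return rel.median(axis=1).rename("prep_factor")
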