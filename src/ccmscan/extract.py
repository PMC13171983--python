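"""Targeted extraction: EIC construction, peak integration, isobar resolution.

For every panel entry the observed centroids falling within the accurate
mass gate (default +/- 5 ppm) and the retention-time window around the
library RT are collapsed into an extracted-ion chromatogram.  The apex is
integrated by trapezoid between the nearest flanking local minima, noise
is estimated robustly from the off-peak points (1.4826 x MAD), and
entries sharing an m/z (isomers: G6P/F6P, Leu/Ile, R5P/Xu5P) are
disambiguated — or flagged ambiguous — by retention time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .ms_io import FeatureTable
from .panel import Panel, PanelEntry

__all__ = [
    "MatchConfig",
    "EIC",
    "PeakMeasurement",
    "build_eic",
    "integrate_peak",
    "resolve_isobars",
    "extract_peaks",
]

_GAUSS_FWHM = 2.3548200450309493  # 2*sqrt(2*ln 2)


@dataclass(frozen=True)
class MatchConfig:
    """Tolerances of the targeted matching step.

    ppm_tol: accurate-mass gate, ppm (the method's +/- 5 ppm).
    rt_tol_min: half-width of the RT search window, minutes.
    snr_min: minimum apex signal-to-noise for a detection call.
    ambiguity_frac: a second apex at least this fraction of the main apex
        height (outside its boundaries) marks the peak ambiguous.
    """

    ppm_tol: float = 5.0
    rt_tol_min: float = 0.5
    snr_min: float = 3.0
    ambiguity_frac: float = 0.5

    def __post_init__(self) -> None:
        if min(self.ppm_tol, self.rt_tol_min, self.snr_min, self.ambiguity_frac) <= 0:
            raise ValueError("all MatchConfig tolerances must be positive")


@dataclass
class EIC:
    """Extracted-ion chromatogram of one entry in one sample."""

    entry_name: str
    polarity: str
    rt: np.ndarray
    intensity: np.ndarray
    mean_ppm: float = float("nan")

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.rt) > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("EIC retention times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("EIC intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.rt)


Status = Literal["matched", "not_detected", "ambiguous"]


@dataclass
class PeakMeasurement:
    """Integrated chromatographic peak of one entry in one sample."""

    entry_name: str
    sample_id: str
    polarity: str
    status: Status
    apex_rt: float = float("nan")
    area: float = 0.0
    height: float = 0.0
    snr: float = 0.0
    ppm_at_apex: float = float("nan")
    rt_delta: float = float("nan")
    boundaries: tuple[float, float] | None = None
    ambiguous_with: list[str] = field(default_factory=list)

    @property
    def detected(self) -> bool:
        return self.status == "matched"


def build_eic(
    features: FeatureTable,
    entry: PanelEntry,
    cfg: MatchConfig = MatchConfig(),
    sample_id: str | None = None,
) -> EIC:
    """Collapse matching centroids of one sample into an EIC.

    A centroid belongs to the EIC iff its ppm error against the entry's
    theoretical m/z is within ``cfg.ppm_tol`` and its RT is within
    ``cfg.rt_tol_min`` of the library RT.  Centroids sharing an RT (same
    scan) have their intensities summed.
    """
    theo = entry.mz(features.polarity)
    if theo is None:
        raise ValueError(f"{entry.name} has no theoretical m/z in {features.polarity} mode")
    d = features.data
    if sample_id is not None:
        d = d[d["sample_id"] == sample_id]
    mz = d["mz"].to_numpy(float)
    rt = d["rt_min"].to_numpy(float)
    keep = (np.abs((mz - theo) / theo) * 1e6 <= cfg.ppm_tol) & (
        np.abs(rt - entry.rt_min) <= cfg.rt_tol_min
    )
    sub = d[keep]
    if not len(sub):
        return EIC(entry.name, features.polarity, np.array([]), np.array([]))
    grouped = sub.groupby("rt_min", sort=True)["intensity"].sum()
    mean_ppm = float(((sub["mz"] - theo) / theo * 1e6).mean())
    return EIC(entry.name, features.polarity, grouped.index.to_numpy(),
               grouped.to_numpy(), mean_ppm)


def _peak_bounds(y: np.ndarray, apex: int) -> tuple[int, int]:
    """Nearest local minima flanking the apex (window edge if none)."""
    left = apex
    while left > 0 and y[left - 1] <= y[left]:
        left -= 1
    right = apex
    n = len(y)
    while right < n - 1 and y[right + 1] <= y[right]:
        right += 1
    return left, right


def _fwhm_sigma(rt: np.ndarray, y: np.ndarray, apex: int) -> float:
    """Peak width estimate from full width at half maximum."""
    half = y[apex] / 2.0
    li = apex
    while li > 0 and y[li] > half:
        li -= 1
    ri = apex
    while ri < len(y) - 1 and y[ri] > half:
        ri += 1
    fwhm = rt[ri] - rt[li]
    return fwhm / _GAUSS_FWHM if fwhm > 0 else 0.0


def integrate_peak(
    eic: EIC,
    cfg: MatchConfig = MatchConfig(),
    entry_rt: float | None = None,
    sample_id: str = "",
) -> PeakMeasurement:
    """Integrate the dominant peak of an EIC.

    Apex is the maximum-intensity point (earlier RT wins ties), boundaries
    the nearest local minima on each side (falling back to apex +/- 3
    sigma-hat from the FWHM when the trace is monotone to the window
    edge), area by trapezoid, noise 1.4826 x MAD of the off-peak points
    (all points when fewer than three lie off-peak).  The peak is
    ``ambiguous`` when a second apex outside the boundaries reaches
    ``cfg.ambiguity_frac`` of the main height.
    """
    if len(eic) == 0:
        return PeakMeasurement(eic.entry_name, sample_id, eic.polarity, "not_detected")
    rt, y = eic.rt, eic.intensity
    apex = int(np.argmax(y))  # argmax returns the first (earliest-RT) maximum
    lb, rb = _peak_bounds(y, apex)
    if lb == 0 and rb == len(y) - 1 and len(y) > 4:
        sigma = _fwhm_sigma(rt, y, apex)
        if sigma > 0:
            lb = int(np.searchsorted(rt, rt[apex] - 3 * sigma, side="left"))
            rb = int(np.searchsorted(rt, rt[apex] + 3 * sigma, side="right") - 1)
    area = float(np.trapezoid(y[lb : rb + 1], rt[lb : rb + 1])) if rb > lb else 0.0
    height = float(y[apex])
    outside = np.concatenate([y[:lb], y[rb + 1 :]])
    ref = outside if len(outside) >= 3 else y
    noise = 1.4826 * float(np.median(np.abs(ref - np.median(ref))))
    snr = height / noise if noise > 0 else (float("inf") if height > 0 else 0.0)
    status: Status = "matched" if snr >= cfg.snr_min else "not_detected"
    if status == "matched" and len(outside):
        if float(outside.max()) >= cfg.ambiguity_frac * height:
            status = "ambiguous"
    rt_delta = float(rt[apex] - entry_rt) if entry_rt is not None else float("nan")
    return PeakMeasurement(
        entry_name=eic.entry_name,
        sample_id=sample_id,
        polarity=eic.polarity,
        status=status,
        apex_rt=float(rt[apex]),
        area=area,
        height=height,
        snr=snr,
        ppm_at_apex=eic.mean_ppm,
        rt_delta=rt_delta,
        boundaries=(float(rt[lb]), float(rt[rb])),
    )


def resolve_isobars(
    entries: list[PanelEntry],
    measurements: list[PeakMeasurement],
    cfg: MatchConfig = MatchConfig(),
) -> dict[str, PeakMeasurement]:
    """Assign detected apices among entries sharing one theoretical m/z.

    Each detected apex goes to the entry whose library RT is closest.  If
    several entries' RTs fall within ``cfg.rt_tol_min`` of the same apex
    and there are fewer resolvable apices than contenders, all contenders
    are flagged ambiguous (the Leu/Ile case); distinct apices keep their
    closest entries unflagged (the G6P/F6P case).
    """
    by_name = {e.name: e for e in entries}
    out: dict[str, PeakMeasurement] = {}
    detected = [m for m in measurements if m.status in ("matched", "ambiguous")]
    for m in measurements:
        if m.status not in ("matched", "ambiguous"):
            out[m.entry_name] = m
    # distinct apex RTs among detections (within half the RT tolerance they
    # count as the same physical peak)
    apices: list[float] = []
    for m in sorted(detected, key=lambda m: m.apex_rt):
        if not apices or abs(m.apex_rt - apices[-1]) > cfg.rt_tol_min / 2:
            apices.append(m.apex_rt)
    for m in detected:
        entry = by_name[m.entry_name]
        contenders = [
            e.name
            for e in entries
            if abs(e.rt_min - m.apex_rt) <= cfg.rt_tol_min and e.name != m.entry_name
        ]
        nearest = min(entries, key=lambda e: abs(e.rt_min - m.apex_rt))
        mm = PeakMeasurement(**{**m.__dict__})
        if contenders and len(apices) < len(contenders) + 1:
            mm.status = "ambiguous"
            mm.ambiguous_with = sorted(contenders)
        elif nearest.name != m.entry_name:
            # apex belongs to the isobaric partner; this entry keeps nothing
            mm = PeakMeasurement(m.entry_name, m.sample_id, m.polarity, "not_detected")
        out[m.entry_name] = mm
    return out


def extract_peaks(
    features: FeatureTable,
    panel: Panel,
    cfg: MatchConfig = MatchConfig(),
    resolve: bool = True,
) -> pd.DataFrame:
    """Run the targeted extraction for every (sample, panel entry) pair.

    Returns a tidy DataFrame with one row per pair carrying all
    :class:`PeakMeasurement` fields.  Isobar groups (entries whose
    theoretical m/z agree within the ppm gate) are resolved per sample.
    """
    pol = features.polarity
    entries = [e for e in panel if e.mz(pol) is not None]
    # isobar grouping by theoretical m/z
    groups: list[list[PanelEntry]] = []
    for e in sorted(entries, key=lambda e: e.mz(pol)):
        if groups and abs(e.mz(pol) - groups[-1][-1].mz(pol)) / e.mz(pol) * 1e6 <= cfg.ppm_tol:
            groups[-1].append(e)
        else:
            groups.append([e])
    rows = []
    data = features.data
    for sid, sub in data.groupby("sample_id", sort=False):
        sub_ft = FeatureTable(pol, sub.reset_index(drop=True), features.samples)
        for grp in groups:
            ms = [
                integrate_peak(build_eic(sub_ft, e, cfg), cfg, e.rt_min, str(sid))
                for e in grp
            ]
            if resolve and len(grp) > 1:
                resolved = resolve_isobars(grp, ms, cfg)
                ms = [resolved[e.name] for e in grp]
            for m in ms:
                rows.append(
                    {
                        "sample_id": str(sid),
                        "entry": m.entry_name,
                        "polarity": pol,
                        "status": m.status,
                        "apex_rt": m.apex_rt,
                        "area": m.area,
                        "height": m.height,
                        "snr": m.snr,
                        "ppm_at_apex": m.ppm_at_apex,
                        "rt_delta": m.rt_delta,
                        "ambiguous_with": ";".join(m.ambiguous_with),
                    }
                )
    return pd.DataFrame(rows)
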