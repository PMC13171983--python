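"""Compound panel: data model, packaged fixture, accurate-mass search.

The panel is the targeted list the whole workflow revolves around: for
each central-carbon-metabolism compound it records identity, pathway
class, chemical formula, HILIC retention time, theoretical [M+H]+/[M-H]-
m/z, the U-13C internal standard assigned for normalization, and the
per-polarity limits of detection.  A transcription of the published
81-analyte + 10-internal-standard panel ships with the package and is
returned by :func:`load_default_panel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Literal, NamedTuple

import numpy as np
import pandas as pd

from .chem import Formula, adduct_mz, monoisotopic_mass, parse_formula, ppm_error

__all__ = [
    "PATHWAYS",
    "PanelEntry",
    "Panel",
    "PanelError",
    "ISAssignment",
    "load_panel",
    "load_default_panel",
]

Polarity = Literal["+", "-"]

#: Closed pathway vocabulary (catches typos in user-supplied panels).
PATHWAYS = frozenset(
    {
        "AA",
        "Glycolysis",
        "Energy",
        "Nucleotides",
        "PPP",
        "Redox",
        "TCA cycle",
        "1C metabolism",
        "Heme biosynthesis",
        "Sugar",
        "Other",
        "IS",
    }
)

#: Da separating [M+H]+ and [M-H]- of the same neutral: two proton masses.
PROTON_PAIR_DELTA = 2.014553

_PANEL_COLUMNS = [
    "name",
    "pathway",
    "formula",
    "rt_min",
    "is_name",
    "intracellular",
    "acs_confirmed",
    "lod_pos_uM",
    "lod_neg_uM",
    "is_internal_standard",
]

#: Rounded calibration-ladder vocabulary every fixture LOD must belong to.
LADDER_LABELS = (0.08, 0.15, 0.3, 0.6, 1.25, 2.5, 5.0, 10.0, 20.0)


class PanelError(ValueError):
    """Raised when a panel TSV fails validation; message lists offenders."""


@dataclass(frozen=True)
class PanelEntry:
    """One panel row: a metabolite or a U-13C internal standard."""

    name: str
    pathway: str
    formula: Formula
    rt_min: float
    mz_pos: float | None
    mz_neg: float | None
    is_name: str | None
    intracellular: bool
    acs_confirmed: bool
    lod_pos_uM: float | None
    lod_neg_uM: float | None
    is_internal_standard: bool

    def mz(self, polarity: Polarity) -> float | None:
        return self.mz_pos if polarity == "+" else self.mz_neg

    def lod(self, polarity: Polarity) -> float | None:
        return self.lod_pos_uM if polarity == "+" else self.lod_neg_uM


class ISAssignment(NamedTuple):
    """Resolved internal standard for one analyte in one polarity."""

    internal_standard: "PanelEntry | None"
    source: Literal["assigned", "fallback", "unnormalizable"]


class Panel:
    """Ordered collection of :class:`PanelEntry` with name and m/z indexes."""

    def __init__(self, entries: list[PanelEntry]):
        self.entries = list(entries)
        self._by_name = {e.name: e for e in self.entries}
        if len(self._by_name) != len(self.entries):
            seen: set[str] = set()
            dups = [e.name for e in self.entries if e.name in seen or seen.add(e.name)]
            raise PanelError(f"duplicate panel names: {sorted(set(dups))}")
        # per-polarity m/z index, sorted for binary search
        self._mz_index: dict[str, tuple[np.ndarray, list[PanelEntry]]] = {}
        for pol in ("+", "-"):
            pairs = [(e.mz(pol), e) for e in self.entries if e.mz(pol) is not None]
            pairs.sort(key=lambda p: p[0])
            self._mz_index[pol] = (
                np.array([p[0] for p in pairs], dtype=float),
                [p[1] for p in pairs],
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PanelEntry]:
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> PanelEntry:
        return self._by_name[name]

    @property
    def analytes(self) -> list[PanelEntry]:
        return [e for e in self.entries if not e.is_internal_standard]

    @property
    def internal_standards(self) -> list[PanelEntry]:
        return [e for e in self.entries if e.is_internal_standard]

    def candidates(
        self, polarity: Polarity, mz: float, ppm_tol: float = 5.0
    ) -> list[PanelEntry]:
        """Entries whose theoretical m/z lies within ``ppm_tol`` of ``mz``.

        Sorted by absolute ppm error (closest first); empty list when no
        panel ion matches.
        """
        if ppm_tol <= 0:
            raise ValueError("ppm_tol must be positive")
        mzs, ents = self._mz_index[polarity]
        if len(mzs) == 0:
            return []
        # |obs - theo|/theo <= tol  <=>  theo in [obs/(1+tol), obs/(1-tol)]
        tol = ppm_tol * 1e-6
        lo = np.searchsorted(mzs, mz / (1 + tol), side="left")
        hi = np.searchsorted(mzs, mz / (1 - tol), side="right")
        hits = [(abs(ppm_error(mz, mzs[i])), ents[i]) for i in range(lo, hi)]
        hits.sort(key=lambda h: (h[0], h[1].name))
        return [e for _, e in hits]

    def is_assignment(self, entry: PanelEntry | str, polarity: Polarity) -> ISAssignment:
        """Resolve the internal standard normalizing ``entry`` in ``polarity``.

        The panel-assigned IS is used when it exists and carries an ion in
        the requested polarity; otherwise the IS of the same polarity with
        the nearest retention time is substituted and flagged "fallback".
        If no IS has an ion in that polarity the analyte is unnormalizable.
        """
        if isinstance(entry, str):
            entry = self[entry]
        if entry.is_internal_standard:
            raise ValueError(f"{entry.name} is itself an internal standard")
        if entry.is_name is not None:
            ist = self._by_name.get(entry.is_name)
            if ist is not None and ist.mz(polarity) is not None:
                return ISAssignment(ist, "assigned")
        pool = [e for e in self.internal_standards if e.mz(polarity) is not None]
        if not pool:
            return ISAssignment(None, "unnormalizable")
        nearest = min(pool, key=lambda e: (abs(e.rt_min - entry.rt_min), e.name))
        return ISAssignment(nearest, "fallback")

    def to_frame(self) -> pd.DataFrame:
        """Panel as a DataFrame (one row per entry, formulas as strings)."""
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "name": e.name,
                    "pathway": e.pathway,
                    "formula": e.formula.source_text or e.formula.format(),
                    "rt_min": e.rt_min,
                    "mz_pos": e.mz_pos,
                    "mz_neg": e.mz_neg,
                    "is_name": e.is_name,
                    "intracellular": e.intracellular,
                    "acs_confirmed": e.acs_confirmed,
                    "lod_pos_uM": e.lod_pos_uM,
                    "lod_neg_uM": e.lod_neg_uM,
                    "is_internal_standard": e.is_internal_standard,
                }
            )
        return pd.DataFrame(rows)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "-", "–", "—", "nan"):
        return None
    return float(s)


def _flag(value) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return str(value).strip().lower() in ("x", "1", "true", "yes")


def load_panel(
    path, *, mass_tol_da: float = 5e-5, lint_lod_labels: bool = True
) -> Panel:
    """Load and validate a panel TSV.

    Columns: ``name pathway formula rt_min is_name intracellular
    acs_confirmed lod_pos_uM lod_neg_uM is_internal_standard`` plus
    optional ``mz_pos``/``mz_neg``.  When m/z columns are present they are
    checked against the formula-computed values (|delta| <= ``mass_tol_da``);
    when absent they are computed.  Internal standards keep only the m/z of
    the polarity they were characterized in, analytes get both by default.

    All structural invariants (unique names, resolvable IS references,
    positive RTs, pos/neg two-proton spacing, LOD vocabulary) are checked
    at load time; violations raise :class:`PanelError` naming row numbers.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        raise PanelError(f"{path}: empty panel file")
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing columns {missing}")

    problems: list[str] = []
    entries: list[PanelEntry] = []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based + header
        try:
            formula = parse_formula(row["formula"])
        except ValueError as exc:
            problems.append(f"row {rowno}: {exc}")
            continue
        rt = float(row["rt_min"])
        if rt <= 0:
            problems.append(f"row {rowno}: rt_min must be positive, got {rt}")
        neutral = monoisotopic_mass(formula)
        is_is = _flag(row.get("is_internal_standard"))
        mz_pos = _opt_float(row.get("mz_pos")) if "mz_pos" in df.columns else None
        mz_neg = _opt_float(row.get("mz_neg")) if "mz_neg" in df.columns else None
        for printed, adduct in ((mz_pos, "[M+H]+"), (mz_neg, "[M-H]-")):
            if printed is not None:
                calc = adduct_mz(neutral, adduct)
                if abs(calc - printed) > mass_tol_da:
                    problems.append(
                        f"row {rowno} ({row['name']}): stored {adduct} {printed} "
                        f"differs from formula value {calc:.5f} by "
                        f"{abs(calc - printed) * 1e3:.3f} mDa"
                    )
        if mz_pos is None and mz_neg is None:
            if is_is:
                problems.append(
                    f"row {rowno} ({row['name']}): internal standard needs an "
                    "explicit mz_pos or mz_neg (polarity of characterization)"
                )
            else:
                mz_pos = adduct_mz(neutral, "[M+H]+")
                mz_neg = adduct_mz(neutral, "[M-H]-")
        if mz_pos is not None and mz_neg is not None:
            if abs((mz_pos - mz_neg) - PROTON_PAIR_DELTA) > 1e-4:
                problems.append(
                    f"row {rowno} ({row['name']}): mz_pos - mz_neg = "
                    f"{mz_pos - mz_neg:.5f}, expected {PROTON_PAIR_DELTA}"
                )
        pathway = str(row["pathway"]).strip()
        if pathway not in PATHWAYS:
            problems.append(f"row {rowno} ({row['name']}): unknown pathway {pathway!r}")
        is_name = row.get("is_name")
        is_name = None if (not isinstance(is_name, str) or not is_name.strip()) else is_name.strip()
        lod_pos = _opt_float(row.get("lod_pos_uM"))
        lod_neg = _opt_float(row.get("lod_neg_uM"))
        if lint_lod_labels:
            for lod, col in ((lod_pos, "lod_pos_uM"), (lod_neg, "lod_neg_uM")):
                if lod is not None and not any(
                    math.isclose(lod, lab, rel_tol=1e-9) for lab in LADDER_LABELS
                ):
                    problems.append(
                        f"row {rowno} ({row['name']}): {col}={lod} is not a "
                        f"calibration-ladder label {LADDER_LABELS}"
                    )
        entries.append(
            PanelEntry(
                name=str(row["name"]).strip(),
                pathway=pathway,
                formula=formula,
                rt_min=rt,
                mz_pos=mz_pos,
                mz_neg=mz_neg,
                is_name=is_name,
                intracellular=_flag(row.get("intracellular")),
                acs_confirmed=_flag(row.get("acs_confirmed")),
                lod_pos_uM=lod_pos,
                lod_neg_uM=lod_neg,
                is_internal_standard=is_is,
            )
        )

    names = {e.name for e in entries}
    for e in entries:
        if e.is_name is not None and e.is_name not in names:
            problems.append(f"{e.name}: dangling internal-standard reference {e.is_name!r}")
    if problems:
        raise PanelError(f"{path}: panel validation failed:\n  " + "\n  ".join(problems))
    return Panel(entries)


def load_default_panel() -> Panel:
    """The packaged central-carbon-metabolism panel (81 analytes + 10 IS)."""
    ref = resources.files("ccmscan.data").joinpath("ccm_panel.tsv")
    with resources.as_file(ref) as p:
        return load_panel(p)
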