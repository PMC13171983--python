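"""LC-MS observations as a long-format centroid table, plus an mzML adapter.

The native interchange format is a plain CSV with one centroid per row
(``sample_id, role, rt_min, mz, intensity`` and optional ``nominal_uM``,
``group``, ``order`` columns), one file per polarity.  This keeps every
fixture human-readable and diff-able.  Standard centroided mzML can be
flattened into the same table through :func:`from_mzml` (pyteomics), and
:func:`write_mzml` emits a minimal one-run mzML for interoperability.
"""

from __future__ import annotations

import base64
import struct
import xml.sax.saxutils as _sax
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "read_features", "write_features", "from_mzml", "write_mzml"]

Polarity = Literal["+", "-"]

#: Full-scan acquisition window, Da; centroids outside are discarded on read.
SCAN_RANGE = (50.0, 1000.0)

ROLES = ("study", "QC", "blank", "standard")

_REQUIRED = ["sample_id", "role", "rt_min", "mz", "intensity"]
_OPTIONAL = ["nominal_uM", "group", "order"]


@dataclass
class FeatureTable:
    """Centroided LC-MS observations of one polarity.

    ``data`` holds one row per centroid; ``samples`` one row per sample_id
    with its role, acquisition order and (for calibration standards) the
    nominal concentration.
    """

    polarity: Polarity
    data: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    n_dropped_out_of_range: int = 0

    def __post_init__(self) -> None:
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        d = self.data
        for col in _REQUIRED:
            if col not in d.columns:
                raise ValueError(f"feature table missing column {col!r}")
        if len(d) and (~np.isfinite(d["intensity"]) | (d["intensity"] < 0)).any():
            raise ValueError("intensities must be finite and >= 0")
        if len(d) and (d["rt_min"] < 0).any():
            raise ValueError("retention times must be >= 0")
        if len(d) and (d["sample_id"].astype(str).str.len() == 0).any():
            raise ValueError("sample_ids must be non-empty")
        if self.samples is None:
            self.samples = self._infer_samples(d)

    @staticmethod
    def _infer_samples(d: pd.DataFrame) -> pd.DataFrame:
        if not len(d):
            return pd.DataFrame(
                columns=["sample_id", "role", "order", "nominal_uM", "group"]
            ).set_index("sample_id")
        first = d.drop_duplicates("sample_id").set_index("sample_id")
        out = pd.DataFrame(index=first.index)
        out["role"] = first["role"]
        out["order"] = (
            first["order"].astype(float) if "order" in first else range(len(first))
        )
        out["nominal_uM"] = (
            first["nominal_uM"].astype(float) if "nominal_uM" in first else np.nan
        )
        out["group"] = first["group"] if "group" in first else pd.NA
        return out

    def __len__(self) -> int:
        return len(self.data)

    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.data[self.data["sample_id"] == sample_id]


def read_features(path, polarity: Polarity) -> FeatureTable:
    """Read a long-format centroid CSV into a :class:`FeatureTable`.

    Centroids with m/z outside the 50-1000 Da acquisition window are
    dropped; the count is recorded on ``n_dropped_out_of_range``.
    Missing required columns or negative intensities are errors.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("rt_min", "mz", "intensity"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            lines = (bad[bad.isna() & df[col].notna()].index + 2).tolist()
            raise ValueError(f"{path}: malformed {col} at line(s) {lines}") from exc
    in_range = (df["mz"] >= SCAN_RANGE[0]) & (df["mz"] <= SCAN_RANGE[1])
    dropped = int((~in_range).sum())
    return FeatureTable(polarity, df[in_range].reset_index(drop=True), None, dropped)


def write_features(table: FeatureTable, path) -> None:
    """Write a :class:`FeatureTable` back to the CSV dialect (lossless)."""
    df = table.data.copy()
    cols = _REQUIRED + [c for c in _OPTIONAL if c in df.columns]
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# mzML adapter (optional; reading via pyteomics, writing minimal XML)

_NS = "{http://psi.hupo.org/ms/mzml}"

_ACC_MS1 = "MS:1000511"
_ACC_PROFILE = "MS:1000128"
_ACC_POS = "MS:1000130"
_ACC_NEG = "MS:1000129"
_ACC_RT = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _cv(elem, tag=None):
    out = {}
    for cv in elem.iter(f"{_NS}cvParam"):
        out[cv.get("accession")] = cv.attrib
    return out


def _decode_array(bda) -> np.ndarray:
    params = _cv(bda)
    raw = base64.b64decode((bda.find(f"{_NS}binary").text or "").strip())
    if _ACC_ZLIB in params:
        import zlib

        raw = zlib.decompress(raw)
    width = "f" if _ACC_F32 in params else "d"
    return np.array(struct.unpack(f"<{len(raw) // (4 if width == 'f' else 8)}{width}", raw))


def from_mzml(path, polarity: Polarity, sample_id: str = "run1",
              role: str = "study") -> FeatureTable:
    """Flatten a centroided mzML file into a single-sample feature table.

    A compact reader for PSI mzML 1.1 MS1 spectra (64/32-bit, optionally
    zlib-compressed arrays).  Scans of the other polarity are skipped;
    profile-mode spectra raise an error asking for centroiding first.
    Retention times are converted from seconds to minutes when the file
    declares seconds.
    """
    import xml.etree.ElementTree as ET

    want = _ACC_POS if polarity == "+" else _ACC_NEG
    other = _ACC_NEG if polarity == "+" else _ACC_POS
    rows: list[tuple[float, float, float]] = []
    for _event, spec in ET.iterparse(str(path)):
        if spec.tag != f"{_NS}spectrum":
            continue
        params = {cv.get("accession") for cv in spec.iter(f"{_NS}cvParam")}
        if _ACC_PROFILE in params:
            raise ValueError(f"{path}: profile-mode spectra found; centroid the data first")
        level = next(
            (cv.get("value") for cv in spec.iter(f"{_NS}cvParam")
             if cv.get("accession") == _ACC_MS1), "1",
        )
        if level != "1" or other in params:
            spec.clear()
            continue
        rt_min = 0.0
        for cv in spec.iter(f"{_NS}cvParam"):
            if cv.get("accession") == _ACC_RT:
                val = float(cv.get("value"))
                rt_min = val / 60.0 if cv.get("unitName", "second") == "second" else val
        mzs = intens = None
        for bda in spec.iter(f"{_NS}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
            if _ACC_MZ_ARRAY in accs:
                mzs = _decode_array(bda)
            elif _ACC_INT_ARRAY in accs:
                intens = _decode_array(bda)
        if mzs is not None and intens is not None:
            for mz, inten in zip(mzs, intens):
                rows.append((rt_min, float(mz), float(inten)))
        spec.clear()
    df = pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"])
    df.insert(0, "role", role)
    df.insert(0, "sample_id", sample_id)
    in_range = (df["mz"] >= SCAN_RANGE[0]) & (df["mz"] <= SCAN_RANGE[1])
    dropped = int((~in_range).sum())
    return FeatureTable(polarity, df[in_range].reset_index(drop=True), None, dropped)


def _encode(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


def write_mzml(table: FeatureTable, path) -> None:
    """Write one sample of a feature table as minimal centroided mzML.

    Centroids sharing a retention time become one spectrum.  Arrays are
    64-bit little-endian, uncompressed, base64-encoded — readable by any
    PSI-compliant parser (pyteomics round-trips it in the test suite).
    """
    pol_acc, pol_name = (
        ("MS:1000130", "positive scan") if table.polarity == "+" else ("MS:1000129", "negative scan")
    )
    d = table.data.sort_values(["rt_min", "mz"], kind="mergesort")
    spectra = []
    for idx, (rt, grp) in enumerate(d.groupby("rt_min", sort=True)):
        mzs, intens = grp["mz"].to_numpy(), grp["intensity"].to_numpy()
        spectra.append(
            f'''   <spectrum index="{idx}" id="scan={idx + 1}" defaultArrayLength="{len(mzs)}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    <cvParam cvRef="MS" accession="{pol_acc}" name="{pol_name}" value=""/>
    <scanList count="1"><scan>
     <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt * 60.0!r}" unitAccession="UO:0000010" unitName="second"/>
    </scan></scanList>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="{len(_encode(mzs))}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitAccession="MS:1000040" unitName="m/z"/>
      <binary>{_encode(mzs)}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="{len(_encode(intens))}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitAccession="MS:1000131" unitName="number of detector counts"/>
      <binary>{_encode(intens)}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>'''
        )
    body = "\n".join(spectra)
    sid = _sax.escape(str(d["sample_id"].iloc[0]) if len(d) else "empty")
    xml = f'''<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <cvList count="2">
  <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  <cv id="UO" fullName="UO" URI="http://ontologies.berkeleybop.org/uo.obo"/>
 </cvList>
 <run id="{sid}">
  <spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp1">
{body}
  </spectrumList>
 </run>
</mzML>
'''
    with open(path, "w") as fh:
        fh.write(xml)
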