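"""Chemical-formula parsing and exact monoisotopic mass arithmetic.

This is the arithmetic underneath every theoretical m/z in the compound
panel: formulas (including uniformly 13C-labelled internal standards) are
parsed into isotope-resolved element counts, summed against a fixed table
of monoisotopic isotope masses, and converted to [M+H]+ / [M-H]- m/z by
adding or subtracting one proton mass.  Only singly charged protonated /
deprotonated species are supported; the panel contains nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ADDUCTS",
    "AdductSpec",
    "Formula",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
]

# Monoisotopic masses, Da (CODATA/IUPAC).  12C is exactly 12 by definition.
MONOISOTOPIC_MASS: Mapping[str, float] = MappingProxyType(
    {
        "H": 1.00782503207,
        "C": 12.0,
        "[13C]": 13.0033548378,
        "N": 14.0030740048,
        "O": 15.9949146196,
        "P": 30.97376163,
        "S": 31.97207100,
    }
)

#: Mass of a proton, Da (mass of H minus one electron mass).
PROTON_MASS: float = 1.007276466


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula strings."""


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged adduct: name, signed mass delta (Da) and charge."""

    name: str
    mass_delta: float
    charge: int


ADDUCTS: Mapping[str, AdductSpec] = MappingProxyType(
    {
        "[M+H]+": AdductSpec("[M+H]+", +PROTON_MASS, +1),
        "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS, -1),
    }
)


@dataclass(frozen=True)
class Formula:
    """Isotope-resolved element counts of a neutral molecule.

    ``counts`` maps isotope-qualified symbols (``C``, ``[13C]``, ``H`` ...)
    to positive integers.  ``source_text`` keeps the string it was parsed
    from, purely for error messages and display.
    """

    counts: Mapping[str, int]
    source_text: str = ""

    def __post_init__(self) -> None:
        if not self.counts:
            raise FormulaError("empty formula: at least one element required")
        for sym, n in self.counts.items():
            if n < 1:
                raise FormulaError(f"count for {sym} must be >= 1, got {n}")
        object.__setattr__(self, "counts", MappingProxyType(dict(self.counts)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return Formula(merged, f"{self.source_text}+{other.source_text}")

    def format(self) -> str:
        """Canonical string: Hill-ish order with [13C] tags, e.g. [13C]6H13O9P."""
        order = ["C", "[13C]", "H"]
        rest = sorted(s for s in self.counts if s not in order)
        parts = []
        for sym in order + rest:
            if sym in self.counts:
                n = self.counts[sym]
                parts.append(f"{sym}{n if n > 1 else ''}")
        return "".join(parts)


def parse_formula(text: str) -> Formula:
    """Parse a molecular formula string into a :class:`Formula`.

    Grammar: ``(isotope-tag? element count?)+`` where an isotope tag is a
    mass number written ``[13C]``, ``^13^C`` or a bare leading ``13C``, and
    applies to the single element symbol that follows.  Unknown elements
    and zero counts are errors, reported with their position in the input.

    >>> parse_formula("C5H10N2O3").counts["C"]
    5
    >>> parse_formula("^13^C6H13O9P").counts["[13C]"]
    6
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    s = text.strip()
    counts: dict[str, int] = {}
    i = 0
    n = len(s)
    while i < n:
        start = i
        isotope = None
        # isotope tag: [13C], ^13^C, or bare digits before a letter
        if s[i] == "[":
            j = i + 1
            while j < n and s[j].isdigit():
                j += 1
            if j == i + 1:
                raise FormulaError(f"{text!r}: expected mass number at position {i}")
            isotope = s[i + 1 : j]
            i = j
            bracketed = True
        elif s[i] == "^":
            j = i + 1
            while j < n and s[j].isdigit():
                j += 1
            if j == i + 1 or j >= n or s[j] != "^":
                raise FormulaError(f"{text!r}: malformed ^mass^ tag at position {i}")
            isotope = s[i + 1 : j]
            i = j + 1
            bracketed = False
        elif s[i].isdigit():
            j = i
            while j < n and s[j].isdigit():
                j += 1
            if j >= n or not s[j].isalpha():
                raise FormulaError(
                    f"{text!r}: digits at position {i} not attached to an element"
                )
            isotope = s[i:j]
            i = j
            bracketed = False
        else:
            bracketed = False
        if i >= n or not s[i].isupper():
            raise FormulaError(f"{text!r}: expected element symbol at position {i}")
        j = i + 1
        if j < n and s[j].islower():
            j += 1
        element = s[i:j]
        i = j
        if isotope is not None and bracketed:
            if i >= n or s[i] != "]":
                raise FormulaError(f"{text!r}: unclosed isotope bracket at {start}")
            i += 1
        # count
        j = i
        while j < n and s[j].isdigit():
            j += 1
        count = int(s[i:j]) if j > i else 1
        i = j
        if count == 0:
            raise FormulaError(f"{text!r}: zero count for {element} at position {start}")
        symbol = f"[{isotope}{element}]" if isotope is not None else element
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(
                f"{text!r}: unknown element or isotope {symbol!r} at position {start}"
            )
        counts[symbol] = counts.get(symbol, 0) + count
    return Formula(counts, text)


def monoisotopic_mass(f: Formula) -> float:
    """Neutral monoisotopic mass in Da: sum of count x isotope mass."""
    return sum(MONOISOTOPIC_MASS[sym] * n for sym, n in f.counts.items())


def adduct_mz(neutral_mass: float, adduct: str | AdductSpec) -> float:
    """m/z of a singly charged adduct of a neutral of given mass.

    ``adduct`` is "[M+H]+" or "[M-H]-" (ASCII or Unicode minus accepted).
    Full precision is returned; display code rounds half-even to 5 dp.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if isinstance(adduct, str):
        key = adduct.replace("−", "-").replace("–", "-")
        if key not in ADDUCTS:
            raise KeyError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}")
        adduct = ADDUCTS[key]
    return neutral_mass + adduct.mass_delta


def formula_mz(text: str, adduct: str) -> float:
    """Convenience: parse, take monoisotopic mass, apply adduct."""
    return adduct_mz(monoisotopic_mass(parse_formula(text)), adduct)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6
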