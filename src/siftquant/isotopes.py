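"""Isotopologue distributions for product ions.

Every product ion appears in a SIFT-MS spectrum as a cluster of
isotopologues: the monoisotopic peak plus satellites at +1, +2, ... Da from
heavy-isotope substitution (13C, 18O, 34S, 37Cl, 81Br).  These satellites
matter twice over: they remove signal from the monoisotopic peak used for
quantitation, and they can land on another analyte's product ion and
interfere (e.g. the 13C isotopologue of N,N-dimethylformamide at m/z 74
under the N-nitrosodimethylamine NO+ product).

The distribution over integer mass offsets is the convolution of per-element
multinomial distributions; each element's per-atom offset distribution is
raised to its atom count by repeated convolution.
"""

from __future__ import annotations

import re
from typing import Mapping

import numpy as np
from pydantic import BaseModel, field_validator

__all__ = [
    "IsotopePattern",
    "DEFAULT_ISOTOPE_TABLE",
    "isotopologue_distribution",
    "parse_composition",
]

# Per-atom mass-offset distributions.  13C 1.1%, 18O 0.2%, 34S 4%,
# 37Cl 24.5% and 81Br (IUPAC 49.3%) are the abundances that matter for
# SIFT-MS work; H and N are treated as monoisotopic at this level of
# precision.
DEFAULT_ISOTOPE_TABLE: dict[str, dict[int, float]] = {
    "C": {0: 0.989, 1: 0.011},
    "H": {0: 1.0},
    "N": {0: 1.0},
    "O": {0: 0.998, 2: 0.002},
    "F": {0: 1.0},
    "S": {0: 0.96, 2: 0.04},
    "Cl": {0: 0.755, 2: 0.245},
    "Br": {0: 0.507, 2: 0.493},
}


class IsotopePattern(BaseModel):
    """Map from integer mass offset (Da) to signal fraction."""

    offsets: dict[int, float]

    @field_validator("offsets")
    @classmethod
    def _normalized(cls, v: dict[int, float]) -> dict[int, float]:
        if any(f < 0 for f in v.values()):
            raise ValueError("isotopologue fractions must be non-negative")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"isotopologue fractions sum to {total}, not 1")
        return v

    @property
    def monoisotopic(self) -> float:
        """Fraction of signal at the zero-offset (all-light) peak."""
        return self.offsets.get(0, 0.0)

    def fraction(self, offset: int) -> float:
        return self.offsets.get(offset, 0.0)


def _element_pattern(dist: Mapping[int, float], count: int) -> np.ndarray:
    """Offset distribution of `count` atoms of one element (multinomial)."""
    max_off = max(dist) if dist else 0
    per_atom = np.zeros(max_off + 1)
    for off, frac in dist.items():
        per_atom[off] = frac
    out = np.array([1.0])
    for _ in range(count):
        out = np.convolve(out, per_atom)
    return out


def isotopologue_distribution(
    formula: Mapping[str, int],
    isotope_table: Mapping[str, Mapping[int, float]] | None = None,
    tail_cutoff: float = 1e-12,
) -> IsotopePattern:
    """Isotopologue signal fractions of an ion with elemental composition
    ``formula`` (element -> atom count).

    Fractions below ``tail_cutoff`` are folded back into the monoisotopic
    peak so that the pattern stays exactly normalized.
    """
    table = DEFAULT_ISOTOPE_TABLE if isotope_table is None else isotope_table
    pattern = np.array([1.0])
    for element, count in formula.items():
        if count < 0:
            raise ValueError(f"negative atom count for element {element!r}")
        if count == 0:
            continue
        if element not in table:
            raise KeyError(f"element {element!r} missing from isotope table")
        dist = table[element]
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ValueError(
                f"per-atom abundances for {element!r} do not sum to 1")
        pattern = np.convolve(pattern, _element_pattern(dist, count))
    offsets = {int(i): float(f) for i, f in enumerate(pattern)
               if f > tail_cutoff}
    dropped = 1.0 - sum(offsets.values())
    offsets[0] = offsets.get(0, 0.0) + dropped
    return IsotopePattern(offsets=offsets)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")


def parse_composition(formula: str) -> dict[str, int]:
    """Parse a chemical formula string into an element -> count map.

    Supports parenthesized groups, e.g. ``"(CH3)2N2OH"``.  Trailing charge
    markers (``+``, ``-``, bullet radicals) are ignored.
    """
    s = formula.replace("+", "").replace("•", "").replace("-", "")
    stack: list[dict[str, int]] = [{}]
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "(":
            stack.append({})
            i += 1
        elif ch == ")":
            i += 1
            m = re.match(r"\d+", s[i:])
            mult = int(m.group()) if m else 1
            i += len(m.group()) if m else 0
            group = stack.pop()
            for el, n in group.items():
                stack[-1][el] = stack[-1].get(el, 0) + n * mult
        else:
            m = re.match(r"([A-Z][a-z]?)(\d*)", s[i:])
            if not m:
                raise ValueError(f"cannot parse formula {formula!r} at {s[i:]!r}")
            el, digits = m.groups()
            n = int(digits) if digits else 1
            stack[-1][el] = stack[-1].get(el, 0) + n
            i += len(m.group())
    if len(stack) != 1:
        raise ValueError(f"unbalanced parentheses in formula {formula!r}")
    return stack[0]
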