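"""Kinetics library: reagent ions, analytes and their reaction channels.

The library is the method developer's database: for each analyte it stores
the reaction channels with every reagent ion (rate coefficient k in
cm^3 s^-1, branching ratio R_b as a fraction, product ion m/z) together
with any secondary chemistry (typically water adducts) configured for each
primary product.  m/z values are signed integers: positive for cations,
negative for anions; the magnitude carries the physics and the sign routes
the ion-source mode.

The on-disk format is a versioned JSON document (schema_version "1");
`load_library`/`save_library` round-trip it exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

__all__ = [
    "ReagentIonSpec",
    "SecondaryChannelSpec",
    "ReactionChannelSpec",
    "AnalyteRecord",
    "KineticsLibrary",
    "LibraryValidationError",
    "load_library",
    "save_library",
]

SCHEMA_VERSION = "1"

# Standard atomic weights (g/mol) for the elements occurring in volatile
# analytes; used only for the MW-vs-formula consistency check.
ATOMIC_WEIGHTS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
}


class LibraryValidationError(ValueError):
    """A library record violates the schema; the message names the record."""


class ReagentIonSpec(BaseModel):
    """A reagent ion (H3O+, NO+, O2+., OH-, O-., O2-., NO2-, NO3-)."""

    label: str
    polarity: Literal[1, -1]
    mz: int
    hydrate_series: list[int] = Field(default_factory=list)
    source_mode: Literal["wet-positive", "wet-negative", "dry-negative"]

    @model_validator(mode="after")
    def _signs(self) -> "ReagentIonSpec":
        if self.mz == 0 or (1 if self.mz > 0 else -1) != self.polarity:
            raise ValueError(
                f"reagent {self.label!r}: sign of m/z {self.mz} must match "
                f"polarity {self.polarity}")
        mags = [abs(m) for m in self.hydrate_series]
        if any((1 if m > 0 else -1) != self.polarity for m in self.hydrate_series):
            raise ValueError(
                f"reagent {self.label!r}: hydrate m/z must share polarity")
        if mags != sorted(mags) or len(set(mags)) != len(mags):
            raise ValueError(
                f"reagent {self.label!r}: hydrate |m/z| must be strictly "
                "increasing")
        return self


class SecondaryChannelSpec(BaseModel):
    """A secondary product ion formed from a primary product and a
    high-concentration partner (water, CO2, excess analyte)."""

    partner_label: str
    secondary_mz: int
    note: str = ""


class ReactionChannelSpec(BaseModel):
    """One reagent-ion -> analyte reaction channel."""

    reagent_label: str
    analyte_id: str
    k: float = Field(gt=0, description="rate coefficient, cm^3 s^-1")
    product_formula: str
    product_mz: int
    Rb: float = Field(gt=0, le=1.0)
    channel_type: Literal["two-body", "association"] = "two-body"
    secondary_products: list[SecondaryChannelSpec] = Field(default_factory=list)
    #: elemental composition of the product ion (for isotopologue work)
    product_composition: Optional[dict[str, int]] = None
    #: optional per-hydrate rate coefficients, hydrate m/z -> k
    hydrate_k: dict[int, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _secondary_signs(self) -> "ReactionChannelSpec":
        for s in self.secondary_products:
            if (s.secondary_mz > 0) != (self.product_mz > 0):
                raise ValueError(
                    f"channel {self.analyte_id}/{self.reagent_label} m/z "
                    f"{self.product_mz}: secondary m/z {s.secondary_mz} has "
                    "opposite sign to its parent product")
        return self


class AnalyteRecord(BaseModel):
    """An analyte molecule and all its configured reaction channels."""

    analyte_id: str
    name: str
    formula: dict[str, int]
    MW: float = Field(gt=0, description="molecular weight, g/mol")
    polarizability: Optional[float] = Field(default=None, description="Angstrom^3")
    dipole_moment: Optional[float] = Field(default=None, description="Debye")
    channels: list[ReactionChannelSpec] = Field(default_factory=list)

    @model_validator(mode="after")
    def _consistent(self) -> "AnalyteRecord":
        try:
            mw_calc = sum(ATOMIC_WEIGHTS[el] * n for el, n in self.formula.items())
        except KeyError as exc:
            raise ValueError(
                f"analyte {self.analyte_id!r}: unknown element {exc}") from exc
        if abs(mw_calc - self.MW) > 1.0:
            raise ValueError(
                f"analyte {self.analyte_id!r}: MW {self.MW} inconsistent with "
                f"formula ({mw_calc:.2f})")
        for ch in self.channels:
            if ch.analyte_id != self.analyte_id:
                raise ValueError(
                    f"analyte {self.analyte_id!r}: channel carries "
                    f"analyte_id {ch.analyte_id!r}")
        # branching ratios per reagent must not exceed unity
        per_reagent: dict[str, float] = {}
        for ch in self.channels:
            per_reagent[ch.reagent_label] = per_reagent.get(ch.reagent_label, 0.0) + ch.Rb
        for reagent, total in per_reagent.items():
            if total > 1.0 + 1e-9:
                raise ValueError(
                    f"analyte {self.analyte_id!r}: branching ratios with "
                    f"{reagent!r} sum to {total:.4f} > 1")
        return self


class KineticsLibrary(BaseModel):
    """Validated collection of reagent ions and analytes."""

    schema_version: str = SCHEMA_VERSION
    reagent_ions: list[ReagentIonSpec] = Field(default_factory=list)
    analytes: list[AnalyteRecord] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_and_resolvable(self) -> "KineticsLibrary":
        labels = [r.label for r in self.reagent_ions]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate reagent ion labels")
        ids = [a.analyte_id for a in self.analytes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate analyte ids")
        known = set(labels)
        for a in self.analytes:
            for ch in a.channels:
                if ch.reagent_label not in known:
                    raise ValueError(
                        f"analyte {a.analyte_id!r}: channel references "
                        f"unknown reagent {ch.reagent_label!r}")
        return self

    # -- lookups -----------------------------------------------------------
    def reagent(self, label: str) -> ReagentIonSpec:
        for r in self.reagent_ions:
            if r.label == label:
                return r
        raise KeyError(f"unknown reagent ion {label!r}")

    def analyte(self, analyte_id: str) -> AnalyteRecord:
        for a in self.analytes:
            if a.analyte_id == analyte_id:
                return a
        raise KeyError(f"unknown analyte {analyte_id!r}")

    def channels_for(self, analyte_id: str,
                     reagent_label: str | None = None) -> list[ReactionChannelSpec]:
        chans = self.analyte(analyte_id).channels
        if reagent_label is None:
            return list(chans)
        return [c for c in chans if c.reagent_label == reagent_label]


def load_library(path: str | Path) -> KineticsLibrary:
    """Load and validate a kinetics library JSON file."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        return KineticsLibrary.model_validate(payload)
    except ValidationError as exc:
        raise LibraryValidationError(
            f"invalid kinetics library {path}: {exc}") from exc


def save_library(lib: KineticsLibrary, path: str | Path) -> None:
    """Write a kinetics library to a JSON file (round-trips via load)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        json.dump(lib.model_dump(mode="json"), fh, indent=1, sort_keys=True)
        fh.write("\n")
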