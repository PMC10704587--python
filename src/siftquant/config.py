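"""Method configuration: which ions to acquire and how to post-process.

A SIM method declares, per analyte, the selected primary product ions
('reagent@mz' keys), the tolerance fraction for multi-ion reporting and
any interference-correction blocks.  The on-disk format is TOML::

    tolerance = 0.2

    [units]
    flow = "torr_l_s"            # or "sccm"

    [[analyte]]
    id = "NDMA"
    ions = ["NO+@74", "H3O+@75", "O2+@74"]

    [[correction.isotopologue]]
    target = "NDMA"
    target_ion = "NO+@74"
    interferent = "DMF"
    interferent_mz = 73
    a = 0.011
    n_iso = 3

    [[correction.response_factor]]
    target = "ethylene_oxide"
    target_ion = "H3O+@45"
    interferent = "acetaldehyde"
    interferent_ion = "NO+@43"
    r = 1.0                      # omit to derive from a calibration run

    [[correction.linear_combination]]
    components = ["ethylbenzene", "xylene"]
    reagent = "O2+"
    mz_list = [91, 106]
    sum_ion = "NO+@106"
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, field_validator

from .library import KineticsLibrary
from .quantitation import DEFAULT_TOLERANCE

__all__ = [
    "AnalyteMethod",
    "IsotopologueBlock",
    "ResponseFactorBlock",
    "LinearCombinationBlock",
    "MethodConfig",
    "load_method_config",
]


def _split_ion(key: str) -> tuple[str, int]:
    reagent, _, mz = key.partition("@")
    return reagent, int(mz)


class AnalyteMethod(BaseModel):
    id: str
    ions: list[str] = Field(default_factory=list)
    isotope_accounting: bool = False

    @field_validator("ions")
    @classmethod
    def _parse(cls, v: list[str]) -> list[str]:
        for key in v:
            _split_ion(key)  # raises on malformed keys
        return v


class IsotopologueBlock(BaseModel):
    target: str
    target_ion: str
    interferent: str
    interferent_mz: int
    a: float = Field(gt=0, lt=1)
    n_iso: int = Field(ge=1)
    mode: str = "linear"


class ResponseFactorBlock(BaseModel):
    target: str
    target_ion: str
    interferent: str
    interferent_ion: str
    r: Optional[float] = Field(default=None, gt=0)


class LinearCombinationBlock(BaseModel):
    components: list[str]
    reagent: str
    mz_list: list[int]
    sum_ion: str


class _Corrections(BaseModel):
    isotopologue: list[IsotopologueBlock] = Field(default_factory=list)
    response_factor: list[ResponseFactorBlock] = Field(default_factory=list)
    linear_combination: list[LinearCombinationBlock] = Field(default_factory=list)


class _Units(BaseModel):
    flow: str = "torr_l_s"

    @field_validator("flow")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in ("torr_l_s", "sccm"):
            raise ValueError(f"unknown flow unit {v!r}")
        return v


class MethodConfig(BaseModel):
    tolerance: float = Field(gt=0, le=1.0, default=DEFAULT_TOLERANCE)
    analyte: list[AnalyteMethod] = Field(default_factory=list)
    correction: _Corrections = Field(default_factory=_Corrections)
    units: _Units = Field(default_factory=_Units)

    def validate_against(self, lib: KineticsLibrary) -> None:
        """Check every referenced analyte/ion exists in the library."""
        for am in self.analyte:
            rec = lib.analyte(am.id)  # KeyError if unknown
            known = {(c.reagent_label, c.product_mz) for c in rec.channels}
            for key in am.ions:
                if _split_ion(key) not in known:
                    raise ValueError(
                        f"method selects ion {key!r} absent from the "
                        f"library entry for {am.id!r}")
        for blk in self.correction.isotopologue:
            lib.analyte(blk.target)
            lib.analyte(blk.interferent)
        for blk in self.correction.response_factor:
            lib.analyte(blk.target)
            lib.analyte(blk.interferent)
        for blk in self.correction.linear_combination:
            for comp in blk.components:
                lib.analyte(comp)

    def method_for(self, analyte_id: str) -> Optional[AnalyteMethod]:
        for am in self.analyte:
            if am.id == analyte_id:
                return am
        return None


def load_method_config(path: str | Path) -> MethodConfig:
    with Path(path).open("rb") as fh:
        payload = tomllib.load(fh)
    return MethodConfig.model_validate(payload)
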