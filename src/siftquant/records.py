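"""Raw selected-ion-monitoring (SIM) data containers.

A :class:`ScanFrame` is one timepoint of a SIM acquisition: a set of
:class:`SIMRecord` entries (one monitored m/z each — reagent ions, their
hydrates, primary and secondary product ions) plus the instrument state
needed to turn count ratios into concentrations.

Counts are stored as non-negative floats: real acquisitions record integer
counts, but noise-free simulated frames carry exact expectations.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

from .icf import ICFCurve

__all__ = ["SIMRecord", "ScanFrame", "InstrumentState"]

Role = Literal["reagent", "hydrate", "primary", "secondary"]


class SIMRecord(BaseModel):
    """Counts accumulated at one monitored m/z over one dwell period."""

    ion_label: str
    mz: int
    counts: float = Field(ge=0)
    dwell: float = Field(gt=0, description="dwell time, s")
    role: Role
    #: for hydrate/primary/secondary records: the reagent ion they belong to
    reagent_label: Optional[str] = None
    #: for product records: the analyte the method assigns this m/z to
    analyte_id: Optional[str] = None

    @property
    def cps(self) -> float:
        return self.counts / self.dwell

    @model_validator(mode="after")
    def _roles(self) -> "SIMRecord":
        if self.role in ("hydrate", "primary", "secondary") and not self.reagent_label:
            raise ValueError(
                f"record {self.ion_label!r} (role {self.role}) must name its "
                "reagent ion")
        return self


class InstrumentState(BaseModel):
    """Instrument parameters entering the concentration calculation.

    ``t_r`` and ``icf_curve`` come from the most recent performance check;
    flows, pressure and temperature are monitored continuously and recorded
    in the raw data; the attenuation factor is the constant reagent-signal
    correction; ``makeup_dilution`` covers inlet makeup-gas dilution
    (1 = none).
    """

    t_r: float = Field(gt=0, description="reaction time, s")
    icf_curve: ICFCurve
    P_g: float = Field(gt=0, description="flow tube pressure, Torr")
    T_g: float = Field(gt=0, description="flow tube temperature, K")
    phi_c: float = Field(gt=0, description="carrier gas flow, Torr L/s")
    phi_s: float = Field(gt=0, description="sample flow, Torr L/s")
    attenuation_factor: float = Field(ge=1.0, default=1.0)
    makeup_dilution: float = Field(ge=1.0, default=1.0)


class ScanFrame(BaseModel):
    """All SIM records of one timepoint."""

    timestamp: float = 0.0
    records: list[SIMRecord] = Field(default_factory=list)
    instrument: Optional[InstrumentState] = None

    @model_validator(mode="after")
    def _reagents_present(self) -> "ScanFrame":
        reagents = {r.ion_label for r in self.records if r.role == "reagent"}
        needed = {r.reagent_label for r in self.records
                  if r.role in ("primary", "secondary", "hydrate")}
        missing = needed - reagents
        if missing:
            raise ValueError(
                f"frame lacks reagent records for {sorted(missing)}")
        return self

    # -- lookups -----------------------------------------------------------
    def find(self, mz: int, role: Role | None = None,
             reagent_label: str | None = None,
             analyte_id: str | None = None) -> Optional[SIMRecord]:
        """Most specific record at an m/z; relaxes analyte, then role."""
        def match(r: SIMRecord, use_analyte: bool, use_role: bool) -> bool:
            if r.mz != mz:
                return False
            if use_role and role is not None and r.role != role:
                return False
            if reagent_label is not None and r.role != "reagent" \
                    and r.reagent_label != reagent_label:
                return False
            if r.role == "reagent" and reagent_label is not None \
                    and r.ion_label != reagent_label:
                return False
            if use_analyte and analyte_id is not None \
                    and r.analyte_id not in (analyte_id, None):
                return False
            return True

        for use_analyte, use_role in ((True, True), (False, True), (False, False)):
            for r in self.records:
                if match(r, use_analyte, use_role):
                    return r
        return None

    def reagent_record(self, label: str) -> SIMRecord:
        for r in self.records:
            if r.role == "reagent" and r.ion_label == label:
                return r
        raise KeyError(f"no reagent record for {label!r} in frame")

    def hydrate_records(self, reagent_label: str) -> list[SIMRecord]:
        return [r for r in self.records
                if r.role == "hydrate" and r.reagent_label == reagent_label]
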