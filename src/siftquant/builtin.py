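"""Built-in fixture kinetics library and certified-standard definition.

The library carries the documented chemistries for the bundled scenarios:

* N-nitrosodimethylamine (NDMA) and its isotopologue interferent
  N,N-dimethylformamide (DMF);
* acetaldehyde and ethylene oxide (primary-ion interference pair);
* ethylbenzene and the xylenes (linear-combination deconvolution);
* ethanol (secondary water-adduct chemistry) and chlorobenzene
  (Cl isotopologue split);
* the seven certified-standard components used by the performance check.

Rate coefficients are in units of cm^3 s^-1.  Values for the standard-gas
components and the negative-ion reactions of the fluoroaromatics are
literature-typical fixture values; the tables' k values are entered as
documented.  The library serializes to the JSON schema via
:func:`siftquant.library.save_library`.
"""

from __future__ import annotations

from .calibration import LowMassReaction, StandardComponent, StandardDefinition
from .library import (AnalyteRecord, KineticsLibrary, ReactionChannelSpec,
                      ReagentIonSpec, SecondaryChannelSpec)

__all__ = ["builtin_library", "builtin_standard"]


def _ch(analyte: str, reagent: str, k: float, formula: str, mz: int, Rb: float,
        composition: dict[str, int] | None = None,
        channel_type: str = "two-body",
        secondaries: list[tuple[str, int]] | None = None,
        ) -> ReactionChannelSpec:
    return ReactionChannelSpec(
        reagent_label=reagent, analyte_id=analyte, k=k,
        product_formula=formula, product_mz=mz, Rb=Rb,
        channel_type=channel_type, product_composition=composition,
        secondary_products=[
            SecondaryChannelSpec(partner_label=p, secondary_mz=m)
            for p, m in (secondaries or [])])


def builtin_library() -> KineticsLibrary:
    """The bundled fixture library (documented chemistries + standard)."""
    reagents = [
        ReagentIonSpec(label="H3O+", polarity=1, mz=19,
                       hydrate_series=[37, 55, 73], source_mode="wet-positive"),
        ReagentIonSpec(label="NO+", polarity=1, mz=30,
                       hydrate_series=[48], source_mode="wet-positive"),
        ReagentIonSpec(label="O2+", polarity=1, mz=32,
                       hydrate_series=[], source_mode="wet-positive"),
        ReagentIonSpec(label="OH-", polarity=-1, mz=-17,
                       hydrate_series=[-35, -53], source_mode="wet-negative"),
        ReagentIonSpec(label="O2-", polarity=-1, mz=-32,
                       hydrate_series=[], source_mode="wet-negative"),
        ReagentIonSpec(label="O-", polarity=-1, mz=-16,
                       hydrate_series=[], source_mode="dry-negative"),
        ReagentIonSpec(label="NO2-", polarity=-1, mz=-46,
                       hydrate_series=[], source_mode="dry-negative"),
        ReagentIonSpec(label="NO3-", polarity=-1, mz=-62,
                       hydrate_series=[], source_mode="dry-negative"),
    ]

    analytes = [
        # --- NDMA / DMF isotopologue-interference pair -------------------
        AnalyteRecord(
            analyte_id="NDMA", name="N-nitrosodimethylamine",
            formula={"C": 2, "H": 6, "N": 2, "O": 1}, MW=74.08,
            channels=[
                _ch("NDMA", "H3O+", 4.9e-9, "(CH3)2N2OH+", 75, 1.00,
                    {"C": 2, "H": 7, "N": 2, "O": 1}),
                _ch("NDMA", "NO+", 3.8e-9, "(CH3)2N2O+", 74, 1.00,
                    {"C": 2, "H": 6, "N": 2, "O": 1}),
                _ch("NDMA", "O2+", 4.1e-9, "(CH3)2N2O+", 74, 0.95,
                    {"C": 2, "H": 6, "N": 2, "O": 1}),
                _ch("NDMA", "O2+", 4.1e-9, "(CH3)2N+", 44, 0.05,
                    {"C": 2, "H": 6, "N": 1}),
            ]),
        AnalyteRecord(
            analyte_id="DMF", name="N,N-dimethylformamide",
            formula={"C": 3, "H": 7, "N": 1, "O": 1}, MW=73.09,
            channels=[
                _ch("DMF", "H3O+", 3.3e-9, "C3H7NOH+", 74, 0.95,
                    {"C": 3, "H": 8, "N": 1, "O": 1}),
                _ch("DMF", "H3O+", 3.3e-9, "CHO+", 29, 0.05,
                    {"C": 1, "H": 1, "O": 1}),
                _ch("DMF", "NO+", 2.5e-9, "C3H7NO+", 73, 0.45,
                    {"C": 3, "H": 7, "N": 1, "O": 1}),
                _ch("DMF", "NO+", 2.5e-9, "C3H6NO+", 72, 0.45,
                    {"C": 3, "H": 6, "N": 1, "O": 1}),
                _ch("DMF", "NO+", 2.5e-9, "C3H7NO.NO+", 103, 0.10,
                    {"C": 3, "H": 7, "N": 2, "O": 2},
                    channel_type="association"),
                _ch("DMF", "O2+", 2.9e-9, "C3H7NO+", 73, 0.95,
                    {"C": 3, "H": 7, "N": 1, "O": 1}),
                _ch("DMF", "O2+", 2.9e-9, "C3H7+", 43, 0.05,
                    {"C": 3, "H": 7}),
            ]),
        # --- acetaldehyde / ethylene oxide (393 K N2 values) -------------
        AnalyteRecord(
            analyte_id="acetaldehyde", name="acetaldehyde",
            formula={"C": 2, "H": 4, "O": 1}, MW=44.05,
            polarizability=4.6, dipole_moment=2.75,
            channels=[
                _ch("acetaldehyde", "H3O+", 3.4e-9, "CH3CHOH+", 45, 1.00,
                    {"C": 2, "H": 5, "O": 1}),
                _ch("acetaldehyde", "NO+", 0.6e-9, "CH3CO+", 43, 0.94,
                    {"C": 2, "H": 3, "O": 1}),
                _ch("acetaldehyde", "NO+", 0.6e-9, "CH3CHO.NO+", 74, 0.06,
                    {"C": 2, "H": 4, "N": 1, "O": 2},
                    channel_type="association"),
                _ch("acetaldehyde", "OH-", 2.0e-9, "CH2CHO-", -43, 1.00,
                    {"C": 2, "H": 3, "O": 1}),
                _ch("acetaldehyde", "O-", 0.2e-9, "C2H3O-", -43, 0.65,
                    {"C": 2, "H": 3, "O": 1}),
                _ch("acetaldehyde", "O-", 0.2e-9, "C2HO-", -41, 0.08,
                    {"C": 2, "H": 1, "O": 1}),
                _ch("acetaldehyde", "O-", 0.2e-9, "CO2H-", -45, 0.13,
                    {"C": 1, "H": 1, "O": 2}),
                _ch("acetaldehyde", "O-", 0.2e-9, "C2H3O2-", -59, 0.14,
                    {"C": 2, "H": 3, "O": 2}),
            ]),
        AnalyteRecord(
            analyte_id="ethylene_oxide", name="ethylene oxide",
            formula={"C": 2, "H": 4, "O": 1}, MW=44.05,
            polarizability=4.4, dipole_moment=1.89,
            channels=[
                _ch("ethylene_oxide", "H3O+", 2.6e-9, "C2H4OH+", 45, 1.00,
                    {"C": 2, "H": 5, "O": 1}),
                _ch("ethylene_oxide", "NO+", 0.1e-9, "C2H4ONO+", 74, 0.97,
                    {"C": 2, "H": 4, "N": 1, "O": 2},
                    channel_type="association"),
                _ch("ethylene_oxide", "NO+", 0.1e-9, "C2H3O+", 43, 0.03,
                    {"C": 2, "H": 3, "O": 1}),
                _ch("ethylene_oxide", "OH-", 0.1e-9, "C2H3O2-", -59, 0.90,
                    {"C": 2, "H": 3, "O": 2}),
                _ch("ethylene_oxide", "OH-", 0.1e-9, "C2HO-", -41, 0.05,
                    {"C": 2, "H": 1, "O": 1}),
                _ch("ethylene_oxide", "OH-", 0.1e-9, "C2H4OH-", -45, 0.05,
                    {"C": 2, "H": 5, "O": 1}),
                _ch("ethylene_oxide", "O-", 0.07e-9, "C2HO-", -41, 0.96,
                    {"C": 2, "H": 1, "O": 1}),
                _ch("ethylene_oxide", "O-", 0.07e-9, "C2H3O-", -43, 0.04,
                    {"C": 2, "H": 3, "O": 1}),
            ]),
        # --- ethylbenzene / xylenes (linear combination) ------------------
        AnalyteRecord(
            analyte_id="ethylbenzene", name="ethylbenzene",
            formula={"C": 8, "H": 10}, MW=106.17,
            channels=[
                _ch("ethylbenzene", "H3O+", 2.4e-9, "C8H10.H+", 107, 1.00,
                    {"C": 8, "H": 11}),
                _ch("ethylbenzene", "NO+", 2.0e-9, "C8H10+", 106, 1.00,
                    {"C": 8, "H": 10}),
                _ch("ethylbenzene", "O2+", 2.0e-9, "C7H7+", 91, 0.70,
                    {"C": 7, "H": 7}),
                _ch("ethylbenzene", "O2+", 2.0e-9, "C8H10+", 106, 0.30,
                    {"C": 8, "H": 10}),
            ]),
        AnalyteRecord(
            analyte_id="xylene", name="xylenes (o-, m-, p-)",
            formula={"C": 8, "H": 10}, MW=106.17,
            channels=[
                _ch("xylene", "H3O+", 2.3e-9, "C8H10.H+", 107, 1.00,
                    {"C": 8, "H": 11}),
                _ch("xylene", "NO+", 1.9e-9, "C8H10+", 106, 1.00,
                    {"C": 8, "H": 10}),
                _ch("xylene", "O2+", 1.9e-9, "C7H7+", 91, 0.20,
                    {"C": 7, "H": 7}),
                _ch("xylene", "O2+", 1.9e-9, "C8H10+", 106, 0.80,
                    {"C": 8, "H": 10}),
            ]),
        # --- ethanol (secondary water-adduct chemistry) -------------------
        AnalyteRecord(
            analyte_id="ethanol", name="ethanol",
            formula={"C": 2, "H": 6, "O": 1}, MW=46.07,
            polarizability=5.1, dipole_moment=1.69,
            channels=[
                _ch("ethanol", "H3O+", 2.7e-9, "C2H5OH.H+", 47, 1.00,
                    {"C": 2, "H": 7, "O": 1},
                    secondaries=[("H2O", 65)]),
                _ch("ethanol", "NO+", 1.2e-9, "C2H5O+", 45, 1.00,
                    {"C": 2, "H": 5, "O": 1},
                    secondaries=[("H2O", 63)]),
            ]),
        # --- chlorobenzene (Cl isotopologue split) ------------------------
        AnalyteRecord(
            analyte_id="chlorobenzene", name="chlorobenzene",
            formula={"C": 6, "H": 5, "Cl": 1}, MW=112.56,
            channels=[
                _ch("chlorobenzene", "O2+", 1.5e-9, "C6H5Cl+", 112, 1.00,
                    {"C": 6, "H": 5, "Cl": 1}),
                _ch("chlorobenzene", "NO+", 1.4e-9, "C6H5Cl+", 112, 1.00,
                    {"C": 6, "H": 5, "Cl": 1}),
            ]),
        # --- certified-standard components --------------------------------
        AnalyteRecord(
            analyte_id="ethene", name="ethene",
            formula={"C": 2, "H": 4}, MW=28.05,
            channels=[
                _ch("ethene", "O2+", 0.68e-9, "C2H4+", 28, 1.00,
                    {"C": 2, "H": 4}),
            ]),
        AnalyteRecord(
            analyte_id="benzene", name="benzene",
            formula={"C": 6, "H": 6}, MW=78.11,
            channels=[
                _ch("benzene", "O2+", 1.6e-9, "C6H6+", 78, 1.00,
                    {"C": 6, "H": 6}),
                _ch("benzene", "H3O+", 1.9e-9, "C6H6.H+", 79, 1.00,
                    {"C": 6, "H": 7}),
            ]),
        AnalyteRecord(
            analyte_id="toluene", name="toluene",
            formula={"C": 7, "H": 8}, MW=92.14,
            channels=[
                _ch("toluene", "O2+", 1.8e-9, "C7H8+", 92, 1.00,
                    {"C": 7, "H": 8}),
                _ch("toluene", "H3O+", 2.1e-9, "C7H8.H+", 93, 1.00,
                    {"C": 7, "H": 9}),
            ]),
        AnalyteRecord(
            analyte_id="difluorobenzene", name="1,4-difluorobenzene",
            formula={"C": 6, "H": 4, "F": 2}, MW=114.09,
            channels=[
                _ch("difluorobenzene", "O2+", 1.7e-9, "C6H4F2+", 114, 1.00,
                    {"C": 6, "H": 4, "F": 2}),
            ]),
        AnalyteRecord(
            analyte_id="tetrafluorobenzene", name="1,2,4,5-tetrafluorobenzene",
            formula={"C": 6, "H": 2, "F": 4}, MW=150.07,
            channels=[
                _ch("tetrafluorobenzene", "O2+", 1.5e-9, "C6H2F4+", 150, 1.00,
                    {"C": 6, "H": 2, "F": 4}),
                _ch("tetrafluorobenzene", "OH-", 1.5e-9, "C6HF4-", -149, 1.00,
                    {"C": 6, "H": 1, "F": 4}),
            ]),
        AnalyteRecord(
            analyte_id="hexafluorobenzene", name="hexafluorobenzene",
            formula={"C": 6, "F": 6}, MW=186.05,
            channels=[
                _ch("hexafluorobenzene", "O2+", 1.2e-9, "C6F6+", 186, 1.00,
                    {"C": 6, "F": 6}),
                _ch("hexafluorobenzene", "OH-", 1.5e-9, "C6F5O-", -183, 1.00,
                    {"C": 6, "F": 5, "O": 1}),
                _ch("hexafluorobenzene", "O-", 1.3e-9, "C6F5O-", -183, 1.00,
                    {"C": 6, "F": 5, "O": 1}),
            ]),
        AnalyteRecord(
            analyte_id="octafluorotoluene", name="octafluorotoluene",
            formula={"C": 7, "F": 8}, MW=236.06,
            channels=[
                _ch("octafluorotoluene", "O2+", 1.1e-9, "C7F8+", 236, 1.00,
                    {"C": 7, "F": 8}),
                _ch("octafluorotoluene", "OH-", 1.5e-9, "C7F7O-", -235, 1.00,
                    {"C": 7, "F": 7, "O": 1}),
            ]),
    ]
    return KineticsLibrary(reagent_ions=reagents, analytes=analytes)


def builtin_standard(concentration: float = 2000.0) -> StandardDefinition:
    """The 7-component certified-standard definition the check uses.

    Components and product m/z mirror the builtin library's channels; all
    at the certified concentration (nominally 2 ppmv = 2000 ppbv).
    """
    def comp(name: str, mz: int, k: float) -> StandardComponent:
        return StandardComponent(name=name, concentration=concentration,
                                 reagent_label="O2+", product_mz=mz, k=k)

    components = [
        comp("ethene", 28, 0.68e-9),
        comp("benzene", 78, 1.6e-9),
        comp("toluene", 92, 1.8e-9),
        comp("difluorobenzene", 114, 1.7e-9),
        comp("tetrafluorobenzene", 150, 1.5e-9),
        comp("hexafluorobenzene", 186, 1.2e-9),
        comp("octafluorotoluene", 236, 1.1e-9),
    ]
    low_mass = [
        # +19 (H3O+) via benzene and toluene; both solved and averaged
        LowMassReaction(component="benzene", reagent_label="H3O+",
                        reagent_mz=19, k=1.9e-9, product_mz=79,
                        concentration=concentration),
        LowMassReaction(component="toluene", reagent_label="H3O+",
                        reagent_mz=19, k=2.1e-9, product_mz=93,
                        concentration=concentration),
        # -17 (OH-) via the three fluoroaromatics; averaged
        LowMassReaction(component="tetrafluorobenzene", reagent_label="OH-",
                        reagent_mz=-17, k=1.5e-9, product_mz=-149,
                        concentration=concentration),
        LowMassReaction(component="hexafluorobenzene", reagent_label="OH-",
                        reagent_mz=-17, k=1.5e-9, product_mz=-183,
                        concentration=concentration),
        LowMassReaction(component="octafluorotoluene", reagent_label="OH-",
                        reagent_mz=-17, k=1.5e-9, product_mz=-235,
                        concentration=concentration),
        # -16 (O-) via hexafluorobenzene
        LowMassReaction(component="hexafluorobenzene", reagent_label="O-",
                        reagent_mz=-16, k=1.3e-9, product_mz=-183,
                        concentration=concentration),
    ]
    return StandardDefinition(components=components, tr_component="ethene",
                              low_mass=low_mass)
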