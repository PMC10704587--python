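"""Automated performance check: reaction time and ICF construction.

The instrument calibrates itself against a certified multicomponent gas
standard (seven stable nonpolar gases at nominally 2 ppmv).  Two quantities
come out of the check:

* the reaction time ``t_r``, from the O2+ + ethene charge-transfer reaction
  (single product at m/z 28, transmission assumed equal to the reagent's at
  m/z 32);
* the instrument calibration function (ICF), one anchor per standard
  component from the known concentration, rate coefficient and t_r, plus
  low-mass reagent-ion anchors (+19 for H3O+, -17 for OH-, -16 for O-)
  solved from dual-reagent reactions, mirrored onto the negative side and
  linearly extrapolated to |m/z| 400.

All signal inputs are attenuation-corrected counts per second.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

from pydantic import BaseModel, Field, field_validator

from .constants import (DEFAULT_CONSTANTS, PPBV, PhysicalConstants,
                        flow_tube_density, ideal_gas_density, sample_fraction)
from .icf import MZ_MAX, ICFCurve

__all__ = [
    "StandardComponent",
    "LowMassReaction",
    "StandardDefinition",
    "PerformanceCheckResult",
    "compute_reaction_time",
    "compute_icf_anchor",
    "compute_low_mass_icf",
    "solve_reagent_icf",
    "build_icf_curve",
    "check_icf_shape",
    "run_performance_check",
]

#: reagent ions whose own ICF is 1 by definition (m/z within the plateau)
PLATEAU_REAGENTS = ("NO+", "O2+")

#: reagent-depletion ratio above which the thin-reaction-limit assumption
#: behind the product/reagent ratio equations is strained
DEPLETION_WARN = 0.25


class StandardComponent(BaseModel):
    """One certified-standard component used as an ICF anchor (or for t_r)."""

    name: str
    concentration: float = Field(gt=0, default=2000.0, description="ppbv")
    reagent_label: str
    product_mz: int
    k: float = Field(gt=0, description="cm^3 s^-1")

    @field_validator("product_mz")
    @classmethod
    def _in_range(cls, v: int) -> int:
        if abs(v) > 400:
            raise ValueError(f"product m/z {v} beyond |m/z| 400")
        return v


class LowMassReaction(BaseModel):
    """A dual-reagent reaction used to solve a low-mass reagent-ion ICF.

    The reagent's ICF (at e.g. +19, -17, -16) is the unknown; the product
    ion's ICF is interpolated from the already-anchored part of the curve.
    """

    component: str
    reagent_label: str
    reagent_mz: int
    k: float = Field(gt=0)
    product_mz: int
    concentration: float = Field(gt=0, default=2000.0)


class StandardDefinition(BaseModel):
    """The certified gas standard and the reactions the check uses."""

    components: list[StandardComponent]
    tr_component: str = "ethene"
    low_mass: list[LowMassReaction] = Field(default_factory=list)

    def component(self, name: str) -> StandardComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(f"standard has no component {name!r}")

    def anchor_components(self) -> list[StandardComponent]:
        """Components anchoring the ICF above the 28-32 plateau."""
        return [c for c in self.components if abs(c.product_mz) > 32]


class PerformanceCheckResult(BaseModel):
    t_r: float = Field(gt=0)
    icf_curve: ICFCurve
    timestamp: float = 0.0
    diagnostics: list[str] = Field(default_factory=list)


def _analyte_density(concentration_ppbv: float, P_g: float, T_g: float,
                     phi_c: float, phi_s: float,
                     constants: PhysicalConstants) -> float:
    """Flow-tube number density (cm^-3) of a sampled trace gas."""
    return (concentration_ppbv * PPBV
            * sample_fraction(phi_c, phi_s)
            * flow_tube_density(P_g, T_g, constants))


def compute_reaction_time(P28: float, R32: float, C_ethene: float, k: float,
                          P_g: float, T_g: float, phi_c: float, phi_s: float,
                          constants: PhysicalConstants = DEFAULT_CONSTANTS,
                          ) -> float:
    """Reaction time t_r (s) from the ethene product/reagent signal ratio.

    In the pseudo-first-order thin-reaction limit P28/R32 = k [C2H4] t_r,
    with the ethene flow-tube density fixed by the standard concentration,
    the flows, pressure and temperature.
    """
    if P28 <= 0:
        raise ValueError("no ethene product signal at m/z 28 (P28 <= 0)")
    if R32 <= 0:
        raise ValueError("no O2+ reagent signal at m/z 32 (R32 <= 0)")
    ratio = P28 / R32
    if ratio > DEPLETION_WARN:
        warnings.warn(
            f"P28/R32 = {ratio:.3f} > {DEPLETION_WARN}: thin-reaction-limit "
            "assumption strained", stacklevel=2)
    density = _analyte_density(C_ethene, P_g, T_g, phi_c, phi_s, constants)
    return ratio / (k * density)


def compute_icf_anchor(comp: StandardComponent, P_i: float, R_j: float,
                       t_r: float, P_g: float, T_g: float,
                       phi_c: float, phi_s: float,
                       constants: PhysicalConstants = DEFAULT_CONSTANTS,
                       ) -> float:
    """ICF anchor at a standard component's product m/z.

    Valid for NO+ or O2+ reagents, whose own ICF is 1 by definition.
    Anchors on the 28-32 plateau are forced to 1 regardless of signals.
    """
    if 28 <= abs(comp.product_mz) <= 32:
        return 1.0
    if comp.reagent_label not in PLATEAU_REAGENTS:
        raise ValueError(
            f"ICF anchors require a plateau reagent ({PLATEAU_REAGENTS}); "
            f"got {comp.reagent_label!r}")
    if R_j <= 0:
        raise ValueError(f"zero reagent signal for {comp.reagent_label!r}")
    if P_i <= 0:
        raise ValueError(f"zero product signal for component {comp.name!r}")
    density = _analyte_density(comp.concentration, P_g, T_g, phi_c, phi_s,
                               constants)
    return k_times(comp.k, density, t_r) * R_j / P_i


def k_times(k: float, density: float, t_r: float) -> float:
    """Predicted thin-limit product/reagent ratio k [M] t_r."""
    return k * density * t_r


def solve_reagent_icf(rxn: LowMassReaction, P_cps: float, R_cps: float,
                      icf_partial: ICFCurve, t_r: float,
                      P_g: float, T_g: float, phi_c: float, phi_s: float,
                      constants: PhysicalConstants = DEFAULT_CONSTANTS,
                      ) -> float:
    """Solve the anchor equation for a reagent ion's own ICF.

    Rearranged so the reagent ICF is the subject, with the (non-unity)
    product-ion ICF interpolated from the partial curve.
    """
    if P_cps <= 0 or R_cps <= 0:
        raise ValueError(
            f"missing signals for low-mass reaction {rxn.component!r} with "
            f"{rxn.reagent_label!r}")
    density = _analyte_density(rxn.concentration, P_g, T_g, phi_c, phi_s,
                               constants)
    icf_product = icf_partial.lookup(abs(rxn.product_mz))
    return P_cps * icf_product / (R_cps * k_times(rxn.k, density, t_r))


def compute_low_mass_icf(reactions: Sequence[LowMassReaction],
                         signals: dict[str, tuple[float, float]],
                         icf_partial: ICFCurve, t_r: float,
                         P_g: float, T_g: float, phi_c: float, phi_s: float,
                         constants: PhysicalConstants = DEFAULT_CONSTANTS,
                         ) -> float:
    """ICF of a low-mass reagent ion from one or more dual-reagent reactions.

    ``signals`` maps component name -> (product cps, reagent cps).  When more
    than one reaction is available (benzene and toluene for +19; three
    fluoroaromatics for -17) the individual solutions are averaged.
    """
    if not reactions:
        raise ValueError("no low-mass reactions supplied")
    values = []
    for rxn in reactions:
        if rxn.component not in signals:
            raise ValueError(
                f"missing signals for component {rxn.component!r}")
        P_cps, R_cps = signals[rxn.component]
        values.append(solve_reagent_icf(rxn, P_cps, R_cps, icf_partial, t_r,
                                        P_g, T_g, phi_c, phi_s, constants))
    return sum(values) / len(values)


def build_icf_curve(anchors: dict[int, float],
                    negative_low_mass: Optional[dict[int, float]] = None,
                    required: Optional[Sequence[int]] = None) -> ICFCurve:
    """Assemble the full two-polarity ICF curve.

    ``anchors`` are positive-side anchors (including the low-mass +19 value
    and the plateau); the value at +400 is linearly extrapolated from the
    186 and 236 anchors; the negative side mirrors every positive anchor at
    |m/z| >= 28 and adds the supplied low-mass negative anchors (-17, -16).
    """
    if required:
        missing = sorted(set(required) - set(anchors))
        if missing:
            raise ValueError(
                f"missing ICF anchors for standard product m/z {missing}")
    full = dict(anchors)
    full.setdefault(28, 1.0)
    full.setdefault(32, 1.0)
    hi = sorted(m for m in full if m > 32)
    if len(hi) < 2:
        raise ValueError("need at least two anchors above m/z 32 to "
                         "extrapolate the curve endpoint")
    a, b = (186, 236) if (186 in full and 236 in full) else tuple(hi[-2:])
    slope = (full[b] - full[a]) / (b - a)
    full[MZ_MAX] = full[a] + slope * (MZ_MAX - a)
    if full[MZ_MAX] <= 0:
        raise ValueError("extrapolated ICF at m/z 400 is non-positive")
    for mz, val in list(full.items()):
        if mz >= 28:
            full[-mz] = val
    for mz, val in (negative_low_mass or {}).items():
        if mz >= 0:
            raise ValueError("negative_low_mass keys must be negative m/z")
        full[mz] = val
    return ICFCurve(anchors=full)


def check_icf_shape(curve: ICFCurve) -> list[str]:
    """Diagnostics for an abnormally shaped ICF curve (warnings only)."""
    diags: list[str] = []
    anchors = curve.anchors
    for mz in (19, -17, -16):
        if mz in anchors and not (0.05 <= anchors[mz] <= 20.0):
            diags.append(
                f"low-mass ICF anchor at m/z {mz} = {anchors[mz]:.3g} "
                "outside 0.05-20x of the 28-32 plateau")
    for positive in (True, False):
        pts = sorted(((abs(m), v) for m, v in anchors.items()
                      if (m > 0) == positive))
        # smoothness: anchor vs the line through its neighbours
        for i in range(1, len(pts) - 1):
            (m0, v0), (m1, v1), (m2, v2) = pts[i - 1:i + 2]
            line = v0 + (v2 - v0) * (m1 - m0) / (m2 - m0)
            if line > 0 and abs(v1 - line) / line > 0.5:
                diags.append(
                    f"ICF anchor at m/z {m1 if positive else -m1} deviates "
                    f"{abs(v1 - line) / line:.0%} from its neighbours "
                    "(non-smooth curve)")
        # monotone-trend breaks at high m/z
        high = [(m, v) for m, v in pts if m >= 150]
        slopes = [v2 - v1 for (_, v1), (_, v2) in zip(high, high[1:])]
        signs = [s for s in slopes if s != 0]
        if any(s1 * s2 < 0 for s1, s2 in zip(signs, signs[1:])):
            diags.append(
                f"ICF trend reverses at high {'positive' if positive else 'negative'} m/z")
    for mz, val in anchors.items():
        if mz >= 28 and -mz in anchors and abs(anchors[-mz] - val) > 1e-9 * val:
            diags.append(f"mirrored ICF at m/z {-mz} inconsistent with +{mz}")
    return diags


def run_performance_check(frames, standard: StandardDefinition,
                          P_g: float, T_g: float, phi_c: float, phi_s: float,
                          attenuation_factor: float = 1.0,
                          constants: PhysicalConstants = DEFAULT_CONSTANTS,
                          timestamp: float = 0.0) -> PerformanceCheckResult:
    """Run the full performance check on acquired (or simulated) frames.

    ``frames`` is a sequence of :class:`~siftquant.records.ScanFrame`
    covering all source modes the standard definition requires.
    """
    diagnostics: list[str] = []

    def reagent_cps(label: str) -> float:
        for fr in frames:
            try:
                rec = fr.reagent_record(label)
            except KeyError:
                continue
            return rec.cps * attenuation_factor
        raise ValueError(f"no reagent record for {label!r} in any frame")

    def product_cps(mz: int, reagent: str, analyte: str) -> float:
        for fr in frames:
            rec = fr.find(mz, role="primary", reagent_label=reagent,
                          analyte_id=analyte)
            if rec is not None:
                return rec.cps
        raise ValueError(
            f"no product record at m/z {mz} ({analyte} via {reagent})")

    # 1. reaction time from the ethene component
    trc = standard.component(standard.tr_component)
    P28 = product_cps(trc.product_mz, trc.reagent_label, trc.name)
    R32 = reagent_cps(trc.reagent_label)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        t_r = compute_reaction_time(P28, R32, trc.concentration, trc.k,
                                    P_g, T_g, phi_c, phi_s, constants)
    diagnostics.extend(str(w.message) for w in caught)

    # 2. positive anchors from the standard components
    anchors: dict[int, float] = {28: 1.0, 32: 1.0}
    for comp in standard.anchor_components():
        P_i = product_cps(comp.product_mz, comp.reagent_label, comp.name)
        R_j = reagent_cps(comp.reagent_label)
        anchors[comp.product_mz] = compute_icf_anchor(
            comp, P_i, R_j, t_r, P_g, T_g, phi_c, phi_s, constants)
    partial = ICFCurve(anchors=anchors)

    # 3. low-mass reagent-ion anchors (+19; -17; -16), grouped by reagent m/z
    by_mz: dict[int, list[LowMassReaction]] = {}
    for rxn in standard.low_mass:
        by_mz.setdefault(rxn.reagent_mz, []).append(rxn)
    negative_low_mass: dict[int, float] = {}
    for mz, rxns in by_mz.items():
        signals = {}
        for rxn in rxns:
            P = product_cps(rxn.product_mz, rxn.reagent_label, rxn.component)
            R = reagent_cps(rxn.reagent_label)
            signals[rxn.component] = (P, R)
        value = compute_low_mass_icf(rxns, signals, partial, t_r,
                                     P_g, T_g, phi_c, phi_s, constants)
        if mz > 0:
            anchors[mz] = value
        else:
            negative_low_mass[mz] = value

    required = [c.product_mz for c in standard.anchor_components()]
    curve = build_icf_curve(anchors, negative_low_mass, required=required)

    diagnostics.extend(check_icf_shape(curve))
    ratio = (ideal_gas_density(P_g, T_g, constants)
             / flow_tube_density(P_g, T_g, constants))
    diagnostics.append(
        f"ideal-gas/instrument-convention density ratio = {ratio:.3f} "
        "(informational; the instrument-convention value is used throughout)")
    return PerformanceCheckResult(t_r=t_r, icf_curve=curve,
                                  timestamp=timestamp,
                                  diagnostics=diagnostics)
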