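"""Counts -> flow-tube number density -> sample ppbv, with multi-ion
tolerance reporting.

The concentration chain is ratio-based: for each selected primary product
ion the analyte number density in the flow tube is

    [M]_i = (ICF-corrected primary + secondary signals) / R_bi
            ---------------------------------------------------
            t_r * sum_j k_j * ICF-corrected reagent ladder signals

(the reagent ladder is the injected reagent ion plus its hydrates, each
attenuation-corrected), and the sample concentration follows from the
dilution of the sample flow in the carrier:

    C_Mi [ppbv] = [M]_i / (n_g * phi_s / (phi_c + phi_s)) * 1e9.

Several per-ion concentrations are then combined by the tolerance rule: the
ions reading within a set fraction (default 20%) above the lowest value are
averaged and the rest rejected as interfered.

Counting precision is Poisson: the standard error of a count is its square
root, propagated through the ratio.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Optional

from pydantic import BaseModel, Field

from .constants import (DEFAULT_CONSTANTS, PPBV, PhysicalConstants,
                        flow_tube_density, sample_fraction)
from .isotopes import isotopologue_distribution
from .library import AnalyteRecord, KineticsLibrary, ReactionChannelSpec
from .records import InstrumentState, ScanFrame, SIMRecord

__all__ = [
    "ConcentrationResult",
    "count_rate",
    "apply_attenuation",
    "poisson_se",
    "number_density_per_ion",
    "number_density_general",
    "to_ppbv",
    "makeup_correct",
    "tolerance_report",
    "quantify_analyte",
    "ion_key",
]

DEFAULT_TOLERANCE = 0.2


class ConcentrationResult(BaseModel):
    """Per-ion and tolerance-selected concentrations for one analyte."""

    analyte_id: str
    per_ion: dict[str, float]
    per_ion_se: dict[str, float] = Field(default_factory=dict)
    reported: float
    used_ions: list[str]
    rejected_ions: list[str] = Field(default_factory=list)
    se: float = 0.0
    tolerance: float = DEFAULT_TOLERANCE
    flags: list[str] = Field(default_factory=list)


def count_rate(counts: float, dwell: float) -> float:
    """Raw count rate (cps) = counts / dwell time.

    No multiplier dead-time correction is applied; reagent-ion attenuation
    keeps the detector in its linear range.
    """
    if dwell <= 0:
        raise ValueError("dwell time must be positive")
    return counts / dwell


def apply_attenuation(cps: float, factor: float, role: str = "reagent") -> float:
    """Undo the constant reagent-ion attenuation (reagents and hydrates only)."""
    if factor < 1.0:
        raise ValueError("attenuation factor must be >= 1")
    if role not in ("reagent", "hydrate"):
        raise ValueError(
            f"attenuation applies to reagent/hydrate signals, not {role!r}")
    return cps * factor


def poisson_se(counts: float) -> float:
    """Standard error of an ion count (Poisson): sqrt(counts)."""
    if counts < 0:
        raise ValueError("counts must be non-negative")
    return math.sqrt(counts)


def ion_key(channel: ReactionChannelSpec) -> str:
    """Stable identifier of a product-ion measurement, 'reagent@mz'."""
    return f"{channel.reagent_label}@{channel.product_mz}"


def _reagent_ladder(frame: ScanFrame, channel: ReactionChannelSpec,
                    lib: KineticsLibrary, state: InstrumentState,
                    ) -> tuple[float, float]:
    """ICF- and k-weighted reagent + hydrate sum and its Poisson variance."""
    reagent = lib.reagent(channel.reagent_label)
    rec = frame.reagent_record(reagent.label)
    icf = state.icf_curve
    total = 0.0
    var = 0.0

    def add(r: SIMRecord, k_j: float) -> None:
        nonlocal total, var
        w = k_j * icf.lookup(r.mz) * state.attenuation_factor
        total += w * r.cps
        var += (w / r.dwell) ** 2 * r.counts

    add(rec, channel.k)
    base_cps = rec.cps * state.attenuation_factor
    if base_cps <= 0:
        raise ValueError(
            f"attenuation-corrected reagent signal for {reagent.label!r} "
            "is not positive")
    for h in frame.hydrate_records(reagent.label):
        add(h, channel.hydrate_k.get(h.mz, channel.k))
    return total, var


def _product_sum(frame: ScanFrame, channel: ReactionChannelSpec,
                 state: InstrumentState) -> tuple[float, float]:
    """ICF-corrected primary + configured secondary signal and variance."""
    icf = state.icf_curve
    rec = frame.find(channel.product_mz, role="primary",
                     reagent_label=channel.reagent_label,
                     analyte_id=channel.analyte_id)
    if rec is None:
        raise ValueError(
            f"frame has no primary record at m/z {channel.product_mz} for "
            f"{channel.analyte_id} via {channel.reagent_label}")
    w = icf.lookup(rec.mz)
    total = w * rec.cps
    var = (w / rec.dwell) ** 2 * rec.counts
    for s in channel.secondary_products:
        srec = frame.find(s.secondary_mz, role="secondary",
                          reagent_label=channel.reagent_label,
                          analyte_id=channel.analyte_id)
        if srec is None:
            warnings.warn(
                f"configured secondary ion m/z {s.secondary_mz} for "
                f"{channel.analyte_id} via {channel.reagent_label} is "
                "missing from the frame: a false low reading will be "
                "calculated", stacklevel=3)
            continue
        sw = icf.lookup(srec.mz)
        total += sw * srec.cps
        var += (sw / srec.dwell) ** 2 * srec.counts
    return total, var


def number_density_per_ion(frame: ScanFrame, channel: ReactionChannelSpec,
                           lib: KineticsLibrary, state: InstrumentState,
                           isotope_fraction: float = 1.0,
                           with_se: bool = False):
    """Analyte number density [M]_i (cm^-3) from one primary product ion.

    ``isotope_fraction`` is the monoisotopic signal fraction of the product
    ion when isotopologue accounting is enabled (1 otherwise); it scales the
    branching ratio, correcting for signal lost to satellites.
    """
    if not (0.0 < isotope_fraction <= 1.0):
        raise ValueError("isotope_fraction must be in (0, 1]")
    num, num_var = _product_sum(frame, channel, state)
    eff = channel.Rb * isotope_fraction
    den, den_var = _reagent_ladder(frame, channel, lib, state)
    density = (num / eff) / (state.t_r * den)
    if not with_se:
        return density
    if num > 0:
        rel_var = num_var / num ** 2 + den_var / den ** 2
        se = density * math.sqrt(rel_var)
    else:
        # zero product counts: SE from one count over the same dwell
        rec = frame.find(channel.product_mz, role="primary",
                         reagent_label=channel.reagent_label)
        unit = (state.icf_curve.lookup(channel.product_mz) / rec.dwell
                / eff / (state.t_r * den))
        se = unit
    return density, se


def number_density_general(frame: ScanFrame, analyte: AnalyteRecord,
                           lib: KineticsLibrary, state: InstrumentState,
                           reagent_label: str,
                           isotope_fractions: Optional[Mapping[str, float]] = None,
                           ) -> float:
    """Analyte number density [M] (cm^-3) combining all primary product ions
    of one reagent ion (the general multi-channel equation).

    Reduces to :func:`number_density_per_ion` for a single channel, and to
    the simple single-reaction form when additionally Rb = 1.
    """
    channels = [c for c in analyte.channels if c.reagent_label == reagent_label]
    if not channels:
        raise ValueError(
            f"analyte {analyte.analyte_id!r} has no channels with "
            f"{reagent_label!r}")
    iso = isotope_fractions or {}
    num = 0.0
    eff = 0.0
    for ch in channels:
        total, _ = _product_sum(frame, ch, state)
        num += total
        eff += ch.Rb * iso.get(ion_key(ch), 1.0)
    den, _ = _reagent_ladder(frame, channels[0], lib, state)
    return (num / eff) / (state.t_r * den)


def to_ppbv(M_density: float, state: InstrumentState,
            constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a flow-tube number density to a sample concentration (ppbv),
    undoing the dilution of the sample flow in the carrier gas."""
    frac = sample_fraction(state.phi_c, state.phi_s)
    n_g = flow_tube_density(state.P_g, state.T_g, constants)
    return M_density / (n_g * frac) / PPBV


def makeup_correct(ppbv: float, state: InstrumentState) -> float:
    """Apply the makeup-gas dilution correction (a final multiplication)."""
    return ppbv * state.makeup_dilution


def tolerance_report(per_ion: Mapping[str, float],
                     tolerance: float = DEFAULT_TOLERANCE,
                     ) -> tuple[float, list[str], list[str]]:
    """Average the per-ion concentrations within ``tolerance`` of the lowest.

    Returns (reported, used ions, rejected ions).  The comparison is
    inclusive: values equal to min * (1 + tolerance) are kept.
    """
    if not per_ion:
        raise ValueError("tolerance report needs at least one per-ion value")
    if not (0.0 < tolerance <= 1.0):
        raise ValueError("tolerance must be in (0, 1]")
    m = min(per_ion.values())
    cut = m * (1.0 + tolerance)
    used = [k for k, v in per_ion.items() if v <= cut or v == m]
    rejected = [k for k in per_ion if k not in used]
    reported = sum(per_ion[k] for k in used) / len(used)
    return reported, used, rejected


def quantify_analyte(frame: ScanFrame, analyte_id: str, lib: KineticsLibrary,
                     state: InstrumentState,
                     ions: Optional[list[str]] = None,
                     tolerance: float = DEFAULT_TOLERANCE,
                     isotope_accounting: bool = False,
                     apply_makeup: bool = True,
                     constants: PhysicalConstants = DEFAULT_CONSTANTS,
                     ) -> ConcentrationResult:
    """Full per-frame quantitation of one analyte.

    ``ions`` restricts the channels to the listed 'reagent@mz' keys (the SIM
    method's selection); by default every library channel present in the
    frame is used.
    """
    analyte = lib.analyte(analyte_id)
    per_ion: dict[str, float] = {}
    per_ion_se: dict[str, float] = {}
    flags: list[str] = []
    for ch in analyte.channels:
        key = ion_key(ch)
        if ions is not None and key not in ions:
            continue
        if frame.find(ch.product_mz, role="primary",
                      reagent_label=ch.reagent_label) is None:
            continue
        iso = 1.0
        if isotope_accounting and ch.product_composition:
            iso = isotopologue_distribution(ch.product_composition).monoisotopic
        density, dse = number_density_per_ion(frame, ch, lib, state,
                                              isotope_fraction=iso,
                                              with_se=True)
        ppbv = to_ppbv(density, state, constants)
        se = to_ppbv(dse, state, constants)
        if apply_makeup:
            ppbv = makeup_correct(ppbv, state)
            se = makeup_correct(se, state)
        per_ion[key] = ppbv
        per_ion_se[key] = se
    if not per_ion:
        raise ValueError(
            f"no selected product ions of {analyte_id!r} found in frame")
    reported, used, rejected = tolerance_report(per_ion, tolerance)
    if rejected:
        flags.append("inspect individual ions: per-ion spread exceeds "
                     f"tolerance ({len(rejected)} ion(s) rejected)")
    se = math.sqrt(sum(per_ion_se[k] ** 2 for k in used)) / len(used)
    return ConcentrationResult(
        analyte_id=analyte_id, per_ion=per_ion, per_ion_se=per_ion_se,
        reported=reported, used_ions=used, rejected_ions=rejected,
        se=se, tolerance=tolerance, flags=flags)
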