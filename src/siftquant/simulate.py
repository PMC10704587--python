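"""Forward signal simulator: the test harness for the whole pipeline.

Generates SIM frames from true sample concentrations, a kinetics library
and an injected instrument truth (reaction time, transmission curve,
reagent levels, flows).  The simulator works at the signal level — the
exact algebraic inverse of the concentration equations — so that noise-free
quantitation of a simulated frame returns the injected truth to machine
precision.  The flow-tube transport physics (exponential reagent decay with
diffusion loss, thin-limit product growth) is exposed separately as
standalone operations for testing; the real instrument folds transport into
the empirical ICF in just the same way.

Counting noise is Poisson over the dwell time, seeded and reproducible.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .constants import (DEFAULT_CONSTANTS, PPBV, PhysicalConstants,
                        flow_tube_density, sample_fraction)
from .icf import ICFCurve
from .isotopes import isotopologue_distribution
from .library import KineticsLibrary
from .calibration import StandardDefinition
from .records import InstrumentState, ScanFrame, SIMRecord

__all__ = [
    "SimulationTruth",
    "DiffusionParams",
    "simulate_frame",
    "simulate_performance_check",
    "reagent_decay",
    "product_signal_thin_limit",
    "instrument_state_from_truth",
]

#: default split of a channel's product signal kept on the primary ion when
#: secondary chemistry is configured but no explicit split is given
DEFAULT_PRIMARY_SPLIT = 0.8

DEPLETION_WARN = 0.25


class DiffusionParams(BaseModel):
    """Diffusion-loss parameters for the flow-tube transport operations."""

    D_R: float = Field(gt=0, description="reagent ion diffusion coefficient")
    Lambda: float = Field(gt=0, description="characteristic diffusion length")
    D_e: float = Field(ge=1.0, default=1.0,
                       description="differential diffusion enhancement")


class SimulationTruth(BaseModel):
    """Everything the simulator needs; the quantities a round trip recovers.

    ``g`` is the transmission truth behind the ICF, as a curve over signed
    m/z with g == 1 on the 28-32 plateau by convention: recorded signals are
    physical signals divided by g(m/z), so a perfect calibration recovers
    g at every anchor.
    """

    true_concentrations: dict[str, float] = Field(default_factory=dict)
    t_r_true: float = Field(gt=0)
    g: ICFCurve
    reagent_base_cps: dict[str, float]
    P_g: float = Field(gt=0)
    T_g: float = Field(gt=0)
    phi_c: float = Field(gt=0)
    phi_s: float = Field(gt=0)
    attenuation_factor: float = Field(ge=1.0, default=1.0)
    makeup_dilution: float = Field(ge=1.0, default=1.0)
    seed: int
    #: per-channel primary share when secondaries exist, keyed 'analyte/reagent@mz'
    secondary_splits: dict[str, float] = Field(default_factory=dict)
    #: hydrate ladder as fixed fractions of the reagent signal, per reagent
    hydrate_fractions: dict[str, dict[int, float]] = Field(default_factory=dict)


def instrument_state_from_truth(truth: SimulationTruth,
                                icf_curve: Optional[ICFCurve] = None,
                                t_r: Optional[float] = None) -> InstrumentState:
    """Build the instrument state a perfectly calibrated analysis would use."""
    return InstrumentState(
        t_r=truth.t_r_true if t_r is None else t_r,
        icf_curve=truth.g if icf_curve is None else icf_curve,
        P_g=truth.P_g, T_g=truth.T_g, phi_c=truth.phi_c, phi_s=truth.phi_s,
        attenuation_factor=truth.attenuation_factor,
        makeup_dilution=truth.makeup_dilution)


def reagent_decay(R0: float, t: float, k: float, M_density: float,
                  diffusion: Optional[DiffusionParams] = None) -> float:
    """Reagent ion abundance after time t: exponential decay under reaction
    plus (optionally) diffusion loss to the flow-tube walls."""
    if t < 0:
        raise ValueError("time must be non-negative")
    rate = k * M_density
    if diffusion is not None:
        rate += diffusion.D_R / diffusion.Lambda ** 2
    return R0 * math.exp(-rate * t)


def product_signal_thin_limit(R0: float, k: float, M_density: float,
                              t: float, D_e: float = 1.0) -> float:
    """Product abundance in the thin-reaction limit, P = R0 k [M] t * D_e.

    D_e >= 1 is the differential diffusion enhancement (smaller reagent ions
    diffuse to the walls faster than larger product ions); D_e = 1 recovers
    the simple pseudo-first-order expression.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if D_e < 1.0:
        raise ValueError("D_e must be >= 1")
    return R0 * k * M_density * t * D_e


def _poissonize(expect_cps: float, dwell: float, noise: bool,
                rng: np.random.Generator) -> float:
    lam = expect_cps * dwell
    if not noise:
        return lam
    return float(rng.poisson(lam))


def simulate_frame(truth: SimulationTruth, lib: KineticsLibrary,
                   analytes: Sequence[str], noise: bool = False,
                   isotopes: bool = False,
                   reagents: Optional[Sequence[str]] = None,
                   dwell_reagent: float = 0.06, dwell_product: float = 0.1,
                   deplete: bool = False,
                   constants: PhysicalConstants = DEFAULT_CONSTANTS,
                   rng: Optional[np.random.Generator] = None,
                   timestamp: float = 0.0) -> ScanFrame:
    """Simulate one SIM frame for the given analytes.

    Product expectations are R_rec * (sum_j k_j R_j) * [M] * t_r partitioned
    by branching ratio, the configured secondary splits and (optionally) the
    isotopologue pattern of each product ion; recorded signals are divided
    by the transmission truth g(m/z), and reagent-side signals additionally
    by the attenuation factor.  ``deplete=True`` additionally scales the
    recorded reagent ladder by the exponential conversion factor (for
    overload scenarios).
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    n_g = flow_tube_density(truth.P_g, truth.T_g, constants)
    frac = sample_fraction(truth.phi_c, truth.phi_s)
    densities = {}
    for a in analytes:
        if a not in truth.true_concentrations:
            raise KeyError(f"no true concentration for analyte {a!r}")
        densities[a] = (truth.true_concentrations[a] * PPBV
                        / truth.makeup_dilution * frac * n_g)

    # channels grouped by reagent
    by_reagent: dict[str, list] = {}
    for a in analytes:
        for ch in lib.analyte(a).channels:
            if reagents is not None and ch.reagent_label not in reagents:
                continue
            by_reagent.setdefault(ch.reagent_label, []).append(ch)

    records: list[SIMRecord] = []
    # accumulated physical product cps keyed by (reagent, mz)
    product_phys: dict[tuple[str, int], dict] = {}

    for reagent_label, channels in by_reagent.items():
        reagent = lib.reagent(reagent_label)
        if reagent_label not in truth.reagent_base_cps:
            raise KeyError(f"no reagent base cps for {reagent_label!r}")
        R0 = truth.reagent_base_cps[reagent_label]
        # conversion fraction for the pseudo-first-order regime check
        conv = 0.0
        for a in {c.analyte_id for c in channels}:
            k_max = max(c.k for c in channels if c.analyte_id == a)
            conv += k_max * densities[a] * truth.t_r_true
        if conv > 1.0:
            raise ValueError(
                f"nonphysical regime: reagent conversion {conv:.2f} > 1 "
                f"for {reagent_label!r}")
        if conv > DEPLETION_WARN:
            warnings.warn(
                f"reagent conversion {conv:.2f} > {DEPLETION_WARN} for "
                f"{reagent_label!r}: pseudo-first-order regime strained",
                stacklevel=2)
        R_rec = R0 * math.exp(-conv) if deplete else R0

        hyd = truth.hydrate_fractions.get(reagent_label, {})
        ladder = {reagent.mz: R_rec}
        for hm, f in hyd.items():
            if hm not in reagent.hydrate_series:
                raise ValueError(
                    f"hydrate m/z {hm} not in {reagent_label!r} series")
            ladder[hm] = f * R_rec

        # reagent + hydrate records (transmission and attenuation applied)
        meas = (R_rec / truth.g.lookup(reagent.mz)
                / truth.attenuation_factor)
        records.append(SIMRecord(
            ion_label=reagent_label, mz=reagent.mz,
            counts=_poissonize(meas, dwell_reagent, noise, rng),
            dwell=dwell_reagent, role="reagent"))
        for hm, phys in ladder.items():
            if hm == reagent.mz:
                continue
            meas = phys / truth.g.lookup(hm) / truth.attenuation_factor
            records.append(SIMRecord(
                ion_label=f"{reagent_label}.H2O@{hm}", mz=hm,
                counts=_poissonize(meas, dwell_reagent, noise, rng),
                dwell=dwell_reagent, role="hydrate",
                reagent_label=reagent_label))

        for ch in channels:
            ladder_sum = sum(
                ch.hydrate_k.get(mz, ch.k) * phys
                for mz, phys in ladder.items())
            P_total = (densities[ch.analyte_id] * truth.t_r_true
                       * ch.Rb * ladder_sum)
            key = f"{ch.analyte_id}/{ch.reagent_label}@{ch.product_mz}"
            if ch.secondary_products:
                split = truth.secondary_splits.get(key, DEFAULT_PRIMARY_SPLIT)
                shares = [(ch.product_mz, "primary", P_total * split)]
                rest = P_total * (1.0 - split) / len(ch.secondary_products)
                shares += [(s.secondary_mz, "secondary", rest)
                           for s in ch.secondary_products]
            else:
                shares = [(ch.product_mz, "primary", P_total)]
            for mz, role, phys in shares:
                contributions = [(mz, phys)]
                if isotopes and ch.product_composition:
                    pattern = isotopologue_distribution(ch.product_composition)
                    sign = 1 if mz > 0 else -1
                    contributions = [(mz + sign * off, phys * f)
                                     for off, f in pattern.offsets.items()]
                for cmz, cphys in contributions:
                    slot = product_phys.setdefault(
                        (ch.reagent_label, cmz),
                        {"phys": 0.0, "role": role,
                         "analyte": ch.analyte_id, "mixed": False})
                    slot["phys"] += cphys
                    if role == "primary":
                        slot["role"] = "primary"
                    if slot["analyte"] != ch.analyte_id:
                        slot["mixed"] = True

    for (reagent_label, mz), slot in sorted(product_phys.items()):
        meas = slot["phys"] / truth.g.lookup(mz)
        analyte = None if slot["mixed"] else slot["analyte"]
        label = f"{analyte or 'mixed'}/{reagent_label}@{mz}"
        records.append(SIMRecord(
            ion_label=label, mz=mz,
            counts=_poissonize(meas, dwell_product, noise, rng),
            dwell=dwell_product, role=slot["role"],
            reagent_label=reagent_label, analyte_id=analyte))

    return ScanFrame(timestamp=timestamp, records=records,
                     instrument=instrument_state_from_truth(truth))


def simulate_performance_check(truth: SimulationTruth,
                               standard: StandardDefinition,
                               lib: KineticsLibrary, noise: bool = False,
                               constants: PhysicalConstants = DEFAULT_CONSTANTS,
                               ) -> list[ScanFrame]:
    """Simulate the frames of a full performance check.

    The standard components are simulated at their certified concentrations,
    one frame per ion-source mode (wet positive; wet negative; dry
    negative), covering the reaction-time reaction, every ICF anchor and
    the low-mass/negative-mode determinations.
    """
    names = [c.name for c in standard.components]
    for rxn in standard.low_mass:
        if rxn.component not in names:
            names.append(rxn.component)
    missing = [n for n in names if not _has_analyte(lib, n)]
    if missing:
        raise ValueError(f"standard components missing from library: {missing}")

    conc = {c.name: c.concentration for c in standard.components}
    for rxn in standard.low_mass:
        conc.setdefault(rxn.component, rxn.concentration)
    check_truth = truth.model_copy(update={
        "true_concentrations": {**truth.true_concentrations, **conc},
        "makeup_dilution": 1.0,  # the standard is delivered undiluted
        # the check runs under dry, leak-free conditions: no hydrate ladder
        "hydrate_fractions": {},
    })

    rng = np.random.default_rng(truth.seed)
    modes = {
        "wet-positive": ("H3O+", "NO+", "O2+"),
        "wet-negative": ("OH-", "O2-"),
        "dry-negative": ("O-", "NO2-", "NO3-"),
    }
    frames = []
    for i, (_mode, reagent_set) in enumerate(modes.items()):
        present = [r for r in reagent_set
                   if r in check_truth.reagent_base_cps]
        if not present:
            continue
        wanted = [n for n in names
                  if any(c.reagent_label in present
                         for c in lib.analyte(n).channels)]
        if not wanted:
            continue
        frames.append(simulate_frame(
            check_truth, lib, wanted, noise=noise, reagents=present,
            constants=constants, rng=rng, timestamp=float(i)))
    return frames


def _has_analyte(lib: KineticsLibrary, name: str) -> bool:
    try:
        lib.analyte(name)
        return True
    except KeyError:
        return False
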