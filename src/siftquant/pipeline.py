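"""End-to-end quantitation runs: per-frame concentrations with corrections,
QC flags and a traceable run log.

Order of operations per frame and analyte: per-ion quantitation ->
interference corrections (isotopologue, then response-factor) -> tolerance
report -> makeup-gas correction.  Linear-combination deconvolution runs
afterwards on its own blocks and emits extra component rows.

QC rules applied per frame:

* overload — total product consumption above 25% of any reagent signal
  (outside the pseudo-first-order linear range);
* inspect-individual-ions — per-ion spread beyond the tolerance (some ions
  rejected), pointing at interference or missing secondary chemistry.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from ._version import __version__ as _pkg_version
from .calibration import PerformanceCheckResult
from .config import MethodConfig, _split_ion
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .interference import (LinearCombinationModel, isotopologue_subtract,
                           linear_combination_deconvolve, primary_subtract,
                           response_factor)
from .isotopes import isotopologue_distribution
from .library import KineticsLibrary
from .quantitation import (ion_key, makeup_correct, number_density_per_ion,
                           to_ppbv, tolerance_report)
from .records import InstrumentState, ScanFrame

__all__ = ["RunLog", "run_quantify", "build_lc_model", "pseudo_concentration"]

OVERLOAD_FRACTION = 0.25


class RunLog(BaseModel):
    """Append-only event log with QC flags."""

    events: list[dict] = Field(default_factory=list)

    def log(self, level: str, message: str, **context) -> None:
        self.events.append({"time": time.time(), "level": level,
                            "message": message, **context})

    @property
    def flags(self) -> list[str]:
        return [e["message"] for e in self.events if e["level"] == "warning"]


def _config_hash(config: MethodConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _state_for(frame: ScanFrame, check: PerformanceCheckResult,
               ) -> InstrumentState:
    if frame.instrument is None:
        raise ValueError(
            "frame carries no instrument state and no defaults were given; "
            "re-export the raw data with a full header")
    return frame.instrument.model_copy(update={
        "t_r": check.t_r, "icf_curve": check.icf_curve})


def _per_ion_ppbv(frame: ScanFrame, analyte_id: str, ions: Sequence[str],
                  lib: KineticsLibrary, state: InstrumentState,
                  isotope_accounting: bool,
                  constants: PhysicalConstants) -> dict[str, float]:
    rec = lib.analyte(analyte_id)
    out: dict[str, float] = {}
    for ch in rec.channels:
        key = ion_key(ch)
        if ions and key not in ions:
            continue
        if frame.find(ch.product_mz, role="primary",
                      reagent_label=ch.reagent_label) is None:
            continue
        iso = 1.0
        if isotope_accounting and ch.product_composition:
            iso = isotopologue_distribution(ch.product_composition).monoisotopic
        density = number_density_per_ion(frame, ch, lib, state,
                                         isotope_fraction=iso)
        out[key] = to_ppbv(density, state, constants)
    return out


def pseudo_concentration(frame: ScanFrame, lib: KineticsLibrary,
                         state: InstrumentState, target_analyte: str,
                         target_ion: str, at_mz: int,
                         constants: PhysicalConstants = DEFAULT_CONSTANTS,
                         ) -> float:
    """Concentration of the signal at ``at_mz`` computed with the target
    analyte's kinetic parameters (the 'pseudo' value interference
    subtraction needs)."""
    reagent, mz = _split_ion(target_ion)
    channels = [c for c in lib.analyte(target_analyte).channels
                if c.reagent_label == reagent and c.product_mz == mz]
    if not channels:
        raise ValueError(
            f"no channel {target_ion!r} for analyte {target_analyte!r}")
    ch = channels[0]
    shifted = ch.model_copy(update={"product_mz": at_mz,
                                    "secondary_products": []})
    density = number_density_per_ion(frame, shifted, lib, state)
    return to_ppbv(density, state, constants)


def _overload_check(frame: ScanFrame, state: InstrumentState,
                    log: RunLog, frame_idx: int) -> None:
    for reagent in (r for r in frame.records if r.role == "reagent"):
        reagent_cps = reagent.cps * state.attenuation_factor
        if reagent_cps <= 0:
            continue
        product_cps = sum(r.cps for r in frame.records
                          if r.role in ("primary", "secondary")
                          and r.reagent_label == reagent.ion_label)
        frac = product_cps / (product_cps + reagent_cps)
        if frac > OVERLOAD_FRACTION:
            log.log("warning",
                    f"overload: {reagent.ion_label} consumption "
                    f"{frac:.0%} exceeds {OVERLOAD_FRACTION:.0%} "
                    "(outside linear range)", frame=frame_idx)


def build_lc_model(block, lib: KineticsLibrary) -> LinearCombinationModel:
    """Branching matrix of a linear-combination block from library Rb."""
    branching = {}
    for comp in block.components:
        row = {}
        for mz in block.mz_list:
            chans = [c for c in lib.analyte(comp).channels
                     if c.reagent_label == block.reagent and c.product_mz == mz]
            row[mz] = chans[0].Rb if chans else 0.0
        branching[comp] = row
    return LinearCombinationModel(components=block.components,
                                  mz_list=block.mz_list, branching=branching)


def run_quantify(config: MethodConfig, frames: Sequence[ScanFrame],
                 lib: KineticsLibrary, check: PerformanceCheckResult,
                 constants: PhysicalConstants = DEFAULT_CONSTANTS,
                 ) -> tuple[pd.DataFrame, RunLog]:
    """Quantify every configured analyte in every frame.

    Returns a tidy results table (one row per frame x analyte, plus
    deconvolved component rows) and the run log.  Each row names the frame,
    library schema version, check timestamp and config hash that produced
    it.
    """
    if check is None:
        raise ValueError("a performance-check result is required")
    config.validate_against(lib)
    log = RunLog()
    cfg_hash = _config_hash(config)
    rows: list[dict] = []

    for idx, frame in enumerate(frames):
        state = _state_for(frame, check)
        _overload_check(frame, state, log, idx)

        per_analyte: dict[str, dict[str, float]] = {}
        for am in config.analyte:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                per_ion = _per_ion_ppbv(frame, am.id, am.ions, lib, state,
                                        am.isotope_accounting, constants)
            for w in caught:
                log.log("warning", str(w.message), frame=idx, analyte=am.id)
            if not per_ion:
                log.log("error",
                        f"no selected ions of {am.id!r} present; frame "
                        "skipped for this analyte", frame=idx)
                continue
            per_analyte[am.id] = per_ion

        # interference corrections on the per-ion values
        for blk in config.correction.isotopologue:
            if blk.target not in per_analyte:
                continue
            per_ion = per_analyte[blk.target]
            if blk.target_ion not in per_ion:
                continue
            c_int = pseudo_concentration(frame, lib, state, blk.target,
                                         blk.target_ion, blk.interferent_mz,
                                         constants)
            res = isotopologue_subtract(per_ion[blk.target_ion], c_int,
                                        blk.a, blk.n_iso, blk.mode)
            per_ion[blk.target_ion] = res.value
            if res.flagged:
                log.log("warning", f"{blk.target}/{blk.target_ion}: {res.note}",
                        frame=idx)

        for blk in config.correction.response_factor:
            if blk.target not in per_analyte:
                continue
            per_ion = per_analyte[blk.target]
            if blk.target_ion not in per_ion:
                continue
            if blk.r is None:
                raise ValueError(
                    f"response factor for {blk.target}/{blk.interferent} "
                    "not set; derive it from a pure-interferent calibration "
                    "run (interference.response_factor)")
            int_reagent, int_mz = _split_ion(blk.interferent_ion)
            c_b = _per_ion_ppbv(frame, blk.interferent,
                                [blk.interferent_ion], lib, state, False,
                                constants).get(blk.interferent_ion)
            if c_b is None:
                log.log("error",
                        f"interferent ion {blk.interferent_ion!r} missing; "
                        "response-factor correction skipped", frame=idx)
                continue
            res = primary_subtract(per_ion[blk.target_ion], c_b, blk.r)
            per_ion[blk.target_ion] = res.value
            if res.flagged:
                log.log("warning", f"{blk.target}/{blk.target_ion}: {res.note}",
                        frame=idx)

        # tolerance report + makeup correction
        for analyte_id, per_ion in per_analyte.items():
            reported, used, rejected = tolerance_report(per_ion,
                                                        config.tolerance)
            if rejected:
                log.log("warning",
                        f"{analyte_id}: per-ion spread exceeds tolerance; "
                        f"inspect individual ions ({rejected})", frame=idx)
            reported = makeup_correct(reported, state)
            rows.append({
                "frame": idx, "timestamp": frame.timestamp,
                "analyte": analyte_id,
                "reported_ppbv": reported,
                "used_ions": ";".join(used),
                "rejected_ions": ";".join(rejected),
                "per_ion_ppbv": json.dumps(
                    {k: makeup_correct(v, state)
                     for k, v in per_ion.items()}),
                "library_version": lib.schema_version,
                "check_timestamp": check.timestamp,
                "config_hash": cfg_hash,
                "package_version": _pkg_version,
            })

        # linear-combination deconvolution -> extra component rows
        for blk in config.correction.linear_combination:
            model = build_lc_model(blk, lib)
            signals = {}
            ok = True
            for mz in blk.mz_list:
                rec = frame.find(mz, role="primary", reagent_label=blk.reagent)
                if rec is None:
                    log.log("error",
                            f"deconvolution signal at m/z {mz} missing",
                            frame=idx)
                    ok = False
                    break
                signals[mz] = rec.cps * state.icf_curve.lookup(mz)
            if not ok:
                continue
            sum_reagent, sum_mz = _split_ion(blk.sum_ion)
            totals = []
            for comp in blk.components:
                val = _per_ion_ppbv(frame, comp, [blk.sum_ion], lib, state,
                                    False, constants).get(blk.sum_ion)
                if val is not None:
                    totals.append(val)
            if not totals:
                log.log("error", f"sum ion {blk.sum_ion!r} missing", frame=idx)
                continue
            total_c = sum(totals) / len(totals)
            comp_ppbv, clipped = linear_combination_deconvolve(
                signals, model, total_c)
            if clipped:
                log.log("warning",
                        "deconvolved fractions clipped to [0, 1]", frame=idx)
            for comp, val in comp_ppbv.items():
                rows.append({
                    "frame": idx, "timestamp": frame.timestamp,
                    "analyte": comp,
                    "reported_ppbv": makeup_correct(val, state),
                    "used_ions": f"deconvolved({blk.reagent}:"
                                 f"{','.join(map(str, blk.mz_list))})",
                    "rejected_ions": "",
                    "per_ion_ppbv": "{}",
                    "library_version": lib.schema_version,
                    "check_timestamp": check.timestamp,
                    "config_hash": cfg_hash,
                    "package_version": _pkg_version,
                })

    return pd.DataFrame(rows), log
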