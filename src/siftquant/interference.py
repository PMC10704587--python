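"""Interference handling: isotopologue subtraction, primary-ion subtraction
with a response factor, linear-combination deconvolution, and labelled sum
reporting for non-resolvable overlaps.

All corrections act on concentrations in ppbv, after per-ion quantitation
and before tolerance reporting.  A corrected concentration that would go
negative is floored at zero and flagged: a tolerance-selected SIFT-MS value
is an upper limit to the true concentration, so negatives carry no
information beyond "below the interference level".

Secondary-product-ion interference (humidity/concentration-dependent adduct
chemistry) is deliberately not corrected here; requests raise
:class:`NotSupportedError` naming the two calibration routes that can
address it.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "CorrectionResult",
    "IsotopologueCorrection",
    "ResponseFactorCorrection",
    "LinearCombinationModel",
    "NonResolvableError",
    "NotSupportedError",
    "isotopologue_subtract",
    "isotope_contribution_fraction",
    "response_factor",
    "primary_subtract",
    "linear_combination_deconvolve",
    "sum_report",
    "SumReport",
    "secondary_interference_correction",
]


class CorrectionResult(BaseModel):
    """A corrected concentration plus bookkeeping."""

    value: float
    flagged: bool = False
    note: str = ""


class NonResolvableError(ValueError):
    """The overlapped components cannot be separated; report a sum instead."""


class NotSupportedError(ValueError):
    """The requested correction is outside this package's scope."""


class IsotopologueCorrection(BaseModel):
    """Declares an isotopologue interference of one analyte on another."""

    target_analyte: str
    interferent_analyte: str
    a: float = Field(gt=0, lt=1, description="isotope abundance fraction")
    n_iso: int = Field(ge=1, description="atoms of the element in the interferent")
    interferent_measured_at: int
    mode: str = "linear"


class ResponseFactorCorrection(BaseModel):
    """Declares a primary-product-ion interference of B on A."""

    target: str
    interferent: str
    shared_mz: int
    unique_B_mz: int
    r: float = Field(gt=0)


class LinearCombinationModel(BaseModel):
    """Branching-ratio matrix for deconvolving co-reacting components.

    ``branching[component][mz]`` is the branching ratio of that component's
    channel at the shared m/z (as a fraction).  The components must react
    with similar rate coefficients for the model to be valid; a sum over a
    separate reagent ion (``sum_reagents``) supplies the total
    concentration to which the deconvolved fractions are applied.
    """

    components: list[str]
    mz_list: list[int]
    branching: dict[str, dict[int, float]]
    sum_reagents: list[str] = Field(default_factory=lambda: ["NO+", "H3O+"])

    @model_validator(mode="after")
    def _well_formed(self) -> "LinearCombinationModel":
        if len(self.components) < 2:
            raise ValueError("deconvolution needs at least two components")
        if len(self.mz_list) < len(self.components):
            raise ValueError("need at least as many m/z as components")
        for c in self.components:
            if c not in self.branching:
                raise ValueError(f"no branching row for component {c!r}")
            row = self.branching[c]
            missing = [m for m in self.mz_list if m not in row]
            if missing:
                raise ValueError(f"component {c!r} lacks branching at {missing}")
            if sum(row.values()) > 1.0 + 1e-9:
                raise ValueError(f"branching row of {c!r} sums above 1")
        return self

    def matrix(self) -> np.ndarray:
        """Matrix A with A[i, j] = branching of component j at mz_list[i]."""
        return np.array([[self.branching[c][mz] for c in self.components]
                         for mz in self.mz_list], dtype=float)


def isotope_contribution_fraction(a: float, n_iso: int,
                                  mode: str = "linear") -> float:
    """Fractional contribution of the interferent's heavy isotopologue.

    ``linear`` uses the n_iso * a product; ``binomial`` the exact
    satellite-to-monoisotopic count ratio of the binomial isotopologue
    distribution, n_iso * a / (1 - a) (the interferent is measured on its
    monoisotopic peak, so its +1 satellite scales with that ratio).  The two
    agree within a few percent whenever n_iso * a is small.
    """
    if not (0.0 < a < 1.0):
        raise ValueError("isotope abundance a must be in (0, 1)")
    if n_iso < 1:
        raise ValueError("n_iso must be >= 1")
    if mode == "linear":
        return n_iso * a
    if mode == "binomial":
        return n_iso * a / (1.0 - a)
    raise ValueError(f"unknown mode {mode!r}")


def isotopologue_subtract(C_app: float, C_int: float, a: float, n_iso: int,
                          mode: str = "linear") -> CorrectionResult:
    """Remove an isotopologue interference from an apparent concentration.

    ``C_int`` is the interferent concentration measured, with the target's
    kinetic data, at the interferent's predominant-isotope ion; its heavy
    isotopologue contributes ``C_int * n_iso * a`` at the target m/z.
    """
    if C_app < 0 or C_int < 0:
        raise ValueError("concentrations must be non-negative")
    corr = C_app - C_int * isotope_contribution_fraction(a, n_iso, mode)
    if corr < 0:
        return CorrectionResult(
            value=0.0, flagged=True,
            note=f"isotopologue subtraction overshoot ({corr:.4g} ppbv "
                 "floored at 0)")
    return CorrectionResult(value=corr)


def response_factor(C_pseudo: float, C_B: float) -> float:
    """Response factor r from a pure interferent calibration sample.

    ``C_pseudo`` is the pure-B sample's concentration at the interfered m/z
    calculated with the *target's* kinetic parameters; ``C_B`` the same
    sample via B's unique ion.
    """
    if C_B <= 0:
        raise ValueError("interferent concentration must be positive")
    if C_pseudo < 0:
        raise ValueError("pseudo concentration must be non-negative")
    return C_pseudo / C_B


def primary_subtract(C_AB: float, C_B: float, r: float) -> CorrectionResult:
    """Subtract a primary-ion interference: C_A = C_AB - r * C_B."""
    if C_AB < 0 or C_B < 0:
        raise ValueError("concentrations must be non-negative")
    if r <= 0:
        raise ValueError("response factor must be positive")
    corr = C_AB - r * C_B
    if corr < 0:
        return CorrectionResult(
            value=0.0, flagged=True,
            note=f"primary-ion subtraction overshoot ({corr:.4g} ppbv "
                 "floored at 0)")
    return CorrectionResult(value=corr)


def linear_combination_deconvolve(signals: Mapping[int, float],
                                  model: LinearCombinationModel,
                                  total_C: float,
                                  ) -> tuple[dict[str, float], bool]:
    """Split a total concentration among co-reacting components.

    ``signals`` are ICF-corrected product-ion cps at the shared m/z;
    ``total_C`` the valid sum measured with a non-discriminating reagent
    ion.  Solves the small branching-ratio linear system for the component
    fractions; out-of-range fractions are clipped to [0, 1] and
    renormalized (Poisson noise can push the unconstrained solution
    outside), with the second return flagging that clipping occurred.
    """
    missing = [m for m in model.mz_list if m not in signals]
    if missing:
        raise ValueError(f"missing signals at m/z {missing}")
    if total_C < 0:
        raise ValueError("total concentration must be non-negative")
    A = model.matrix()
    if np.linalg.matrix_rank(A, tol=1e-10 * np.abs(A).max()) < len(model.components):
        raise NonResolvableError(
            "branching matrix is singular (components react identically); "
            "report a sum instead (sum_report)")
    s = np.array([signals[m] for m in model.mz_list], dtype=float)
    f, *_ = np.linalg.lstsq(A, s, rcond=None)
    total = f.sum()
    if total <= 0:
        raise ValueError("deconvolved fractions sum to <= 0; check signals")
    f = f / total
    clipped = bool((f < -1e-9).any() or (f > 1 + 1e-9).any())
    if clipped or (f < 0).any() or (f > 1).any():
        f = np.clip(f, 0.0, 1.0)
        f = f / f.sum()
    return ({c: float(frac * total_C)
             for c, frac in zip(model.components, f)}, clipped)


class SumReport(BaseModel):
    label: str
    value: float
    note: str = ""


def sum_report(components: Sequence[str], value: float,
               k_values: Optional[Mapping[str, float]] = None,
               spread_tolerance: float = 0.10) -> SumReport:
    """Report a labelled sum for non-resolvable components.

    When the members' rate coefficients spread by more than
    ``spread_tolerance`` (relative), the report carries an uncertainty note:
    the sum is then only approximate because the members respond
    differently.
    """
    if not components:
        raise ValueError("no components to sum")
    label = " + ".join(components) if len(components) > 1 else components[0]
    if len(components) == 1:
        return SumReport(label=label, value=value)
    note = ""
    if k_values:
        ks = [k_values[c] for c in components if c in k_values]
        if len(ks) >= 2:
            spread = (max(ks) - min(ks)) / (sum(ks) / len(ks))
            if spread > spread_tolerance:
                note = (f"member rate coefficients spread by {spread:.0%}; "
                        "reported sum carries extra uncertainty")
    return SumReport(label=f"sum of {label}" if len(components) > 1 else label,
                     value=value, note=note)


def secondary_interference_correction(*_args, **_kwargs):
    """Secondary-product-ion interference is not correctable here."""
    raise NotSupportedError(
        "secondary-product-ion interference correction is not supported; "
        "it requires either (1) analysing at constant humidity/interferent "
        "concentration after calibrating the interferent secondary "
        "chemistry under those conditions, or (2) a concentration-dependent "
        "calibration of the interferent secondary chemistry used to predict "
        "the contribution")
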