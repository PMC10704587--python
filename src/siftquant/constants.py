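"""Physical constants and unit helpers shared across the package.

SIFT-MS concentration arithmetic runs on a handful of instrument-convention
constants.  The flow-tube number density uses the instrument convention
``TORR_DENSITY_CM3`` (molecules cm^-3 at 1 Torr, referenced to
:data:`T_REF_K`); an independent ideal-gas evaluation is available for
cross-checking and is reported as a diagnostic by the calibration module,
never silently substituted.
"""

from __future__ import annotations

from pydantic import BaseModel

#: Number density of gas molecules at 1 Torr (cm^-3), instrument convention.
TORR_DENSITY_CM3 = 3.894e15

#: Gas constant in Torr L K^-1 mol^-1 (instrument convention).
R_GAS_TORR_L = 62.48

#: Avogadro's number (mol^-1), instrument convention.
N_AVOGADRO = 6.022e23

#: Reference temperature (K) at which TORR_DENSITY_CM3 is taken.
T_REF_K = 300.0

#: Kinetics libraries tabulate rate coefficients at this temperature (K).
T_LIBRARY_K = 300.0

# The two documented operating-point pairings (22 sccm <-> 0.3 Torr L/s,
# 145 sccm <-> 2 Torr L/s) imply slightly different factors; their mean
# defines the interface conversion.
SCCM_TO_TORR_L_S = 0.5 * (0.3 / 22.0 + 2.0 / 145.0)

#: ppbv as a mole fraction.
PPBV = 1e-9


class PhysicalConstants(BaseModel):
    """Constants entering the reaction-time and ICF equations."""

    c: float = TORR_DENSITY_CM3
    R_gas: float = R_GAS_TORR_L
    N_A: float = N_AVOGADRO
    T_ref: float = T_REF_K

    model_config = {"frozen": True}


DEFAULT_CONSTANTS = PhysicalConstants()


def flow_tube_density(P_g: float, T_g: float,
                      constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Total gas number density in the flow tube (cm^-3).

    Uses the instrument-convention constant ``c`` at 1 Torr, scaled linearly
    in pressure and inversely in temperature from the reference temperature.
    """
    if P_g <= 0 or T_g <= 0:
        raise ValueError("pressure and temperature must be positive")
    return constants.c * P_g * (constants.T_ref / T_g)


def ideal_gas_density(P_g: float, T_g: float,
                      constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Ideal-gas number density (cm^-3) from the printed R and N_A.

    Independent cross-check of :func:`flow_tube_density`; the systematic
    ratio between the two is surfaced as a calibration diagnostic.
    """
    if P_g <= 0 or T_g <= 0:
        raise ValueError("pressure and temperature must be positive")
    # mol per litre -> molecules per cm^3
    return P_g * constants.N_A / (constants.R_gas * T_g) / 1000.0


def sample_fraction(phi_c: float, phi_s: float) -> float:
    """Fraction of flow-tube gas that is sampled air, phi_s/(phi_c + phi_s)."""
    if phi_s <= 0 or phi_c <= 0:
        raise ValueError("flows must be positive")
    return phi_s / (phi_c + phi_s)


def sccm_to_torr_l_s(flow_sccm: float) -> float:
    """Convert a flow in sccm to Torr L s^-1 (interface convenience)."""
    return flow_sccm * SCCM_TO_TORR_L_S
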