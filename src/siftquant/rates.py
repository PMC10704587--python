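"""Collisional rate coefficients for ion-molecule capture.

Thermal ion-molecule reactions are bounded by the collisional (capture) rate
coefficient k_c.  For nonpolar molecules k_c is the temperature-independent
Langevin value set by the polarizability alone; for polar molecules the
permanent dipole raises k_c (up to two- to three-fold) and makes it fall
with temperature, described here by the Su-Chesnavich trajectory
parametrization in the reduced-dipole variable

    x = mu_D / sqrt(2 alpha k_B T)

Tabulated library rate coefficients (measured at a reference temperature,
conventionally 300 K in helium) can be rescaled to the instrument flow-tube
temperature by the ratio of parametrized capture rates; association channels
have no such theory and must be measured under the operating conditions.
"""

from __future__ import annotations

import math

from scipy import constants as sc

from .constants import T_LIBRARY_K

__all__ = [
    "langevin_rate",
    "su_chesnavich_ratio",
    "su_chesnavich_rate",
    "effective_rate",
]

# 2*pi*e*sqrt(1e-24 cm^3 / 1 u in g): Langevin prefactor for alpha in
# Angstrom^3 and reduced mass in Da, with e in esu (Gaussian units).
_E_ESU = sc.elementary_charge * sc.c * 100.0 / 10.0  # 4.8032e-10 esu
_U_G = sc.atomic_mass * 1000.0
_LANGEVIN_PREF = 2.0 * math.pi * _E_ESU * math.sqrt(1e-24 / _U_G)

_KB_ERG = sc.Boltzmann * 1e7  # erg/K
_DEBYE_ESU_CM = 1e-18


def langevin_rate(polarizability: float, ion_mass: float,
                  molecule_mass: float) -> float:
    """Langevin capture rate coefficient (cm^3 s^-1).

    Parameters
    ----------
    polarizability : molecular polarizability in Angstrom^3.
    ion_mass, molecule_mass : masses in Da; the reduced mass is formed here.
    """
    if ion_mass <= 0 or molecule_mass <= 0:
        raise ValueError("masses must be positive")
    if polarizability is None:
        raise ValueError(
            "polarizability unavailable: supply a measured rate coefficient")
    if polarizability < 0:
        raise ValueError("polarizability must be non-negative")
    mu = ion_mass * molecule_mass / (ion_mass + molecule_mass)
    return _LANGEVIN_PREF * math.sqrt(polarizability / mu)


def su_chesnavich_ratio(dipole: float, polarizability: float, T: float) -> float:
    """Capture enhancement k_c/k_L for a polar molecule at temperature T.

    ``dipole`` in Debye, ``polarizability`` in Angstrom^3.  Returns 1 for a
    nonpolar molecule; always >= 1.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if dipole < 0 or polarizability <= 0:
        raise ValueError("dipole must be >= 0 and polarizability > 0")
    if dipole == 0:
        return 1.0
    x = (dipole * _DEBYE_ESU_CM
         / math.sqrt(2.0 * polarizability * 1e-24 * _KB_ERG * T))
    if x >= 2.0:
        ratio = 0.4767 * x + 0.6200
    else:
        ratio = (x + 0.5090) ** 2 / 10.526 + 0.9754
    # the x<2 branch dips to 0.999997 at x=0; capture cannot be slower than
    # Langevin, so clamp
    return max(ratio, 1.0)


def su_chesnavich_rate(k_L: float, dipole: float, polarizability: float,
                       T: float) -> float:
    """Capture rate coefficient k_c(T) (cm^3 s^-1) from the Langevin value."""
    if k_L <= 0:
        raise ValueError("k_L must be positive")
    return k_L * su_chesnavich_ratio(dipole, polarizability, T)


def effective_rate(channel, analyte, T: float, mode: str = "tabulated",
                   T_ref: float = T_LIBRARY_K) -> float:
    """Rate coefficient for a reaction channel at flow-tube temperature T.

    ``tabulated`` returns the stored library value unchanged.  ``recomputed``
    rescales the stored value by the Su-Chesnavich capture ratio between T
    and the library reference temperature; nonpolar analytes are unaffected.
    Association channels cannot be rescaled (their rates in N2 carrier at
    elevated temperature are unpredictably different from tabulations) and
    raise in recomputed mode.
    """
    if mode == "tabulated":
        return channel.k
    if mode != "recomputed":
        raise ValueError(f"unknown mode {mode!r}")
    if channel.channel_type == "association":
        raise ValueError(
            "association channel rates need to be experimentally determined "
            "under the operating conditions; recomputation is not supported")
    dipole = analyte.dipole_moment or 0.0
    if dipole == 0.0:
        return channel.k
    if analyte.polarizability is None:
        raise ValueError(
            f"analyte {analyte.analyte_id!r} has a dipole moment but no "
            "polarizability; cannot rescale")
    scale = (su_chesnavich_ratio(dipole, analyte.polarizability, T)
             / su_chesnavich_ratio(dipole, analyte.polarizability, T_ref))
    return channel.k * scale
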