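"""Ready-made simulation scenarios (study conditions for the bundled
chemistries).

The instrument truth reflects typical operating conditions of an advanced
SIFT-MS instrument: flow tube at 0.46 Torr heated to 120 degC, nitrogen
carrier at 2 Torr L/s, sample capillary at 0.3 Torr L/s, reagent signals
of a few Mcps behind a 100x attenuation, reaction time of about 6 ms.
The transmission truth g rises with |m/z| (poorer transmission needs a
larger correction), is 1 on the 28-32 plateau by definition, and is
mirrored onto the negative side.
"""

from __future__ import annotations

from .builtin import builtin_library, builtin_standard
from .icf import ICFCurve
from .simulate import SimulationTruth

__all__ = ["default_transmission_truth", "default_truth", "SCENARIOS",
           "scenario"]


def default_transmission_truth() -> ICFCurve:
    """A realistic piecewise-linear transmission truth over both polarities."""
    pos = {19: 1.4, 28: 1.0, 32: 1.0, 78: 1.3, 92: 1.5, 114: 1.8,
           150: 2.4, 186: 3.2, 236: 4.4}
    # endpoint on the line through the two highest anchors, as the
    # calibration itself extrapolates
    slope = (pos[236] - pos[186]) / (236 - 186)
    pos[400] = pos[236] + slope * (400 - 236)
    anchors = dict(pos)
    for mz, val in pos.items():
        if mz >= 28:
            anchors[-mz] = val
    anchors[-17] = 1.3
    anchors[-16] = 1.2
    return ICFCurve(anchors=anchors)


def default_truth(seed: int, concentrations: dict[str, float],
                  **overrides) -> SimulationTruth:
    """Simulation truth under the default study conditions."""
    params = dict(
        true_concentrations=concentrations,
        t_r_true=6.0e-3,
        g=default_transmission_truth(),
        reagent_base_cps={"H3O+": 5.0e6, "NO+": 4.0e6, "O2+": 6.0e6,
                          "OH-": 2.0e6, "O-": 1.0e6, "O2-": 1.0e6},
        P_g=0.46, T_g=393.15, phi_c=2.0, phi_s=0.3,
        attenuation_factor=100.0,
        hydrate_fractions={"H3O+": {37: 0.15, 55: 0.03}},
        seed=seed,
    )
    params.update(overrides)
    return SimulationTruth(**params)


SCENARIOS: dict[str, dict[str, float]] = {
    # isotopologue interference of the 13C satellite of DMF on NDMA
    "ndma-dmf": {"NDMA": 10.0, "DMF": 100.0},
    # primary-ion interference of acetaldehyde on ethylene oxide at m/z 45
    "acetaldehyde-eo": {"acetaldehyde": 50.0, "ethylene_oxide": 20.0},
    # linear-combination deconvolution of the C8H10 isomers
    "xylenes": {"ethylbenzene": 30.0, "xylene": 30.0},
    # secondary water-adduct chemistry
    "ethanol": {"ethanol": 200.0},
}


def scenario(name: str, seed: int):
    """Return (truth, library, analytes, standard) for a named scenario."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from "
                       f"{sorted(SCENARIOS)}")
    conc = dict(SCENARIOS[name])
    return (default_truth(seed, conc), builtin_library(), list(conc),
            builtin_standard())
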