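"""Shared fixtures: the built-in library, a calibrated instrument and
noise-free simulated data under the default study conditions."""

from __future__ import annotations

import pytest

import siftquant as sq


@pytest.fixture(scope="session")
def lib() -> sq.KineticsLibrary:
    return sq.builtin_library()


@pytest.fixture(scope="session")
def standard() -> sq.StandardDefinition:
    return sq.builtin_standard()


@pytest.fixture(scope="session")
def truth() -> sq.SimulationTruth:
    return sq.default_truth(seed=1, concentrations={
        "NDMA": 10.0, "DMF": 100.0, "benzene": 50.0, "ethanol": 200.0,
        "acetaldehyde": 50.0, "ethylene_oxide": 20.0,
        "ethylbenzene": 30.0, "xylene": 30.0,
    })


@pytest.fixture(scope="session")
def check_result(truth, standard, lib) -> sq.PerformanceCheckResult:
    frames = sq.simulate_performance_check(truth, standard, lib, noise=False)
    return sq.run_performance_check(
        frames, standard, P_g=truth.P_g, T_g=truth.T_g,
        phi_c=truth.phi_c, phi_s=truth.phi_s,
        attenuation_factor=truth.attenuation_factor)


@pytest.fixture(scope="session")
def state(truth, check_result) -> sq.InstrumentState:
    return sq.instrument_state_from_truth(
        truth, icf_curve=check_result.icf_curve, t_r=check_result.t_r)


@pytest.fixture()
def flat_truth() -> sq.SimulationTruth:
    """Identity transmission, no hydrates: the simplest exact instrument."""
    return sq.default_truth(
        seed=7, concentrations={"benzene": 100.0},
        g=sq.ICFCurve(anchors={10: 1.0, 400: 1.0, -10: 1.0, -400: 1.0}),
        hydrate_fractions={}, attenuation_factor=1.0)
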