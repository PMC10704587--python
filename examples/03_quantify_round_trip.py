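"""Full chain on synthetic data: simulate -> calibrate -> quantify.

Known concentrations are injected into the forward simulator; the analysis
chain (performance check, per-ion number densities, dilution conversion,
tolerance report) recovers them.  With Poisson noise the spread follows
counting statistics.
"""

import warnings

from siftquant import (builtin_library, builtin_standard, default_truth,
                       instrument_state_from_truth, quantify_analyte,
                       run_performance_check, simulate_frame,
                       simulate_performance_check)

lib = builtin_library()
standard = builtin_standard()
conc = {"benzene": 50.0, "ethanol": 200.0}
truth = default_truth(seed=42, concentrations=conc)

check = run_performance_check(
    simulate_performance_check(truth, standard, lib, noise=False), standard,
    P_g=truth.P_g, T_g=truth.T_g, phi_c=truth.phi_c, phi_s=truth.phi_s,
    attenuation_factor=truth.attenuation_factor)
state = instrument_state_from_truth(truth, icf_curve=check.icf_curve,
                                    t_r=check.t_r)

print(f"{'analyte':<10} {'truth':>8} {'noise-free':>11} {'noisy':>8} "
      f"{'+/- SE':>7}")
for analyte, true_ppbv in conc.items():
    quiet = simulate_frame(truth, lib, list(conc), noise=False)
    noisy = simulate_frame(truth, lib, list(conc), noise=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        exact = quantify_analyte(quiet, analyte, lib, state)
        est = quantify_analyte(noisy, analyte, lib, state)
    print(f"{analyte:<10} {true_ppbv:>8.1f} {exact.reported:>11.4f} "
          f"{est.reported:>8.2f} {est.se:>7.2f}")

print("\nNoise-free reports equal the injected truth to machine precision;"
      "\nnoisy reports scatter within the propagated Poisson SE.")
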