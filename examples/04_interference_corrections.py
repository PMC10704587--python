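"""Interference handling: isotopologue subtraction and linear-combination
deconvolution.

Scenario 1 -- NDMA in the presence of a 10-fold DMF excess: every NDMA
product ion sits 1 Da above a DMF ion, so the 13C satellites of DMF
inflate the apparent NDMA reading; the declared subtraction restores it.

Scenario 2 -- ethylbenzene vs the xylenes: identical product m/z but
near-opposite O2+ branching (70/30 vs 20/80) lets a 2x2 linear system
split the summed concentration.
"""

from siftquant import (LinearCombinationModel, MethodConfig, builtin_library,
                       builtin_standard, default_truth,
                       linear_combination_deconvolve, run_performance_check,
                       simulate_frame, simulate_performance_check)
from siftquant.pipeline import run_quantify

lib = builtin_library()
standard = builtin_standard()
truth = default_truth(seed=7, concentrations={"NDMA": 10.0, "DMF": 100.0})
check = run_performance_check(
    simulate_performance_check(truth, standard, lib, noise=False), standard,
    P_g=truth.P_g, T_g=truth.T_g, phi_c=truth.phi_c, phi_s=truth.phi_s,
    attenuation_factor=truth.attenuation_factor)

frame = simulate_frame(truth, lib, ["NDMA", "DMF"], noise=False,
                       isotopes=True)
base = {
    "analyte": [
        {"id": "NDMA", "ions": ["H3O+@75", "NO+@74", "O2+@74"],
         "isotope_accounting": True},
        {"id": "DMF", "ions": ["O2+@73", "H3O+@74"],
         "isotope_accounting": True},
    ],
}
corrections = [
    {"target": "NDMA", "target_ion": "NO+@74", "interferent": "DMF",
     "interferent_mz": 73, "a": 0.011, "n_iso": 3, "mode": "binomial"},
    {"target": "NDMA", "target_ion": "O2+@74", "interferent": "DMF",
     "interferent_mz": 73, "a": 0.011, "n_iso": 3, "mode": "binomial"},
    {"target": "NDMA", "target_ion": "H3O+@75", "interferent": "DMF",
     "interferent_mz": 74, "a": 0.011, "n_iso": 3, "mode": "binomial"},
]
for label, cfg in [
    ("uncorrected", MethodConfig.model_validate(base)),
    ("corrected", MethodConfig.model_validate(
        {**base, "correction": {"isotopologue": corrections}})),
]:
    results, _ = run_quantify(cfg, [frame], lib, check)
    ndma = results[results.analyte == "NDMA"].reported_ppbv.iloc[0]
    print(f"NDMA ({label:>11}): {ndma:6.2f} ppbv   (truth 10.00)")

model = LinearCombinationModel(
    components=["ethylbenzene", "xylene"], mz_list=[91, 106],
    branching={"ethylbenzene": {91: 0.70, 106: 0.30},
               "xylene": {91: 0.20, 106: 0.80}})
signals = {91: 0.45, 106: 0.55}  # a 50:50 mixture's branching-weighted mix
split, _ = linear_combination_deconvolve(signals, model, total_C=60.0)
print("\nC8H10 deconvolution of a 60 ppbv total "
      f"(signals 91:106 = 45:55): {split['ethylbenzene']:.1f} ppbv "
      f"ethylbenzene + {split['xylene']:.1f} ppbv xylenes")
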