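"""Interference corrections: isotopologue and primary-ion subtraction,
linear-combination deconvolution and sum reporting."""

from __future__ import annotations

import numpy as np
import pytest

import siftquant as sq
from siftquant.interference import (LinearCombinationModel, NonResolvableError,
                                    NotSupportedError,
                                    isotope_contribution_fraction,
                                    isotopologue_subtract,
                                    linear_combination_deconvolve,
                                    primary_subtract, response_factor,
                                    secondary_interference_correction,
                                    sum_report)


class TestIsotopologueSubtraction:
    def test_no_interferent_is_identity(self):
        assert isotopologue_subtract(10.0, 0.0, 0.011, 3).value == 10.0

    def test_dmf_on_ndma_linear(self):
        # three carbons at 1.1%: 10 - 100 * 0.033 = 6.7
        res = isotopologue_subtract(10.0, 100.0, 0.011, 3)
        assert res.value == pytest.approx(6.7)
        assert not res.flagged

    def test_dmf_on_ndma_binomial_crosscheck(self):
        # exact satellite/monoisotopic ratio 3 * 0.011 / 0.989 = 0.0334;
        # linear and exact corrections agree to a few percent of the
        # subtracted contribution
        res = isotopologue_subtract(10.0, 100.0, 0.011, 3, mode="binomial")
        assert res.value == pytest.approx(10.0 - 100 * 3 * 0.011 / 0.989)
        lin = isotopologue_subtract(10.0, 100.0, 0.011, 3, mode="linear")
        assert abs(res.value - lin.value) < 0.05 * (10.0 - res.value)

    def test_overshoot_floors_at_zero_with_flag(self):
        res = isotopologue_subtract(1.0, 100.0, 0.011, 3)
        assert res.value == 0.0 and res.flagged

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            isotopologue_subtract(1.0, 1.0, 1.5, 3)
        with pytest.raises(ValueError):
            isotopologue_subtract(1.0, 1.0, 0.011, 0)

    def test_subtract_then_readd_is_identity(self):
        contribution = 100.0 * isotope_contribution_fraction(0.011, 3)
        res = isotopologue_subtract(5.0 + contribution, 100.0, 0.011, 3)
        assert res.value == pytest.approx(5.0, rel=1e-12)

    def test_linear_vs_binomial_agree_for_small_na(self):
        """The n*a shorthand tracks the exact binomial single-substitution
        fraction within 5% relative whenever n*a < 0.1."""
        for a in (0.002, 0.011, 0.04):
            for n in range(1, 26):
                if n * a >= 0.1:
                    continue
                lin = isotope_contribution_fraction(a, n, "linear")
                exact = isotope_contribution_fraction(a, n, "binomial")
                assert abs(lin - exact) / exact < 0.05, (a, n)


class TestResponseFactorSubtraction:
    def test_response_factor_examples(self):
        assert response_factor(50.0, 100.0) == 0.5
        assert response_factor(100.0, 100.0) == 1.0
        with pytest.raises(ValueError):
            response_factor(50.0, 0.0)

    def test_primary_subtract_examples(self):
        assert primary_subtract(30.0, 20.0, 0.5).value == pytest.approx(20.0)
        assert primary_subtract(30.0, 0.0, 0.5).value == 30.0
        res = primary_subtract(5.0, 20.0, 0.5)
        assert res.value == 0.0 and res.flagged

    def test_simulated_pure_interferent_gives_analytic_r(self, lib, truth,
                                                         state):
        """A pure acetaldehyde sample quantified at m/z 45 with ethylene
        oxide kinetics yields r = (k_acet Rb) / (k_eo Rb) analytically
        (both H3O+ products sit at the same m/z, so the ICF cancels)."""
        pure = truth.model_copy(update={"true_concentrations":
                                        {"acetaldehyde": 80.0}})
        frame = sq.simulate_frame(pure, lib, ["acetaldehyde"], noise=False)
        eo_ch = lib.channels_for("ethylene_oxide", "H3O+")[0]
        pseudo = sq.to_ppbv(
            sq.quantitation.number_density_per_ion(frame, eo_ch, lib, state),
            state) * state.makeup_dilution
        acet = sq.quantify_analyte(frame, "acetaldehyde", lib, state,
                                   ions=["NO+@43"]).reported
        r = response_factor(pseudo, acet)
        k_a = lib.channels_for("acetaldehyde", "H3O+")[0].k
        assert r == pytest.approx(k_a / eo_ch.k, rel=1e-9)

    def test_ethylene_oxide_recovered_after_subtraction(self, lib, truth,
                                                        state):
        """Table-derived kinetics: the acetaldehyde interference on the
        ethylene oxide H3O+ product is removed exactly (noise-free)."""
        frame = sq.simulate_frame(truth, lib,
                                  ["acetaldehyde", "ethylene_oxide"],
                                  noise=False)
        eo_ch = lib.channels_for("ethylene_oxide", "H3O+")[0]
        c_ab = sq.to_ppbv(
            sq.quantitation.number_density_per_ion(frame, eo_ch, lib, state),
            state) * state.makeup_dilution
        # the OH- m/z -43 product is the acetaldehyde ion free of any
        # ethylene oxide contribution (the NO+ m/z 43 ion carries a small
        # one through the slow 3% channel)
        c_b = sq.quantify_analyte(frame, "acetaldehyde", lib, state,
                                  ions=["OH-@-43"]).reported
        k_a = lib.channels_for("acetaldehyde", "H3O+")[0].k
        r = k_a / eo_ch.k
        res = primary_subtract(c_ab, c_b, r)
        assert res.value == pytest.approx(
            truth.true_concentrations["ethylene_oxide"], rel=1e-9)


def xylene_model() -> LinearCombinationModel:
    return LinearCombinationModel(
        components=["ethylbenzene", "xylene"], mz_list=[91, 106],
        branching={"ethylbenzene": {91: 0.70, 106: 0.30},
                   "xylene": {91: 0.20, 106: 0.80}})


class TestLinearCombination:
    def test_pure_ethylbenzene(self):
        result, clipped = linear_combination_deconvolve(
            {91: 0.70, 106: 0.30}, xylene_model(), 40.0)
        assert result["ethylbenzene"] == pytest.approx(40.0)
        assert result["xylene"] == pytest.approx(0.0, abs=1e-9)
        assert not clipped

    def test_equal_mixture_from_045_055_signals(self):
        result, _ = linear_combination_deconvolve(
            {91: 0.45, 106: 0.55}, xylene_model(), 60.0)
        assert result["ethylbenzene"] == pytest.approx(30.0)
        assert result["xylene"] == pytest.approx(30.0)

    def test_identical_rows_non_resolvable(self):
        model = LinearCombinationModel(
            components=["o-xylene", "m-xylene"], mz_list=[91, 106],
            branching={"o-xylene": {91: 0.2, 106: 0.8},
                       "m-xylene": {91: 0.2, 106: 0.8}})
        with pytest.raises(NonResolvableError):
            linear_combination_deconvolve({91: 1.0, 106: 4.0}, model, 10.0)

    def test_noise_free_sweep_unbiased(self):
        """Deconvolved fractions across the 0..1 composition range carry no
        bias beyond roundoff."""
        model = xylene_model()
        A = model.matrix()
        for f in np.linspace(0.0, 1.0, 21):
            s = A @ np.array([f, 1.0 - f])
            result, _ = linear_combination_deconvolve(
                {91: s[0], 106: s[1]}, model, 100.0)
            assert abs(result["ethylbenzene"] / 100.0 - f) < 1e-6

    def test_noisy_recovery_within_propagated_se(self):
        """Over 200 Poisson-noisy equal-k mixtures (the regime where the
        branching-only model is exact) the mean deconvolved fraction is
        unbiased within 3x the propagated SE of the mean."""
        model = xylene_model()
        A = model.matrix()
        rng = np.random.default_rng(123)
        for truth_frac in (0.25, 0.5, 0.75):
            lam = 4000.0 * (A @ np.array([truth_frac, 1.0 - truth_frac]))

            def fraction(signals):
                result, _ = linear_combination_deconvolve(
                    {91: signals[0], 106: signals[1]}, model, 1.0)
                return result["ethylbenzene"]

            # propagated SE by one-count-SE bumps (linearization)
            var = 0.0
            for i in range(2):
                bumped = lam.copy()
                bumped[i] += np.sqrt(lam[i])
                var += (fraction(bumped) - fraction(lam)) ** 2
            se_single = np.sqrt(var)

            vals = np.array([fraction(rng.poisson(lam).astype(float))
                             for _ in range(200)])
            assert abs(vals.mean() - truth_frac) <= \
                3 * se_single / np.sqrt(200), truth_frac


class TestSumReporting:
    def test_xylene_isomers_sum_label(self):
        rep = sum_report(["o-xylene", "m-xylene", "p-xylene"], 45.0,
                         k_values={"o-xylene": 1.9e-9, "m-xylene": 1.95e-9,
                                   "p-xylene": 1.9e-9})
        assert rep.label.startswith("sum of")
        assert rep.value == 45.0 and rep.note == ""

    def test_single_member_is_itself(self):
        rep = sum_report(["benzene"], 12.0)
        assert rep.label == "benzene" and rep.note == ""

    def test_dissimilar_members_flagged(self):
        rep = sum_report(["a", "b"], 10.0,
                         k_values={"a": 1.0e-9, "b": 1.5e-9})
        assert "uncertainty" in rep.note

    def test_secondary_interference_not_supported(self):
        with pytest.raises(NotSupportedError, match="humidity"):
            secondary_interference_correction()
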