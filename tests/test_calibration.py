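"""Performance check: reaction-time inversion, ICF anchor recovery, curve
assembly and shape diagnostics."""

from __future__ import annotations

import numpy as np
import pytest

import siftquant as sq
from siftquant.calibration import (build_icf_curve, check_icf_shape,
                                   compute_icf_anchor, compute_reaction_time,
                                   solve_reagent_icf)

STATE = dict(P_g=0.46, T_g=393.15, phi_c=2.0, phi_s=0.3)


class TestReactionTime:
    def test_linear_in_signal_ratio(self):
        t1 = compute_reaction_time(1000.0, 6e6, 2000.0, 0.68e-9, **STATE)
        t2 = compute_reaction_time(2000.0, 6e6, 2000.0, 0.68e-9, **STATE)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_zero_product_signal_errors(self):
        with pytest.raises(ValueError, match="P28"):
            compute_reaction_time(0.0, 6e6, 2000.0, 0.68e-9, **STATE)

    def test_depletion_warning(self):
        with pytest.warns(UserWarning, match="thin-reaction"):
            compute_reaction_time(2e6, 6e6, 2000.0, 0.68e-9, **STATE)

    def test_round_trip_recovers_injected_time(self, truth, standard, lib):
        frames = sq.simulate_performance_check(truth, standard, lib)
        result = sq.run_performance_check(
            frames, standard, P_g=truth.P_g, T_g=truth.T_g,
            phi_c=truth.phi_c, phi_s=truth.phi_s,
            attenuation_factor=truth.attenuation_factor)
        assert abs(result.t_r - truth.t_r_true) / truth.t_r_true < 1e-9


class TestIcfAnchors:
    comp = sq.StandardComponent(name="hexafluorobenzene", reagent_label="O2+",
                                product_mz=186, k=1.2e-9)

    def test_proportional_to_product_signal(self):
        a1 = compute_icf_anchor(self.comp, 1000.0, 6e6, 6e-3, **STATE)
        a2 = compute_icf_anchor(self.comp, 2000.0, 6e6, 6e-3, **STATE)
        assert a1 == pytest.approx(2 * a2, rel=1e-12)

    def test_plateau_anchor_forced_to_one(self):
        comp = sq.StandardComponent(name="ethene", reagent_label="O2+",
                                    product_mz=28, k=0.68e-9)
        assert compute_icf_anchor(comp, 123.0, 6e6, 6e-3, **STATE) == 1.0

    def test_zero_reagent_signal_errors(self):
        with pytest.raises(ValueError, match="reagent"):
            compute_icf_anchor(self.comp, 1000.0, 0.0, 6e-3, **STATE)

    def test_anchors_recover_injected_transmission(self, truth, standard, lib,
                                                   check_result):
        for mz, g in truth.g.anchors.items():
            got = check_result.icf_curve.anchors.get(mz)
            assert got is not None, f"anchor {mz} missing"
            assert got == pytest.approx(g, rel=1e-9), f"anchor {mz}"


class TestLowMassIcf:
    def _signals(self, g19, lib, truth, standard):
        """Analytic benzene/toluene dual-reagent signals for a given g(19)."""
        t, frames = truth, sq.simulate_performance_check(
            truth.model_copy(update={"g": self._curve(g19)}), standard, lib)
        return frames

    @staticmethod
    def _curve(g19):
        anchors = {19: g19, 28: 1.0, 32: 1.0, 78: 1.0, 92: 1.0, 114: 1.0,
                   150: 1.0, 186: 1.0, 236: 1.0, 400: 1.0}
        anchors.update({-m: v for m, v in anchors.items() if m >= 28})
        anchors.update({-17: 1.0, -16: 1.0})
        return sq.ICFCurve(anchors=anchors)

    def _recover(self, g19, truth, standard, lib):
        frames = self._signals(g19, lib, truth, standard)
        res = sq.run_performance_check(
            frames, standard, P_g=truth.P_g, T_g=truth.T_g,
            phi_c=truth.phi_c, phi_s=truth.phi_s,
            attenuation_factor=truth.attenuation_factor)
        return res.icf_curve.anchors[19]

    def test_flat_transmission_returns_one(self, truth, standard, lib):
        assert self._recover(1.0, truth, standard, lib) == pytest.approx(
            1.0, abs=1e-9)

    def test_recovers_injected_low_mass_value(self, truth, standard, lib):
        assert self._recover(0.5, truth, standard, lib) == pytest.approx(
            0.5, abs=1e-9)

    def test_benzene_and_toluene_solutions_agree(self, truth, standard, lib):
        t = truth.model_copy(update={"g": self._curve(0.7)})
        frames = sq.simulate_performance_check(t, standard, lib)
        partial = sq.ICFCurve(anchors={28: 1.0, 32: 1.0, 78: 1.0, 92: 1.0,
                                       114: 1.0, 150: 1.0, 186: 1.0, 236: 1.0})
        values = []
        for rxn in [r for r in standard.low_mass if r.reagent_mz == 19]:
            P = next(rec for f in frames for rec in f.records
                     if rec.mz == rxn.product_mz)
            R = next(rec for f in frames for rec in f.records
                     if rec.role == "reagent" and rec.ion_label == "H3O+")
            values.append(solve_reagent_icf(
                rxn, P.cps, R.cps * t.attenuation_factor, partial, t.t_r_true,
                t.P_g, t.T_g, t.phi_c, t.phi_s))
        assert values[0] == pytest.approx(values[1], abs=1e-9)

    def test_missing_signals_error(self, standard):
        partial = sq.ICFCurve(anchors={28: 1.0, 32: 1.0, 78: 1.0, 92: 1.0})
        rxns = [r for r in standard.low_mass if r.reagent_mz == 19]
        with pytest.raises(ValueError, match="missing"):
            sq.compute_low_mass_icf(rxns, {}, partial, 6e-3, **STATE)


class TestCurveAssembly:
    def test_all_unity_anchors_give_identity_curve(self):
        anchors = {19: 1.0, 28: 1.0, 32: 1.0, 78: 1.0, 92: 1.0, 114: 1.0,
                   150: 1.0, 186: 1.0, 236: 1.0}
        curve = build_icf_curve(anchors, {-17: 1.0, -16: 1.0})
        for mz in (10, 19, 45, 107, 236, 400, -16, -30, -150, -400):
            assert curve.lookup(mz) == pytest.approx(1.0)

    def test_endpoint_extrapolated_from_186_and_236(self):
        anchors = {19: 1.0, 28: 1.0, 32: 1.0, 78: 1.0, 92: 1.0, 114: 1.0,
                   150: 1.5, 186: 2.0, 236: 3.0}
        curve = build_icf_curve(anchors, {-17: 1.0, -16: 1.0})
        assert curve.anchors[400] == pytest.approx(
            2.0 + (3.0 - 2.0) / (236 - 186) * (400 - 186))
        assert curve.anchors[400] == pytest.approx(6.28)

    def test_negative_side_mirrors_positive(self, check_result):
        curve = check_result.icf_curve
        for mz in (78, 114, 150, 236, 300, 400):
            assert curve.lookup(-mz) == pytest.approx(curve.lookup(mz))

    def test_missing_anchor_listed(self):
        anchors = {28: 1.0, 32: 1.0, 78: 1.2, 92: 1.3, 186: 2.0, 236: 3.0}
        with pytest.raises(ValueError, match="150"):
            build_icf_curve(anchors, required=[78, 92, 114, 150, 186, 236])

    def test_anchor_order_irrelevant(self):
        anchors = {19: 1.4, 28: 1.0, 32: 1.0, 78: 1.3, 92: 1.5, 114: 1.8,
                   150: 2.4, 186: 3.2, 236: 4.4}
        shuffled = dict(reversed(list(anchors.items())))
        c1 = build_icf_curve(anchors, {-17: 1.3, -16: 1.2})
        c2 = build_icf_curve(shuffled, {-17: 1.3, -16: 1.2})
        assert c1.anchors == c2.anchors


class TestLookup:
    curve = sq.ICFCurve(anchors={19: 1.0, 28: 1.0, 32: 1.0, 50: 1.0,
                                 100: 2.0, 400: 2.0, -50: 1.0, -400: 1.0})

    def test_midpoint_interpolation(self):
        assert self.curve.lookup(75) == pytest.approx(1.5)

    def test_exact_at_anchor(self):
        assert self.curve.lookup(100) == 2.0

    def test_plateau_is_one_regardless_of_anchors(self):
        odd = sq.ICFCurve(anchors={27: 5.0, 33: 5.0, 400: 5.0})
        assert odd.lookup(30) == 1.0

    def test_out_of_range_rejected(self):
        for mz in (5, 401, -401, 0):
            with pytest.raises(ValueError):
                self.curve.lookup(mz)


class TestShapeDiagnostics:
    def test_identity_curve_clean(self):
        anchors = {19: 1.0, 28: 1.0, 32: 1.0, 78: 1.0, 92: 1.0, 114: 1.0,
                   150: 1.0, 186: 1.0, 236: 1.0}
        curve = build_icf_curve(anchors, {-17: 1.0, -16: 1.0})
        assert check_icf_shape(curve) == []

    def test_spike_flagged_by_mz(self):
        anchors = {19: 1.0, 28: 1.0, 32: 1.0, 78: 1.0, 92: 100.0, 114: 1.0,
                   150: 1.0, 186: 1.0, 236: 1.0}
        curve = build_icf_curve(anchors, {-17: 1.0, -16: 1.0})
        assert any("92" in d for d in check_icf_shape(curve))

    def test_extreme_low_mass_anchor_flagged(self):
        anchors = {19: 40.0, 28: 1.0, 32: 1.0, 78: 1.0, 92: 1.0, 114: 1.0,
                   150: 1.0, 186: 1.0, 236: 1.0}
        curve = build_icf_curve(anchors, {-17: 1.0, -16: 1.0})
        assert any("19" in d and "low-mass" in d for d in check_icf_shape(curve))

    def test_realistic_check_is_clean(self, check_result):
        shape = [d for d in check_result.diagnostics if "density" not in d]
        assert shape == []


class TestNoisyCalibration:
    def test_anchor_scatter_follows_poisson_propagation(self, standard, lib):
        """Over 200 noisy checks the mean anchor is unbiased within 3x the
        propagated counting SE of the mean, and the scatter matches."""
        mz = 186
        comp = standard.component("hexafluorobenzene")
        values = []
        for seed in range(200):
            t = sq.default_truth(seed=seed, concentrations={})
            frames = sq.simulate_performance_check(t, standard, lib,
                                                   noise=True)
            res = sq.run_performance_check(
                frames, standard, P_g=t.P_g, T_g=t.T_g, phi_c=t.phi_c,
                phi_s=t.phi_s, attenuation_factor=t.attenuation_factor)
            values.append(res.icf_curve.anchors[mz])
        truth0 = sq.default_truth(seed=0, concentrations={})
        quiet = sq.simulate_performance_check(truth0, standard, lib,
                                              noise=False)
        # the O2+ reagent record cancels between the t_r and anchor
        # equations, leaving the two product-ion counts
        P = next(r for f in quiet for r in f.records
                 if r.mz == mz and r.role == "primary")
        P28 = next(r for f in quiet for r in f.records
                   if r.mz == 28 and r.role == "primary")
        g_true = truth0.g.anchors[mz]
        se_single = g_true * np.sqrt(1 / P.counts + 1 / P28.counts)
        values = np.array(values)
        assert abs(values.mean() - g_true) <= 3 * se_single / np.sqrt(len(values))
        assert values.std(ddof=1) == pytest.approx(se_single, rel=0.35)
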