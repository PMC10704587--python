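"""Counts -> ppbv chain: count rates, attenuation, per-ion densities,
dilution conversion and tolerance reporting."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import siftquant as sq
from siftquant.quantitation import (apply_attenuation, count_rate,
                                    makeup_correct, number_density_general,
                                    number_density_per_ion, poisson_se,
                                    to_ppbv, tolerance_report)


class TestCountOps:
    @pytest.mark.parametrize("counts,dwell,cps", [
        (5000, 0.05, 100000.0), (0, 0.1, 0.0), (1234, 0.1, 12340.0)])
    def test_count_rate(self, counts, dwell, cps):
        assert count_rate(counts, dwell) == cps

    def test_count_rate_needs_positive_dwell(self):
        with pytest.raises(ValueError):
            count_rate(10, 0.0)

    def test_attenuation(self):
        assert apply_attenuation(1e5, 100.0) == 1e7
        assert apply_attenuation(1e5, 1.0) == 1e5
        with pytest.raises(ValueError, match="reagent"):
            apply_attenuation(1e5, 100.0, role="primary")

    @pytest.mark.parametrize("counts,se", [(100, 10.0), (0, 0.0), (2500, 50.0)])
    def test_poisson_se(self, counts, se):
        assert poisson_se(counts) == se


def _minimal_frame(P_cps, R_cps, dwell=1.0):
    """One reagent + one product record, identity ICF, no hydrates."""
    return sq.ScanFrame(records=[
        sq.SIMRecord(ion_label="O2+", mz=32, counts=R_cps * dwell,
                     dwell=dwell, role="reagent"),
        sq.SIMRecord(ion_label="benzene/O2+@78", mz=78, counts=P_cps * dwell,
                     dwell=dwell, role="primary", reagent_label="O2+",
                     analyte_id="benzene"),
    ])


@pytest.fixture()
def flat_state():
    return sq.InstrumentState(
        t_r=6e-3, icf_curve=sq.ICFCurve(anchors={10: 1.0, 400: 1.0,
                                                 -10: 1.0, -400: 1.0}),
        P_g=0.46, T_g=393.15, phi_c=2.0, phi_s=0.3, attenuation_factor=1.0)


class TestNumberDensity:
    def test_zero_product_signal_gives_zero(self, lib, flat_state):
        frame = _minimal_frame(0.0, 1e6)
        ch = lib.channels_for("benzene", "O2+")[0]
        assert number_density_per_ion(frame, ch, lib, flat_state) == 0.0

    def test_constructed_ratio_recovers_density(self, lib, flat_state):
        # P/R = k [M*] t_r by construction; inversion returns [M*] exactly
        ch = lib.channels_for("benzene", "O2+")[0]
        M_star = 3.0e8
        frame = _minimal_frame(1e6 * ch.k * M_star * flat_state.t_r, 1e6)
        got = number_density_per_ion(frame, ch, lib, flat_state)
        assert got == pytest.approx(M_star, rel=1e-9)

    def test_zero_reagent_signal_errors(self, lib, flat_state):
        frame = _minimal_frame(100.0, 0.0)
        ch = lib.channels_for("benzene", "O2+")[0]
        with pytest.raises(ValueError, match="reagent"):
            number_density_per_ion(frame, ch, lib, flat_state)

    def test_dropping_secondary_lowers_reading(self, lib, truth, state):
        """Ethanol via H3O+ (water-adduct secondary at m/z 65): removing the
        secondary record strictly lowers the per-ion density and warns."""
        frame = sq.simulate_frame(truth, lib, ["ethanol"], noise=False)
        ch = lib.channels_for("ethanol", "H3O+")[0]
        full = number_density_per_ion(frame, ch, lib, state)
        pruned = sq.ScanFrame(records=[r for r in frame.records if r.mz != 65],
                              instrument=frame.instrument)
        with pytest.warns(UserWarning, match="false low"):
            partial = number_density_per_ion(pruned, ch, lib, state)
        assert partial < full

    def test_general_reduces_to_per_ion_for_single_channel(self, lib,
                                                           flat_state):
        ch = lib.channels_for("benzene", "O2+")[0]
        frame = _minimal_frame(5000.0, 1e6)
        per = number_density_per_ion(frame, ch, lib, flat_state)
        gen = number_density_general(frame, lib.analyte("benzene"), lib,
                                     flat_state, "O2+")
        assert gen == pytest.approx(per, rel=1e-12)

    def test_general_on_consistent_channels_matches_per_ion(self, lib, truth,
                                                            state):
        # NDMA via O2+ has two channels (Rb 0.95/0.05) fed consistently
        frame = sq.simulate_frame(truth, lib, ["NDMA"], noise=False)
        analyte = lib.analyte("NDMA")
        per = [number_density_per_ion(frame, ch, lib, state)
               for ch in lib.channels_for("NDMA", "O2+")]
        gen = number_density_general(frame, analyte, lib, state, "O2+")
        assert per[0] == pytest.approx(per[1], rel=1e-9)
        assert gen == pytest.approx(per[0], rel=1e-9)

    def test_general_lies_between_inconsistent_per_ion_values(self, lib, truth,
                                                              state):
        frame = sq.simulate_frame(truth, lib, ["NDMA"], noise=False)
        # inflate the minor O2+ channel (m/z 44) two-fold
        records = [r.model_copy(update={"counts": r.counts * 2})
                   if r.mz == 44 else r for r in frame.records]
        frame2 = sq.ScanFrame(records=records, instrument=frame.instrument)
        per = sorted(number_density_per_ion(frame2, ch, lib, state)
                     for ch in lib.channels_for("NDMA", "O2+"))
        gen = number_density_general(frame2, lib.analyte("NDMA"), lib, state,
                                     "O2+")
        assert per[0] < gen < per[1]


class TestPpbvConversion:
    def test_zero_density(self, flat_state):
        assert to_ppbv(0.0, flat_state) == 0.0

    def test_dilution_scaling(self, flat_state):
        more_carrier = flat_state.model_copy(update={"phi_c": 4.0})
        base = to_ppbv(1e8, flat_state)
        assert to_ppbv(1e8, more_carrier) == pytest.approx(
            base * (4.0 + 0.3) / (2.0 + 0.3))

    def test_simulator_round_trip_100_ppbv(self, lib, flat_truth):
        frame = sq.simulate_frame(flat_truth, lib, ["benzene"], noise=False)
        state = sq.instrument_state_from_truth(flat_truth)
        r = sq.quantify_analyte(frame, "benzene", lib, state)
        assert r.reported == pytest.approx(100.0, rel=1e-6)

    def test_makeup_correction(self, flat_state):
        s = flat_state.model_copy(update={"makeup_dilution": 11.0})
        assert makeup_correct(10.0, s) == pytest.approx(110.0)
        assert makeup_correct(10.0, flat_state) == 10.0
        with pytest.raises(ValueError):
            sq.InstrumentState(t_r=6e-3, icf_curve=flat_state.icf_curve,
                               P_g=0.46, T_g=393.15, phi_c=2.0, phi_s=0.3,
                               makeup_dilution=-2.0)


class TestToleranceRule:
    def test_documented_example(self):
        reported, used, rejected = tolerance_report({"A": 10.0, "B": 11.0,
                                                     "C": 13.0})
        assert reported == pytest.approx(10.5)
        assert sorted(used) == ["A", "B"] and rejected == ["C"]

    def test_single_ion(self):
        assert tolerance_report({"A": 7.0})[0] == 7.0

    def test_equal_inputs(self):
        reported, used, rejected = tolerance_report({"A": 5.0, "B": 5.0})
        assert reported == 5.0 and rejected == []

    def test_boundary_is_inclusive(self):
        reported, used, _ = tolerance_report({"A": 10.0, "B": 12.0})
        assert sorted(used) == ["A", "B"] and reported == 11.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            tolerance_report({})

    @settings(max_examples=100, deadline=None)
    @given(st.dictionaries(st.sampled_from("ABCDEF"),
                           st.floats(0.0, 1e6), min_size=1))
    def test_reported_never_exceeds_tolerance_band(self, per_ion):
        reported, used, _ = tolerance_report(per_ion)
        assert used
        assert reported <= 1.2 * min(per_ion.values()) + 1e-9


class TestStatisticalProperties:
    def test_end_to_end_linearity(self, lib, standard):
        """Reported ppbv is linear through the origin over 1-1000 ppbv on
        noise-free simulations (constant response ratio)."""
        ratios = []
        for c in (1.0, 10.0, 100.0, 1000.0):
            t = sq.default_truth(seed=3, concentrations={"benzene": c})
            frame = sq.simulate_frame(t, lib, ["benzene"], noise=False)
            state = sq.instrument_state_from_truth(t)
            ratios.append(sq.quantify_analyte(frame, "benzene", lib,
                                              state).reported / c)
        assert np.ptp(ratios) < 1e-9 * ratios[0]

    def test_poisson_scatter_matches_propagated_se(self, lib):
        """Over 500 noisy simulations at fixed truth the empirical SD of the
        reported value matches the propagated sqrt(N) SE within 20%."""
        base = sq.default_truth(seed=0, concentrations={"benzene": 100.0},
                                hydrate_fractions={})
        state = sq.instrument_state_from_truth(base)
        quiet = sq.simulate_frame(base, lib, ["benzene"], noise=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            se_prop = sq.quantify_analyte(quiet, "benzene", lib, state,
                                          ions=["O2+@78"]).se
        values = []
        for seed in range(500):
            t = base.model_copy(update={"seed": seed})
            frame = sq.simulate_frame(t, lib, ["benzene"], noise=True)
            values.append(sq.quantify_analyte(frame, "benzene", lib, state,
                                              ions=["O2+@78"]).reported)
        sd = float(np.std(values, ddof=1))
        assert sd == pytest.approx(se_prop, rel=0.2)
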