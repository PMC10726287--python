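"""Synapse placement, conductance kinetics, unitary calibration."""

import numpy as np
import pytest

from vmthal import morphology as M
from vmthal import simulate as S
from vmthal import synapses as SY


@pytest.fixture(scope="module")
def groups(ref_tree):
    return SY.build_groups(ref_tree, seed=7)


class TestPlacement:
    def test_determinism(self, ref_tree):
        a = SY.build_groups(ref_tree, seed=3)
        b = SY.build_groups(ref_tree, seed=3)
        for name in a:
            assert a[name].terminals == b[name].terminals

    def test_dri_is_ten_percent_of_mod(self, groups):
        ratio = len(groups["DRI-l"].terminals) / len(groups["MOD"].terminals)
        assert ratio == pytest.approx(0.10, abs=0.005)

    def test_mod_active_fraction(self, groups):
        g = groups["MOD"]
        assert g.n_active == pytest.approx(0.4 * len(g.terminals), abs=1.0)

    def test_totals_scale_with_dendritic_length(self, ref_tree):
        small = M.build_cell(M.synth_skeleton(11, n_primary=3, max_depth=2))
        gs = SY.build_groups(small, seed=1)
        gl = SY.build_groups(ref_tree, seed=1)
        ls = sum(c.length for c in small.compartments
                 if c.region in ("dend", "primary_dend"))
        ll = sum(c.length for c in ref_tree.compartments
                 if c.region in ("dend", "primary_dend"))
        for name in ("MOD", "RTN", "SNR"):
            expected = len(gl[name].terminals) * ls / ll
            assert len(gs[name].terminals) == pytest.approx(
                expected, abs=max(3.0, 0.1 * expected))

    def test_reference_full_scale_totals(self):
        # at the reference dendritic length the printed totals are recovered
        for name, rule in SY.default_rules().items():
            if name == "DRI-l":
                continue
            assert rule.ref_total == SY.REF_TOTALS[name]
        assert round(SY.REF_TOTALS["MOD"] * SY.MOD_ACTIVE_FRACTION) == 1450

    def test_snr_spacing_and_somatic_terminals(self, ref_tree, groups):
        rules = SY.default_rules()
        assert rules["SNR"].sampling_spacing == 2.8
        assert rules["MOD"].sampling_spacing == 0.8
        assert rules["RTN"].sampling_spacing == 0.8
        soma_id = next(c.id for c in ref_tree.compartments
                       if c.region == "soma")
        n_soma = sum(1 for t in groups["SNR"].terminals if t == soma_id)
        assert n_soma == round(0.2 * len(groups["SNR"].terminals))

    def test_treeless_placement_rejected(self):
        bare = M.MorphTree([M.SkeletonNode(0, None, "soma")])
        bare.compartments = []
        with pytest.raises(ValueError):
            SY.place_synapses(bare, SY.default_rules()["MOD"], 0)


class TestConductanceWaveforms:
    def test_gaba_decay_q10_scaled(self):
        t = np.arange(0.0, 120.0, 0.01)
        g = SY.synaptic_conductance(SY.KINETICS["SNR"], [0.0], t, 37.0)
        tau_expected = 14.0 / (2.1 ** 0.5)  # ~9.66 ms at 37 degC
        k = np.argmin(np.abs(t - tau_expected))
        assert g.max() == pytest.approx(1.0, abs=1e-6)
        assert g[k] == pytest.approx(np.exp(-1.0), abs=0.01)

    def test_nmda_ampa_peak_ratio(self):
        t = np.arange(0.0, 300.0, 0.01)
        for name, ratio in (("MOD", 1.91), ("DRI-l", 0.6)):
            ga, gn = SY.synaptic_conductance(SY.KINETICS[name], [0.0], t,
                                             34.0, g_unit=2.0)
            assert ga.max() == pytest.approx(2.0, rel=1e-3)
            assert gn.max() / ga.max() == pytest.approx(ratio, rel=1e-3)

    def test_events_sum_linearly(self):
        t = np.arange(0.0, 200.0, 0.01)
        kin = SY.KINETICS["RTN"]
        one = SY.synaptic_conductance(kin, [50.0], t, 32.0)
        two = SY.synaptic_conductance(kin, [50.0, 50.0], t, 32.0)
        assert np.allclose(two, 2.0 * one)


class TestCalibration:
    def test_psc_monotone_in_unitary_conductance(self, normal_cell, groups):
        cond = S.CONDITIONS["b26"]
        group = groups["SNR"]
        terms = [group.terminals[0]]
        amps = []
        for g_unit in (1.0, 4.0, 16.0):
            ev = [(0.0, terms[0], group.group_index, g_unit)]
            res = S.run_voltage_clamp(normal_cell, -64.0, cond, events=ev,
                                      t_end=120.0)
            amps.append(abs(S.psc_amplitude(res)))
        assert amps[0] < amps[1] < amps[2]

    def test_calibration_converges_and_is_idempotent(self, normal_cell,
                                                     groups):
        group = groups["SNR"]
        g1 = SY.calibrate_group(normal_cell, group, seed=0)
        cond_name, v_cmd, e_gaba, n_act, target = SY.CALIBRATION_TARGETS["SNR"]
        ev = [(0.0, group.terminals[0], group.group_index, g1)]
        # recalibrating from the recovered value reproduces the target PSC
        g2 = SY.calibrate_unitary_conductance(
            normal_cell, group, target, S.CONDITIONS[cond_name], v_cmd,
            n_active=n_act, seed=0)
        assert g2 == pytest.approx(g1, rel=0.05)

    def test_unreachable_target_raises(self, normal_cell, groups):
        with pytest.raises(RuntimeError, match="unreachable"):
            SY.calibrate_unitary_conductance(
                normal_cell, groups["SNR"], 1e6, S.CONDITIONS["b26"],
                -64.0, g_bracket=(1e-3, 1.0))

    def test_dri_target_is_depression_scaled(self):
        # 75% of the published 165-pA driver EPSC
        assert SY.CALIBRATION_TARGETS["DRI-l"][4] == pytest.approx(
            0.75 * 165.0, abs=0.05)
        assert SY.CALIBRATION_TARGETS["DRI-l"][3] == 4


class TestEvents:
    def test_make_events_requires_matching_counts(self, ref_tree, groups):
        with pytest.raises(ValueError):
            SY.make_events({"SNR": groups["SNR"]}, {"SNR": []}, rng=0)

    def test_make_events_sorted_and_complete(self, groups):
        n = groups["SNR"].n_active
        trains = {"SNR": [np.array([0.01 * k]) for k in range(n)]}
        ev = SY.make_events({"SNR": groups["SNR"]}, trains, rng=1)
        times = [e[0] for e in ev]
        assert times == sorted(times)
        assert len(ev) == n
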