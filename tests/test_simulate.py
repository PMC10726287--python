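"""Cable-solver correctness: closed forms, charge balance, convergence."""

import math

import numpy as np
import pytest

from vmthal import biophysics as B
from vmthal import morphology as M
from vmthal import simulate as S

from conftest import make_passive_params, two_comp_tree


def soma_only_cell(g_leak=50.0, v_rest=-70.0):
    tree = two_comp_tree()
    tree.compartments = tree.compartments[:1]
    return S.compile_cell(tree, make_passive_params(g_leak=g_leak,
                                                    v_rest=v_rest))


def passive_condition(**kw):
    return S.SimCondition("passive", temperature=34.0, **kw)


class TestPassiveClosedForms:
    def test_rc_charging_single_compartment(self):
        cell = soma_only_cell(g_leak=50.0)
        area = cell.area[0]
        amp_pa = 20.0
        res = S.integrate(cell, passive_condition(), 200.0,
                          pulses=[(0.0, 200.0, amp_pa)], rec_stride=1)
        g = 50.0e-6                      # S/cm2
        tau = 1e-3 / g                   # ms, c_m = 1 uF/cm2
        dv_inf = amp_pa * 1e-12 / (g * area) * 1e3  # mV
        t = res.t_full
        analytic = -70.0 + dv_inf * (1.0 - np.exp(-t / tau))
        # within 1% of the step amplitude everywhere on the trace
        assert np.max(np.abs(res.v_soma - analytic)) < 0.01 * dv_inf

    def test_two_compartment_steady_state(self, passive_two_comp):
        cell = passive_two_comp
        amp_pa = 50.0
        res = S.integrate(cell, passive_condition(), 400.0,
                          pulses=[(0.0, 400.0, amp_pa)], rec_stride=4)
        # analytic two-node resistive network
        g = 50.0e-6
        G1, G2 = g * cell.area[0], g * cell.area[1]     # S
        gc = cell.g_pair[1]
        lhs = np.array([[G1 + gc, -gc], [-gc, G2 + gc]])
        rhs = np.array([amp_pa * 1e-12, 0.0])           # A
        dv = np.linalg.solve(lhs, rhs) * 1e3            # mV
        assert res.v[-1][0] == pytest.approx(-70.0 + dv[0], abs=abs(dv[0]) * 0.01)
        assert res.v[-1][1] == pytest.approx(-70.0 + dv[1], abs=abs(dv[0]) * 0.01)

    def test_resting_cell_stays_at_rest(self, passive_two_comp):
        res = S.integrate(passive_two_comp, passive_condition(), 100.0)
        assert np.max(np.abs(res.v_soma + 70.0)) < 1e-6


class TestChargeBalance:
    def test_residual_below_tolerance_active_model(self, normal_cell):
        res = S.integrate(normal_cell, S.CONDITIONS["b8"], 100.0,
                          pulses=[(10.0, 90.0, 150.0)])
        assert res.resid_max < 1e-6

    def test_residual_with_synaptic_events(self, normal_cell):
        dend = [c.id for c in normal_cell.tree.compartments
                if c.region == "dend"][:3]
        events = [(5.0 * k, c, g, 2.0) for k, c in enumerate(dend, 1)
                  for g in (0, 2)]
        res = S.integrate(normal_cell, S.CONDITIONS["invivo"], 60.0,
                          events=events)
        assert res.resid_max < 1e-6


class TestConvergence:
    def test_dt_halving_changes_endpoint_below_tenth_mv(self, normal_cell):
        cond = S.CONDITIONS["b8"]
        pulses = [(0.0, 100.0, -10.0)]  # brief hyperpolarizing probe
        v_end = []
        for dt in (0.025, 0.0125):
            res = S.integrate(normal_cell, cond, 150.0, dt=dt, pulses=pulses)
            v_end.append(res.v_soma[-1])
        assert abs(v_end[0] - v_end[1]) < 0.1

    def test_dt_bounds_enforced(self, normal_cell):
        with pytest.raises(ValueError):
            S.integrate(normal_cell, S.CONDITIONS["b8"], 1.0, dt=0.1)


class TestSpikeDetection:
    def test_subthreshold_trace_empty(self):
        v = np.full(1000, -60.0)
        assert S.detect_spikes(v, 0.025).size == 0

    def test_single_crossing(self):
        v = np.full(1000, -60.0)
        v[400:420] = 10.0
        t = S.detect_spikes(v, 0.025)
        assert t.size == 1
        assert t[0] == pytest.approx(400 * 0.025, abs=0.05)

    def test_double_crossing_within_refractory_merged(self):
        v = np.full(2000, -60.0)
        v[400:410] = 10.0   # two bumps 0.25 ms apart
        v[420:430] = 10.0
        assert S.detect_spikes(v, 0.025, min_interval=1.0).size == 1
        assert S.detect_spikes(v, 0.025, min_interval=0.2).size == 2


class TestBlockers:
    def test_ttx_silences_p1_step(self, normal_cell):
        from dataclasses import replace
        cond = replace(S.CONDITIONS["b8"], blockers=frozenset({"TTX"}),
                       bias_current=93.0)
        res = S.integrate(normal_cell, cond, 500.0,
                          pulses=[(0.0, 500.0, 300.0)])
        assert res.spikes.size == 0

    def test_cesium_silences_potassium_currents(self, normal_cell):
        from dataclasses import replace
        base = S.integrate(normal_cell, S.CONDITIONS["b8"], 100.0)
        cs = replace(S.CONDITIONS["b8"],
                     blockers=frozenset({"TTX", "cesium"}))
        res = S.integrate(normal_cell, cs, 100.0)
        for name in ("KDR", "KA", "KD", "KM", "SK", "BK"):
            assert np.allclose(res.i_channel[name], 0.0)
        assert not np.allclose(base.i_channel["KM"], 0.0)


class TestVoltageClamp:
    def test_clamp_at_reversal_gives_zero_psc(self):
        cell = soma_only_cell()
        res = S.run_voltage_clamp(cell, -81.0, passive_condition(),
                                  events=[(0.0, 0, 2, 5.0)])
        assert abs(S.psc_amplitude(res)) < 0.5  # pA

    def test_ohmic_psc_on_passive_soma(self):
        cell = soma_only_cell()
        v_cmd, g_unit = -60.0, 3.0
        res = S.run_voltage_clamp(cell, v_cmd, passive_condition(),
                                  events=[(0.0, 0, 2, g_unit)])
        expected = g_unit * (v_cmd - S.E_GABA)  # nS * mV = pA
        assert S.psc_amplitude(res) == pytest.approx(expected, rel=0.02)

    def test_command_bounds(self, normal_cell):
        with pytest.raises(ValueError):
            S.run_voltage_clamp(normal_cell, 80.0, S.CONDITIONS["b26"])


class TestProtocols:
    def test_p1_definition(self):
        p = S.protocol("P1", "normal")
        assert p.step_amplitudes == tuple(range(20, 301, 20))
        assert p.step_duration == 2000.0
        assert p.bias == 93.0
        assert S.protocol("P1", "parkinsonian").bias == 67.0

    def test_p4_p5_definitions(self):
        p4 = S.protocol("P4")
        assert p4.step_amplitudes == (-1000.0,) and p4.step_duration == 0.5
        p5 = S.protocol("P5")
        assert p5.step_amplitudes == (-10.0,) and p5.step_duration == 100.0

    def test_save_load_round_trip(self, normal_cell, tmp_path):
        res = S.integrate(normal_cell, S.CONDITIONS["b8"], 20.0)
        path = tmp_path / "trace.npz"
        res.save(path)
        back = S.SimResult.load(path)
        assert np.allclose(back.v_soma, res.v_soma)
        assert np.allclose(back.i_channel["KM"], res.i_channel["KM"])
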