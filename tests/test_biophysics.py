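"""Parameters, electro-diffusion relations, Ca shells, channel distributions."""

import numpy as np
import pytest

from vmthal import biophysics as B
from vmthal import kinetics as K


class TestQ10:
    def test_reference_temperature_identity(self):
        assert B.q10_factor(32.0, 32.0, 2.5) == 1.0

    def test_one_decade(self):
        assert B.q10_factor(42.0, 32.0, 2.5) == pytest.approx(2.5)

    def test_half_decade(self):
        assert B.q10_factor(37.0, 32.0, 2.1) == pytest.approx(2.1 ** 0.5)


class TestNernst:
    def test_equal_concentrations(self):
        assert B.nernst_potential(1, 10.0, 10.0, 37.0) == 0.0

    def test_tenfold_gradient_body_temperature(self):
        # RT/F ln10 at 310.15 K
        assert B.nernst_potential(1, 1.0, 10.0, 37.0) == pytest.approx(
            61.5, abs=0.2)

    def test_divalent_halves(self):
        e1 = B.nernst_potential(1, 1.0, 10.0, 30.0)
        e2 = B.nernst_potential(2, 1.0, 10.0, 30.0)
        assert e2 == pytest.approx(e1 / 2.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            B.nernst_potential(1, 0.0, 10.0, 37.0)


class TestGHK:
    def test_zero_flux_at_nernst(self):
        e = B.ghk_ca_reversal(1e-4, 2.0, 34.0)
        assert B.ghk_flux(e, 1e-4, 2.0, 34.0) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_zero_at_zero_volt(self):
        assert B.ghk_flux(0.0, 2.0, 2.0, 34.0) == pytest.approx(0.0,
                                                               abs=1e-12)

    def test_inward_at_rest_with_gradient(self):
        assert B.ghk_flux(-70.0, 5e-5, 2.0, 34.0) < 0.0

    def test_raising_internal_ca_reduces_inward_flux(self):
        fluxes = [B.ghk_flux(-60.0, ci, 2.0, 34.0)
                  for ci in (5e-5, 5e-4, 5e-3, 5e-2)]
        assert all(a < b for a, b in zip(fluxes, fluxes[1:]))


class TestCalciumShell:
    def test_exponential_relaxation(self):
        dom = B.CaMicrodomain("T", tau=52.7, delta=17.19)
        dom.current_ca = 1e-3
        B.update_calcium(dom, 0.0, 52.7)  # one time constant
        expected = B.CA_REST + (1e-3 - B.CA_REST) * np.exp(-1.0)
        assert dom.current_ca == pytest.approx(expected, rel=1e-9)

    def test_constant_current_steady_state(self):
        dom = B.CaMicrodomain("L1", tau=31.0, delta=2.2)
        i = -1e-3  # inward
        for _ in range(int(31.0 * 20)):
            B.update_calcium(dom, i, 1.0)
        expected = B.CA_REST + B.CA_UNIT * 2.2 * abs(i) * 31.0
        assert dom.current_ca == pytest.approx(expected, rel=1e-3)

    def test_published_l2_decay_constant(self):
        p = B.canonical_params("normal")
        assert p.ca_domains["L2"].tau == pytest.approx(1639.33)


class TestCanonicalParams:
    def test_published_values(self):
        n = B.canonical_params("normal")
        p = B.canonical_params("parkinsonian")
        assert n.channels["KM"].g == pytest.approx(306.76)
        assert p.channels["KM"].g == pytest.approx(9.69)
        assert n.r_i == pytest.approx(156.35)
        assert n.c_m == 1.0 and p.c_m == 1.0

    def test_km_fold_ratio_rounds_to_32(self):
        n = B.canonical_params("normal")
        p = B.canonical_params("parkinsonian")
        assert round(n.channels["KM"].g / p.channels["KM"].g) == 32

    def test_serialization_keys(self):
        doc = B.canonical_params("normal").to_dict()
        assert doc["KM"]["T_m"] == pytest.approx(8.86)
        assert doc["CaL"]["p_1"] == pytest.approx(93.78)
        assert doc["Ca_buffer"]["L2"]["tau"] == pytest.approx(1639.33)

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError):
            B.canonical_params("lesioned")


class TestXE991:
    def test_seventy_percent_block(self):
        p = B.canonical_params("normal")
        p.channels["KM"].g = 100.0
        b = B.apply_xe991(p)
        assert b.channels["KM"].g == pytest.approx(30.0)
        assert B.apply_xe991(b).channels["KM"].g == pytest.approx(9.0)

    def test_other_channels_untouched(self):
        p = B.canonical_params("normal")
        b = B.apply_xe991(p)
        for name in B.CHANNEL_NAMES:
            if name != "KM":
                assert b.channels[name].g == p.channels[name].g


@pytest.fixture(scope="module")
def dmap(ref_tree):
    params = B.canonical_params("normal")
    return params, B.apply_distribution(params, ref_tree), ref_tree


class TestDistribution:
    def test_kdr_uniform_somatodendritic(self, dmap):
        params, d, tree = dmap
        i = d.channel_index["KDR"]
        vals = [d.g[i, c.id] for c in tree.compartments
                if c.region in ("soma", "dend", "primary_dend")]
        assert np.allclose(vals, params.channels["KDR"].g * B.UNIT_SCALE)

    def test_cat_doubled_on_primary_halved_elsewhere(self, dmap):
        params, d, tree = dmap
        i = d.channel_index["CaT"]
        soma = next(c for c in tree.compartments if c.region == "soma")
        g_soma = d.g[i, soma.id]
        for c in tree.compartments:
            if c.region == "primary_dend":
                assert d.g[i, c.id] == pytest.approx(2.0 * g_soma)
            elif c.region == "dend":
                assert d.g[i, c.id] == pytest.approx(0.5 * g_soma)

    def test_ih_absent_in_ais(self, dmap):
        _, d, tree = dmap
        i = d.channel_index["IH"]
        for c in tree.compartments:
            if c.region.startswith("ais"):
                assert d.g[i, c.id] == 0.0

    def test_sk_bk_follow_cal_profile_and_absent_in_axon(self, dmap):
        params, d, tree = dmap
        for name in ("SK", "BK"):
            i = d.channel_index[name]
            for c in tree.compartments:
                if c.region.startswith("ais"):
                    assert d.g[i, c.id] == 0.0
                elif c.region == "dend":
                    assert d.g[i, c.id] == pytest.approx(
                        params.channels[name].g * B.UNIT_SCALE / 3.0)

    def test_na_attenuates_with_branch_depth(self, dmap):
        _, d, tree = dmap
        i = d.channel_index["NaT"]
        depth = {n.id: n.branch_depth for n in tree.nodes}
        for c in tree.compartments:
            if c.region in ("primary_dend", "dend"):
                expected = (6235.45 * B.UNIT_SCALE
                            * 0.5 ** depth[c.section_id])
                assert d.g[i, c.id] == pytest.approx(expected)


class TestGateKinetics:
    @pytest.mark.parametrize("name", K.GATE_NAMES)
    def test_bounded_steady_state_positive_tau(self, name):
        v = np.linspace(-120.0, 60.0, 361)
        inf, tau = K.gate_inf_tau(name, v)
        assert np.all((inf >= 0.0) & (inf <= 1.0))
        assert np.all(np.asarray(tau) > 0.0)

    def test_temperature_scales_only_time_constants(self):
        _, inf1, tau1 = K.build_gate_tables(None, 27.0)
        _, inf2, tau2 = K.build_gate_tables(None, 37.0)
        assert np.allclose(inf1, inf2)
        assert np.allclose(tau1 / tau2, 2.5, rtol=1e-6)

    def test_nap_is_nat_shifted_down_14mv(self):
        v = np.linspace(-90.0, 0.0, 181)
        m_nat, _ = K.gate_inf_tau("NaT_m", v)
        m_nap, _ = K.gate_inf_tau("NaP_m", v - 14.0)
        assert np.allclose(m_nat, m_nap)
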