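"""Compiled inner loop of the cable-equation integrator.

One backward-Euler step solves the linearized membrane equation on the tree
by Hines ordered elimination (parents precede children in compartment order,
so a reverse sweep eliminates leaves first).  Gating variables advance by the
exponential (Rush-Larsen) rule using tabulated steady states and per-step
relaxation factors; Ca-dependent gates (SK, BK) and the GHK calcium fluxes
are evaluated directly.  Calcium microdomain currents are treated explicitly
(they are small), everything else implicitly, which keeps the scheme
unconditionally stable at the default 0.025-ms step.

All state arrays are modified in place so repeated calls continue a
simulation.  Units: mV, ms, S/cm2, mA/cm2, nA for reported whole-cell
currents, mM for Ca.
"""

import numpy as np
from numba import njit

# gate row indices (must match kinetics.GATE_NAMES)
NAT_M, NAT_H, NAP_M, NAP_H, KDR_N, KA_M, KA_H, KD_M, KD_H, KM_M, IH_M, \
    CAT_M, CAT_H, CAL_M = range(14)

# channel rows of the density matrix (must match biophysics.CHANNEL_NAMES)
NAT, NAP, KDR, KA, KD, KM, IH, CAT, CAL, SK, BK = range(11)

# synaptic state rows: MOD ampa rise/decay, nmda rise/decay; DRI-l same; SNR; RTN
N_SYN_STATE = 10

F_RT_FACTOR = 96485.33212 / 8.31446  # F/R, K/V


@njit(cache=True, fastmath=True)
def _ghk(v, ci, co, temp_k):
    """GHK flux per unit permeability (mA/cm2 for P=1 cm/s, conc in mM)."""
    xi = 2.0 * F_RT_FACTOR * v * 1e-3 / temp_k
    if xi > 500.0:
        xi = 500.0
    elif xi < -500.0:
        xi = -500.0
    if abs(xi) < 1e-6:
        frac = ci - co + 0.5 * xi * (ci + co)
    else:
        frac = (ci - co * np.exp(-xi)) / (1.0 - np.exp(-xi)) * xi
    return 2.0 * 96485.33212 * frac * 1e-3


@njit(cache=True, fastmath=True)
def run(dt, nsteps,
        parent, area, g_pair, c_eff,
        g_chan, g_km_floor, p_cal, g_leak,
        e_na, e_k, e_h, e_leak, e_gaba, temp_c,
        inf_tab, rl_tab, v_min, inv_dv,
        gates, ca, ca_tau, ca_delta, ca_rest,
        bk_vh_base, bk_ca_slope, bk_ca_ref, bk_k, shift_bk, rl_bk,
        sk_kd, sk_hill, rl_sk,
        syn_s, syn_dec, nmda_ratio, syn_norm_a, syn_norm_n, nmda_mg,
        ev_step, ev_comp, ev_group, ev_w,
        inj_comp, inj, vclamp_on, vcmd,
        v, rec_stride,
        v_soma, v_all, i_chan_out, i_syn_out, i_clamp_out):
    """Advance ``nsteps``; returns the maximum charge-balance residual (mA/cm2)."""
    n = v.shape[0]
    nv = inf_tab.shape[1]
    a = np.empty(n)
    rhs = np.empty(n)
    gsum_child = np.empty(n)
    i_const = np.empty(n)     # explicit current densities (GHK + injected)
    g_tot = np.empty(n)
    ge_sum = np.empty(n)      # sum of g_x * e_x
    i_cat = np.empty(n)
    i_cal1 = np.empty(n)
    i_cal2 = np.empty(n)
    temp_k = temp_c + 273.15
    resid_max = 0.0
    ev_ptr = 0
    n_ev = ev_step.shape[0]
    rt2f = 1e3 * 8.31446 * temp_k / (2.0 * 96485.33212)  # Nernst factor mV
    ca_unit = 1e4 / (2.0 * 96485.33212)
    v_old = np.empty(n)

    for step in range(nsteps):
        # --- synaptic events due at this step
        while ev_ptr < n_ev and ev_step[ev_ptr] <= step:
            j = ev_comp[ev_ptr]
            gidx = ev_group[ev_ptr]
            w = ev_w[ev_ptr]
            if gidx < 2:  # excitatory: AMPA + NMDA difference-of-exponentials
                base = 4 * gidx
                syn_s[base + 0, j] += w * syn_norm_a[gidx]
                syn_s[base + 1, j] += w * syn_norm_a[gidx]
                wn = w * nmda_ratio[gidx] * syn_norm_n[gidx]
                syn_s[base + 2, j] += wn
                syn_s[base + 3, j] += wn
            else:         # inhibitory single-exponential
                syn_s[6 + gidx, j] += w
            ev_ptr += 1

        # --- gate updates at the current voltage (staggered)
        for j in range(n):
            x = (v[j] - v_min) * inv_dv
            if x < 0.0:
                x = 0.0
            elif x > nv - 1.001:
                x = nv - 1.001
            k0 = int(x)
            fr = x - k0
            for gi in range(14):
                inf = inf_tab[gi, k0] * (1.0 - fr) + inf_tab[gi, k0 + 1] * fr
                rl = rl_tab[gi, k0] * (1.0 - fr) + rl_tab[gi, k0 + 1] * fr
                gates[gi, j] += rl * (inf - gates[gi, j])

        # SK activation from L2 Ca; BK activation from voltage and L1 Ca
        for j in range(n):
            ca2 = ca[1, j]
            if ca2 < 1e-9:
                ca2 = 1e-9
            r = (ca2 / sk_kd) ** sk_hill
            zinf = r / (1.0 + r)
            # extra state rows appended after the 14 tabulated gates
            gates[14, j] += rl_sk * (zinf - gates[14, j])
            ca1 = ca[0, j]
            if ca1 < 1e-9:
                ca1 = 1e-9
            vh = bk_vh_base + shift_bk - bk_ca_slope * np.log10(ca1 / bk_ca_ref)
            minf = 1.0 / (1.0 + np.exp(-(v[j] - vh) / bk_k))
            gates[15, j] += rl_bk * (minf - gates[15, j])

        # --- synaptic state decay
        for r_ in range(N_SYN_STATE):
            d = syn_dec[r_]
            for j in range(n):
                syn_s[r_, j] *= d

        # --- assemble membrane terms
        for j in range(n):
            g_na_t = g_chan[NAT, j] * gates[NAT_M, j] ** 3 * gates[NAT_H, j]
            g_na_p = g_chan[NAP, j] * gates[NAP_M, j] ** 3 * gates[NAP_H, j]
            g_kdr = g_chan[KDR, j] * gates[KDR_N, j] ** 4
            g_ka = g_chan[KA, j] * gates[KA_M, j] ** 4 * gates[KA_H, j]
            g_kd = g_chan[KD, j] * gates[KD_M, j] * gates[KD_H, j]
            g_km = g_chan[KM, j] * gates[KM_M, j] + g_km_floor[j]
            g_ih = g_chan[IH, j] * gates[IH_M, j]
            g_sk = g_chan[SK, j] * gates[14, j]
            g_bk = g_chan[BK, j] * gates[15, j]
            g_k_all = g_kdr + g_ka + g_kd + g_km + g_sk + g_bk
            # T-type: conductance with GHK-derived (Nernst) reversal from domain T
            caT = ca[2, j]
            if caT < 1e-9:
                caT = 1e-9
            e_cat = rt2f * np.log(2.0 / caT)
            g_cat = g_chan[CAT, j] * gates[CAT_M, j] ** 2 * gates[CAT_H, j]
            i_cat[j] = g_cat * (v[j] - e_cat)
            # L-type: GHK flux, two permeability components feeding L1 and L2
            mcal = gates[CAL_M, j] ** 2
            flux1 = _ghk(v[j], ca[0, j], 2.0, temp_k)
            flux2 = _ghk(v[j], ca[1, j], 2.0, temp_k)
            i_cal1[j] = p_cal[0, j] * mcal * flux1
            i_cal2[j] = p_cal[1, j] * mcal * flux2
            # synaptic conductances (stored in nS -> S/cm2)
            inv_area = 1e-9 / area[j]
            g_mod_a = (syn_s[1, j] - syn_s[0, j]) * inv_area
            g_dri_a = (syn_s[5, j] - syn_s[4, j]) * inv_area
            blk = 1.0 / (1.0 + np.exp(-0.062 * v[j]) * nmda_mg / 3.57)
            g_mod_n = (syn_s[3, j] - syn_s[2, j]) * inv_area * blk
            g_dri_n = (syn_s[7, j] - syn_s[6, j]) * inv_area * blk
            g_snr = syn_s[8, j] * inv_area
            g_rtn = syn_s[9, j] * inv_area
            g_exc = g_mod_a + g_mod_n + g_dri_a + g_dri_n
            g_gab = g_snr + g_rtn
            g_tot[j] = (g_na_t + g_na_p + g_k_all + g_ih + g_cat
                        + g_leak[j] + g_exc + g_gab)
            ge_sum[j] = ((g_na_t + g_na_p) * e_na + g_k_all * e_k
                         + g_ih * e_h + g_cat * e_cat + g_leak[j] * e_leak
                         + g_gab * e_gaba)  # excitatory e_rev = 0
            i_const[j] = i_cal1[j] + i_cal2[j]
        # injected current (nA -> mA/cm2, depolarizing = positive inward)
        i_const[inj_comp] -= inj[step] * 1e-6 / area[inj_comp]

        # --- assemble and solve the tree system
        for j in range(n):
            v_old[j] = v[j]
            gsum_child[j] = 0.0
        for j in range(1, n):
            gsum_child[parent[j]] += g_pair[j] / area[parent[j]]
        cdt = c_eff / dt
        for j in range(n):
            ax = gsum_child[j]
            if j > 0:
                ax += g_pair[j] / area[j]
            a[j] = cdt + g_tot[j] + ax
            rhs[j] = cdt * v[j] + ge_sum[j] - i_const[j]
        # eliminate leaves-to-root
        for j in range(n - 1, 0, -1):
            p = parent[j]
            gj = g_pair[j] / area[j]
            gp = g_pair[j] / area[p]
            f = gp / a[j]
            a[p] -= f * gj
            rhs[p] += f * rhs[j]
        if vclamp_on:
            v[0] = vcmd[step]
            i_clamp_out[step] = (a[0] * v[0] - rhs[0]) * area[0] * 1e6  # nA
        else:
            v[0] = rhs[0] / a[0]
            i_clamp_out[step] = 0.0
        for j in range(1, n):
            v[j] = (rhs[j] + (g_pair[j] / area[j]) * v[parent[j]]) / a[j]

        # --- charge-balance residual of the linearized system
        for j in range(n):
            ax = 0.0
            if j > 0:
                ax += g_pair[j] / area[j] * (v[parent[j]] - v[j])
            # child axial inflow is subtracted in the second pass below;
            # rhs is reused as the residual accumulator
            rhs[j] = cdt * (v[j] - v_old[j]) + g_tot[j] * v[j] - ge_sum[j] \
                + i_const[j] - ax
        for j in range(1, n):
            p = parent[j]
            rhs[p] -= g_pair[j] / area[p] * (v[j] - v[p])
        for j in range(n):
            if abs(rhs[j]) > resid_max:
                resid_max = abs(rhs[j])

        # --- calcium microdomains (exact exponential update, explicit current)
        for j in range(n):
            for d in range(3):
                if d == 0:
                    ica = i_cal1[j]
                elif d == 1:
                    ica = i_cal2[j]
                else:
                    ica = i_cat[j]
                target = ca_rest - ca_unit * ca_delta[d] * ica * ca_tau[d]
                dec = np.exp(-dt / ca_tau[d])
                ca[d, j] = target + (ca[d, j] - target) * dec

        # --- records
        v_soma[step] = v[0]
        if step % rec_stride == 0:
            ridx = step // rec_stride
            for j in range(n):
                v_all[ridx, j] = v[j]
            for ci in range(11):
                i_chan_out[ci, ridx] = 0.0
            for gi2 in range(4):
                i_syn_out[gi2, ridx] = 0.0
            for j in range(n):
                am = area[j] * 1e6  # mA/cm2 * cm2 -> nA
                i_chan_out[NAT, ridx] += g_chan[NAT, j] * gates[NAT_M, j] ** 3 \
                    * gates[NAT_H, j] * (v[j] - e_na) * am
                i_chan_out[NAP, ridx] += g_chan[NAP, j] * gates[NAP_M, j] ** 3 \
                    * gates[NAP_H, j] * (v[j] - e_na) * am
                i_chan_out[KDR, ridx] += g_chan[KDR, j] * gates[KDR_N, j] ** 4 \
                    * (v[j] - e_k) * am
                i_chan_out[KA, ridx] += g_chan[KA, j] * gates[KA_M, j] ** 4 \
                    * gates[KA_H, j] * (v[j] - e_k) * am
                i_chan_out[KD, ridx] += g_chan[KD, j] * gates[KD_M, j] \
                    * gates[KD_H, j] * (v[j] - e_k) * am
                i_chan_out[KM, ridx] += (g_chan[KM, j] * gates[KM_M, j]
                                         + g_km_floor[j]) * (v[j] - e_k) * am
                i_chan_out[IH, ridx] += g_chan[IH, j] * gates[IH_M, j] \
                    * (v[j] - e_h) * am
                i_chan_out[CAT, ridx] += i_cat[j] * am
                i_chan_out[CAL, ridx] += (i_cal1[j] + i_cal2[j]) * am
                i_chan_out[SK, ridx] += g_chan[SK, j] * gates[14, j] \
                    * (v[j] - e_k) * am
                i_chan_out[BK, ridx] += g_chan[BK, j] * gates[15, j] \
                    * (v[j] - e_k) * am
                inv_area = 1e-9 / area[j]
                blk = 1.0 / (1.0 + np.exp(-0.062 * v[j]) * nmda_mg / 3.57)
                i_syn_out[0, ridx] += ((syn_s[1, j] - syn_s[0, j])
                                       + (syn_s[3, j] - syn_s[2, j]) * blk) \
                    * inv_area * v[j] * am
                i_syn_out[1, ridx] += ((syn_s[5, j] - syn_s[4, j])
                                       + (syn_s[7, j] - syn_s[6, j]) * blk) \
                    * inv_area * v[j] * am
                i_syn_out[2, ridx] += syn_s[8, j] * inv_area \
                    * (v[j] - e_gaba) * am
                i_syn_out[3, ridx] += syn_s[9, j] * inv_area \
                    * (v[j] - e_gaba) * am
    return resid_max
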