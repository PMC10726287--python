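"""Gating kinetics of the 11 Hodgkin-Huxley conductances.

The channel complement is: transient (NaT) and persistent (NaP) sodium;
delayed-rectifier (KDR), A-type (KA), delaying shaker-related (KD) and
M-type (KM) potassium; H-type cation current (IH); T-type (CaT) and L-type
(CaL) calcium; and the small- (SK) and big-conductance (BK) calcium-activated
potassium currents.  Steady states are Boltzmann curves and time constants
smooth bell curves over voltage — the functional families used throughout the
thalamic modelling literature — with per-channel hooks for the fitted
modifiers: multiplicative factors on activation/inactivation time constants
(``tm``/``th``/``tn``), half-value shifts (KD, BK), and the persistent sodium
current defined as the transient kinetics with activation and inactivation
half-values lowered by 14 mV.

SK gating depends only on intracellular Ca (Hill curve); BK gating depends on
voltage with a Ca-dependent half-activation (shifting ~45 mV per decade of
Ca); both are computed directly in the integrator rather than tabulated.

All time constants are in ms at the reference temperature (34 degC) and are
divided by the Q10 factor at run temperature.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GATE_NAMES", "gate_inf_tau", "build_gate_tables",
           "sk_act", "bk_act", "REF_TEMP", "KINETICS_Q10",
           "V_TABLE_MIN", "V_TABLE_MAX", "V_TABLE_STEP"]

REF_TEMP = 34.0      # degC, reference temperature of the kinetics
KINETICS_Q10 = 2.5   # Q10 for all gating time constants (BK value, shared)

V_TABLE_MIN, V_TABLE_MAX, V_TABLE_STEP = -120.0, 60.0, 0.05

#: order of the voltage-tabulated gates used by the integrator
GATE_NAMES = ["NaT_m", "NaT_h", "NaP_m", "NaP_h", "KDR_n", "KA_m", "KA_h",
              "KD_m", "KD_h", "KM_m", "IH_m", "CaT_m", "CaT_h", "CaL_m"]


def _boltz(v, vh, k):
    return 1.0 / (1.0 + np.exp(-(v - vh) / k))


def _bell(v, mu, sigma):
    return np.exp(-(((v - mu) / sigma) ** 2))


def gate_inf_tau(name: str, v, mods: dict | None = None):
    """Steady state and time constant (ms at 34 degC) of one gate.

    ``mods`` carries the fitted modifiers: ``tm_nat``, ``th_nat``, ``tn_kdr``,
    ``tm_km``, ``tm_bk`` (multiplicative, >0), ``shift_kd`` and ``shift_bk``
    (mV added to the half-values).  Missing entries default to the identity.
    """
    m = mods or {}
    v = np.asarray(v, float)
    tm_nat = m.get("tm_nat", 1.0)
    th_nat = m.get("th_nat", 1.0)
    tn_kdr = m.get("tn_kdr", 1.0)
    tm_km = m.get("tm_km", 1.0)
    s_kd = m.get("shift_kd", 0.0)

    if name == "NaT_m":
        return _boltz(v, -43.0, 6.0), tm_nat * (0.05 + 0.4 * _bell(v, -43.0, 15.0))
    if name == "NaT_h":
        return _boltz(v, -58.0, -6.5), th_nat * (1.0 + 10.0 * _bell(v, -60.0, 16.0))
    # NaP: NaT kinetics with activation/inactivation half-values 14 mV lower
    if name == "NaP_m":
        return _boltz(v, -57.0, 6.0), tm_nat * (0.05 + 0.4 * _bell(v, -57.0, 15.0))
    if name == "NaP_h":
        return _boltz(v, -72.0, -6.5), th_nat * (1.0 + 10.0 * _bell(v, -74.0, 16.0))
    if name == "KDR_n":
        # slow deactivation below threshold prolongs the AHP and lets NaT
        # recover between spikes (sustained tonic firing without block)
        return _boltz(v, -32.0, 9.0), tn_kdr * (0.8 + 6.0 * _bell(v, -50.0, 30.0))
    if name == "KA_m":
        return _boltz(v, -50.0, 10.0), 0.3 + 1.2 * _bell(v, -45.0, 30.0)
    if name == "KA_h":
        # window around -60 mV: a sustained subthreshold brake
        return _boltz(v, -68.0, -6.0), 8.0 + 40.0 * _bell(v, -75.0, 20.0)
    if name == "KD_m":
        return _boltz(v, -52.0 + s_kd, 9.0), 1.0 + 3.0 * _bell(v, -52.0 + s_kd, 25.0)
    if name == "KD_h":
        return (_boltz(v, -75.0 + s_kd, -8.0),
                150.0 + 500.0 * _bell(v, -75.0 + s_kd, 25.0))
    if name == "KM_m":
        # slow de-activation on hyperpolarization, fast re-activation when
        # depolarized: recovery from silence is brief when the density is high
        return _boltz(v, -38.0, 9.0), tm_km * (8.0 + 40.0 * _bell(v, -75.0, 18.0))
    if name == "IH_m":
        return _boltz(v, -76.0, -5.5), 50.0 + 400.0 * _bell(v, -81.0, 20.0)
    if name == "CaT_m":
        return _boltz(v, -57.0, 6.2), 0.3 + 1.5 * _bell(v, -60.0, 20.0)
    if name == "CaT_h":
        return _boltz(v, -81.0, -4.0), 20.0 + 70.0 * _bell(v, -88.0, 20.0)
    if name == "CaL_m":
        return _boltz(v, -20.0, 7.0), 0.5 + 2.0 * _bell(v, -25.0, 20.0)
    raise KeyError(f"unknown gate {name}")


def build_gate_tables(mods: dict | None, temp: float):
    """Tabulate inf and tau for every voltage-dependent gate.

    Returns ``(v_grid, inf_table, tau_table)`` with tables of shape
    ``(len(GATE_NAMES), len(v_grid))``.  Time constants are divided by the
    Q10 temperature factor so the integrator consumes run-temperature values.
    Tables are cached per (modifiers, temperature); callers must not mutate
    the returned arrays.
    """
    key = (tuple(sorted((mods or {}).items())), float(temp))
    hit = _TABLE_CACHE.get(key)
    if hit is not None:
        return hit
    v = np.arange(V_TABLE_MIN, V_TABLE_MAX + V_TABLE_STEP / 2, V_TABLE_STEP)
    qf = KINETICS_Q10 ** ((temp - REF_TEMP) / 10.0)
    inf = np.empty((len(GATE_NAMES), v.size))
    tau = np.empty_like(inf)
    for i, name in enumerate(GATE_NAMES):
        gi, gt = gate_inf_tau(name, v, mods)
        inf[i] = gi
        tau[i] = np.maximum(np.broadcast_to(gt, v.shape), 1e-3) / qf
    if len(_TABLE_CACHE) > 64:
        _TABLE_CACHE.clear()
    _TABLE_CACHE[key] = (v, inf, tau)
    return v, inf, tau


_TABLE_CACHE: dict = {}


# -- Ca-dependent gates ------------------------------------------------------

SK_KD = 3e-3     # mM, half-activation of SK in microdomain-shell units
SK_HILL = 2.5
SK_TAU = 1.0     # ms

BK_VH_BASE = 0.0       # mV half-activation at 1 uM Ca, before the fitted shift
BK_CA_SLOPE = 45.0     # mV shift per decade of Ca
BK_CA_REF = 1e-3       # mM
BK_K = 11.0            # mV slope factor
BK_TAU_BASE = 100.0    # ms, scaled by the fitted tm multiplier; the slow
                       # gating makes BK an activity-integrating adaptation
                       # current with second-scale recovery after silence


def sk_act(ca):
    """SK steady-state activation from microdomain Ca (mM)."""
    r = (np.maximum(ca, 1e-9) / SK_KD) ** SK_HILL
    return r / (1.0 + r)


def bk_act(v, ca, shift_bk=0.0):
    """BK steady-state activation from voltage and microdomain Ca (mM)."""
    vh = BK_VH_BASE + shift_bk - BK_CA_SLOPE * np.log10(np.maximum(ca, 1e-9) / BK_CA_REF)
    return 1.0 / (1.0 + np.exp(-(v - vh) / BK_K))
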