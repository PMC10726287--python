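"""Cable-equation simulation of the compiled thalamocortical models.

Wraps the compiled backward-Euler kernel with the experimental vocabulary:
slice conditions (temperature, reversal potentials, channel blockers, holding
voltage), the five in-vitro current-clamp protocols, ideal somatic voltage
clamp, and somatic spike detection.

The integrator is first-order implicit on the tree (Hines elimination) with
exponential gate updates, which is unconditionally stable; the default step
is 0.025 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel, kinetics
from .biophysics import (DensityMap, ModelParams, apply_distribution,
                         q10_factor)
from .morphology import MorphTree

__all__ = [
    "SimCondition", "Protocol", "SimResult", "CompiledCell", "compile_cell",
    "integrate", "run_current_clamp", "run_voltage_clamp", "detect_spikes",
    "CONDITIONS", "protocol", "E_GABA", "E_H",
]

E_GABA = -81.0   # mV, GABA-A reversal
E_H = -43.0      # mV, H-current reversal

#: AMPA/NMDA double-exponential time constants (ms, at the kinetics
#: reference temperature) and Mg concentration of the NMDA block
AMPA_TAU_RISE, AMPA_TAU_DECAY = 0.2, 1.0
NMDA_TAU_RISE, NMDA_TAU_DECAY = 2.0, 25.0
NMDA_MG = 2.0                       # mM, standard slice-aCSF Mg concentration
GABA_TAU_DECAY_32 = 14.0            # ms at 32 degC
GABA_Q10 = 2.1
NMDA_RATIO = {"MOD": 1.91, "DRI-l": 0.6}


@dataclass(frozen=True)
class SimCondition:
    """One simulated slice / in-vivo condition."""

    name: str = "custom"
    temperature: float = 34.0   # degC
    e_na: float = 69.0          # mV
    e_k: float = -105.0         # mV
    e_gaba: float = E_GABA      # mV
    v_hold: float | None = None  # mV (informational; bias sets the hold)
    blockers: frozenset = frozenset()
    bias_current: float = 0.0   # pA


#: replicated experimental conditions; 'invivo' extrapolates the 27-degC
#: reversals to body temperature via the Nernst T-dependence
CONDITIONS = {
    "b8": SimCondition("b8", 27.0, 69.0, -105.0, E_GABA, -69.0),
    "mpsc": SimCondition("mpsc", 24.0, 69.0, -105.0, E_GABA, -79.3,
                         frozenset({"TTX", "cesium"})),
    "b30": SimCondition("b30", 34.0, 69.0, -107.1, E_GABA, -68.4,
                        frozenset({"TTX"})),
    "b26": SimCondition("b26", 32.0, 60.1, -105.8, E_GABA, -64.0),
    "invivo": SimCondition("invivo", 37.0, 71.3, -108.5, E_GABA, None),
}


@dataclass
class Protocol:
    """A family of current-clamp steps on top of a bias current."""

    id: str
    step_amplitudes: tuple   # pA
    step_duration: float     # ms
    bias: float = 0.0        # pA
    pre_window: float = 500.0   # ms settle before the step
    post_window: float = 300.0  # ms after step offset


_BIAS = {"normal": 93.0, "parkinsonian": 67.0}


def protocol(pid: str, state: str = "normal") -> Protocol:
    """The five in-vitro protocols; bias currents are state-specific."""
    bias = _BIAS[state]
    if pid == "P1":
        return Protocol("P1", tuple(range(20, 301, 20)), 2000.0, bias)
    if pid == "P2":
        return Protocol("P2", (-200.0, -150.0, -100.0, -50.0), 2000.0, bias)
    if pid == "P3":
        return Protocol("P3", (-200.0, -150.0, -100.0, -50.0), 2000.0, 0.0)
    if pid == "P4":
        return Protocol("P4", (-1000.0,), 0.5, 0.0, post_window=200.0)
    if pid == "P5":
        return Protocol("P5", (-10.0,), 100.0, 0.0, post_window=200.0)
    raise ValueError(f"unknown protocol {pid}")


@dataclass
class SimResult:
    """Time grid, voltages, per-channel and per-group currents, spikes."""

    dt: float                 # ms, base integration step
    rec_stride: int
    v_soma: np.ndarray        # (nsteps,) mV every step
    v: np.ndarray             # (nrec, ncomp) mV at stride
    i_channel: dict           # name -> (nrec,) nA whole-cell current
    i_syn: dict               # class -> (nrec,) nA
    i_clamp: np.ndarray       # (nsteps,) nA (voltage clamp only)
    spikes: np.ndarray        # ms, somatic spike times
    resid_max: float          # mA/cm2, worst charge-balance residual
    meta: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        """Recording-grid times in ms."""
        return np.arange(self.v.shape[0]) * self.dt * self.rec_stride

    @property
    def t_full(self) -> np.ndarray:
        return np.arange(self.v_soma.size) * self.dt

    def save(self, path) -> None:
        """Write the traces as a compressed npz container."""
        np.savez_compressed(
            path, dt=self.dt, rec_stride=self.rec_stride,
            v_soma=self.v_soma, v=self.v, spikes=self.spikes,
            i_clamp=self.i_clamp, resid_max=self.resid_max,
            **{f"i_channel_{k}": x for k, x in self.i_channel.items()},
            **{f"i_syn_{k}": x for k, x in self.i_syn.items()})

    @classmethod
    def load(cls, path) -> "SimResult":
        z = np.load(path)
        i_ch = {k[10:]: z[k] for k in z.files if k.startswith("i_channel_")}
        i_sy = {k[6:]: z[k] for k in z.files if k.startswith("i_syn_")}
        return cls(float(z["dt"]), int(z["rec_stride"]), z["v_soma"], z["v"],
                   i_ch, i_sy, z["i_clamp"], z["spikes"],
                   float(z["resid_max"]))


@dataclass
class CompiledCell:
    """Morphology + parameters flattened into solver arrays."""

    tree: MorphTree
    params: ModelParams
    densities: DensityMap
    parent: np.ndarray      # (n,) int32, parent[0] = -1
    area: np.ndarray        # (n,) cm2
    g_pair: np.ndarray      # (n,) S axial coupling to parent
    soma_index: int = 0

    @property
    def n_comp(self) -> int:
        return self.parent.size


def compile_cell(tree: MorphTree, params: ModelParams) -> CompiledCell:
    """Flatten a compiled tree and a parameter set into solver arrays."""
    comps = tree.compartments
    if not comps:
        raise ValueError("morphology has no compartments; run build_cell first")
    n = len(comps)
    parent = np.full(n, -1, np.int32)
    area = np.empty(n)
    for c in comps:
        parent[c.id] = -1 if c.parent_id is None else c.parent_id
        area[c.id] = c.membrane_area * 1e-8  # um2 -> cm2
    # axial conductance between compartment and parent: half-cylinder
    # resistances in series, r_i in Ohm cm, geometry in cm
    g_pair = np.zeros(n)
    for c in comps:
        if c.parent_id is None:
            continue
        p = comps[c.parent_id]
        r = 0.0
        for seg in (c, p):
            L = seg.length * 1e-4 / 2.0
            rad = seg.diameter * 1e-4 / 2.0
            r += params.r_i * L / (math.pi * rad * rad)
        g_pair[c.id] = 1.0 / r
    dens = apply_distribution(params, tree)
    return CompiledCell(tree, params, dens, parent, area, g_pair)


def _blocked_densities(cell: CompiledCell, blockers) -> tuple[np.ndarray, np.ndarray]:
    """Copy of the density matrix with blocker effects applied."""
    g = cell.densities.g.copy()
    g_floor = cell.densities.g_km_floor.copy()
    idx = cell.densities.channel_index
    if "TTX" in blockers:
        g[idx["NaT"]] = 0.0
        g[idx["NaP"]] = 0.0
    if "cesium" in blockers:
        for name in ("KDR", "KA", "KD", "KM", "SK", "BK"):
            g[idx[name]] = 0.0
        g_floor[:] = 0.0
    return g, g_floor


def _dual_exp_norm(tau_r: float, tau_d: float) -> float:
    tp = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
    return 1.0 / (math.exp(-tp / tau_d) - math.exp(-tp / tau_r))


def _syn_constants(dt: float, temp: float):
    """Per-step decay factors and peak normalizers of the synapse states."""
    qf = q10_factor(temp, kinetics.REF_TEMP, kinetics.KINETICS_Q10)
    gaba_q = q10_factor(temp, 32.0, GABA_Q10)
    taus = np.array([AMPA_TAU_RISE, AMPA_TAU_DECAY,
                     NMDA_TAU_RISE, NMDA_TAU_DECAY] * 2
                    + [GABA_TAU_DECAY_32, GABA_TAU_DECAY_32])
    taus[:8] /= qf
    taus[8:] /= gaba_q
    dec = np.exp(-dt / taus)
    norm_a = np.full(2, _dual_exp_norm(taus[0], taus[1]))
    norm_n = np.full(2, _dual_exp_norm(taus[2], taus[3]))
    ratio = np.array([NMDA_RATIO["MOD"], NMDA_RATIO["DRI-l"]])
    return dec, norm_a, norm_n, ratio, taus


class SimState:
    """Mutable integration state, snapshot-able between runs."""

    def __init__(self, cell: CompiledCell, v0: float):
        n = cell.n_comp
        self.v = np.full(n, v0)
        self.gates = np.zeros((16, n))
        self.ca = np.full((3, n), self.cal_rest(cell))
        self.syn_s = np.zeros((_kernel.N_SYN_STATE, n))

    @staticmethod
    def cal_rest(cell: CompiledCell) -> float:
        return cell.params.ca_domains["L1"].resting_ca

    def init_gates(self, cell: CompiledCell, temp: float) -> None:
        mods = cell.params.kinetic_mods()
        for gi, name in enumerate(kinetics.GATE_NAMES):
            inf, _ = kinetics.gate_inf_tau(name, self.v, mods)
            self.gates[gi] = inf
        self.gates[14] = kinetics.sk_act(self.ca[1])
        self.gates[15] = kinetics.bk_act(self.v, self.ca[0],
                                         mods.get("shift_bk", 0.0))

    def copy(self) -> "SimState":
        s = object.__new__(SimState)
        s.v = self.v.copy()
        s.gates = self.gates.copy()
        s.ca = self.ca.copy()
        s.syn_s = self.syn_s.copy()
        return s


def _events_to_arrays(events, dt: float):
    """Sort (t_ms, comp, group, weight_nS) tuples into kernel arrays."""
    if not events:
        z = np.zeros(0)
        return z.astype(np.int64), z.astype(np.int32), z.astype(np.int32), z
    ev = sorted(events)
    t = np.array([e[0] for e in ev])
    return (np.asarray(np.rint(t / dt), np.int64),
            np.array([e[1] for e in ev], np.int32),
            np.array([e[2] for e in ev], np.int32),
            np.array([e[3] for e in ev], float))


def integrate(cell: CompiledCell, condition: SimCondition, t_end: float,
              dt: float = 0.025, *, pulses=(), events=(), state: SimState | None = None,
              v_init: float | None = None, vclamp: float | np.ndarray | None = None,
              rec_stride: int = 8, seed: int = 0) -> SimResult:
    """Integrate the cable equation for ``t_end`` ms.

    ``pulses`` is a sequence of ``(t_on_ms, t_off_ms, amplitude_pA)`` somatic
    injections (the condition's bias current is added on top for the whole
    run); ``events`` is a sequence of ``(t_ms, compartment, group, g_unit_nS)``
    synaptic activations with group 0=MOD, 1=DRI-l, 2=SNR, 3=RTN.  Passing a
    ``state`` continues from (and mutates) that state, otherwise a fresh
    steady-state initialization at ``v_init`` (default: the model's resting
    potential) is used.  ``vclamp`` switches the soma to an ideal voltage
    clamp at the given command voltage (scalar or per-step array).

    Raises a solver error naming the first offending compartment if the
    voltage leaves a physiological bracket (NaN or beyond +-200 mV).
    """
    if not 0.005 <= dt <= 0.05:
        raise ValueError("dt must lie in [0.005, 0.05] ms")
    nsteps = int(round(t_end / dt))
    temp = condition.temperature
    g, g_floor = _blocked_densities(cell, condition.blockers)
    mods = cell.params.kinetic_mods()
    v_grid, inf_tab, tau_tab = kinetics.build_gate_tables(mods, temp)
    rl_tab = 1.0 - np.exp(-dt / tau_tab)
    qf = q10_factor(temp, kinetics.REF_TEMP, kinetics.KINETICS_Q10)
    rl_bk = 1.0 - math.exp(-dt * qf / (kinetics.BK_TAU_BASE
                                       * cell.params.channels["BK"].mods.tau_m))
    rl_sk = 1.0 - math.exp(-dt * qf / kinetics.SK_TAU)

    if state is None:
        state = SimState(cell, cell.params.v_rest if v_init is None else v_init)
        state.init_gates(cell, temp)

    inj = np.full(nsteps, condition.bias_current * 1e-3)  # pA -> nA
    for (t0, t1, amp) in pulses:
        i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
        inj[max(i0, 0):min(i1, nsteps)] += amp * 1e-3

    ev_step, ev_comp, ev_group, ev_w = _events_to_arrays(list(events), dt)
    dec, norm_a, norm_n, ratio, _ = _syn_constants(dt, temp)

    if vclamp is None:
        vclamp_on, vcmd = False, np.zeros(nsteps)
    else:
        vclamp_on = True
        vcmd = np.broadcast_to(np.asarray(vclamp, float), (nsteps,)).copy()
        state.v[0] = vcmd[0] if nsteps else state.v[0]

    nrec = (nsteps + rec_stride - 1) // rec_stride
    v_soma = np.empty(nsteps)
    v_all = np.empty((nrec, cell.n_comp))
    i_chan = np.zeros((11, nrec))
    i_syn = np.zeros((4, nrec))
    i_clamp = np.zeros(nsteps)

    dom = cell.params.ca_domains
    resid = _kernel.run(
        dt, nsteps, cell.parent, cell.area, cell.g_pair,
        cell.params.c_m * 1e-3,
        g, g_floor, cell.densities.p_cal, cell.densities.g_leak,
        condition.e_na, condition.e_k, E_H, cell.params.v_rest,
        condition.e_gaba, temp,
        inf_tab, rl_tab, v_grid[0], 1.0 / (v_grid[1] - v_grid[0]),
        state.gates, state.ca,
        np.array([dom["L1"].tau, dom["L2"].tau, dom["T"].tau]),
        np.array([dom["L1"].delta, dom["L2"].delta, dom["T"].delta]),
        dom["L1"].resting_ca,
        kinetics.BK_VH_BASE, kinetics.BK_CA_SLOPE, kinetics.BK_CA_REF,
        kinetics.BK_K, mods["shift_bk"], rl_bk,
        kinetics.SK_KD, kinetics.SK_HILL, rl_sk,
        state.syn_s, dec, ratio, norm_a, norm_n, NMDA_MG,
        ev_step, ev_comp, ev_group, ev_w,
        cell.soma_index, inj, vclamp_on, vcmd,
        state.v, rec_stride,
        v_soma, v_all, i_chan, i_syn, i_clamp)

    if not np.isfinite(state.v).all() or np.abs(state.v).max() > 200.0:
        bad = np.flatnonzero(~np.isfinite(state.v) | (np.abs(state.v) > 200.0))[0]
        raise FloatingPointError(
            f"solver divergence at compartment {bad} (t = {t_end} ms)")

    names = list(cell.densities.channel_index)
    return SimResult(dt, rec_stride, v_soma, v_all,
                     {nm: i_chan[i] for i, nm in enumerate(names)},
                     {nm: i_syn[i] for i, nm in
                      enumerate(["MOD", "DRI-l", "SNR", "RTN"])},
                     i_clamp, detect_spikes(v_soma, dt), resid,
                     meta={"condition": condition.name, "t_end": t_end,
                           "seed": seed})


def detect_spikes(v: np.ndarray, dt: float, threshold: float = -20.0,
                  min_interval: float = 1.0) -> np.ndarray:
    """Upward threshold crossings of a uniformly sampled trace (times in ms).

    Crossings closer than ``min_interval`` are merged into one event.
    """
    v = np.asarray(v)
    up = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold))
    if up.size == 0:
        return np.empty(0)
    t = (up + 1) * dt
    keep = np.concatenate([[True], np.diff(t) >= min_interval])
    return t[keep]


def run_current_clamp(cell: CompiledCell, proto: Protocol,
                      condition: SimCondition, dt: float = 0.025,
                      rec_stride: int = 8) -> list[SimResult]:
    """Run every step amplitude of a protocol; returns one result per step.

    The bias current is applied throughout; the cell is settled once under
    the bias and that state is reused for every amplitude.  Each result's
    ``meta`` carries the step amplitude and the on/off times.
    """
    cond = replace(condition, bias_current=proto.bias)
    settle = SimState(cell, cell.params.v_rest)
    settle.init_gates(cell, cond.temperature)
    integrate(cell, cond, proto.pre_window, dt, state=settle,
              rec_stride=64)
    out = []
    for amp in proto.step_amplitudes:
        st = settle.copy()
        t_end = proto.step_duration + proto.post_window
        res = integrate(cell, cond, t_end, dt, state=st,
                        pulses=[(0.0, proto.step_duration, amp)],
                        rec_stride=rec_stride)
        res.meta.update(amplitude=amp, step_on=0.0,
                        step_off=proto.step_duration, protocol=proto.id,
                        bias=proto.bias)
        out.append(res)
    return out


def run_voltage_clamp(cell: CompiledCell, v_cmd: float,
                      condition: SimCondition, events=(),
                      t_end: float = 200.0, settle: float = 300.0,
                      dt: float = 0.025) -> SimResult:
    """Ideal somatic voltage clamp; returns the clamp-current trace.

    The clamp is held at ``v_cmd`` for ``settle`` ms to reach the holding
    current, then the synaptic ``events`` (shifted by the settle time) are
    delivered.  PSC amplitudes are peak deviations of ``i_clamp`` from the
    holding current.
    """
    if not -120.0 <= v_cmd <= 40.0:
        raise ValueError("clamp command outside [-120, 40] mV")
    ev = [(t + settle, c, g, w) for (t, c, g, w) in events]
    res = integrate(cell, condition, settle + t_end, dt, events=ev,
                    vclamp=v_cmd, v_init=v_cmd, rec_stride=4)
    res.meta.update(v_cmd=v_cmd, settle=settle)
    return res


def psc_amplitude(res: SimResult) -> float:
    """Peak PSC (pA, signed) of a voltage-clamp run relative to holding."""
    settle = res.meta["settle"]
    i = res.i_clamp
    n0 = int(round(settle / res.dt))
    hold = i[n0 - 1]
    dev = i[n0:] - hold
    k = np.argmax(np.abs(dev))
    return float(dev[k] * 1e3)  # nA -> pA
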