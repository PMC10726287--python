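"""The four afferent synapse classes and their calibration.

Classes: glutamatergic modulators (MOD, cortical layer-6-like) and
driver-like inputs (DRI-l, layer-5/subcortical), and GABAergic inputs from
substantia nigra pars reticulata (SNR) and reticular thalamic nucleus (RTN).
Excitatory synapses have AMPA+NMDA components (NMDA/AMPA peak ratio 1.91 for
MOD, 0.6 for DRI-l; reversal 0 mV); inhibitory synapses are single
exponential-decay conductances (decay 14 ms at 32 degC, Q10 2.1, reversal
-81 mV).

Placement walks the dendrites in steps of the class sampling spacing (0.8 um
for MOD/RTN, 2.8 um for SNR) and samples terminal counts from
diameter-bracket densities; DRI-l terminals are instead drawn from a
distance-from-soma distribution and fixed at 10% of the MOD terminal count;
a proportion of SNR terminals sits on the soma.  Bracket densities are
calibrated so that a full-scale reconstruction (reference dendritic length
``REF_LENGTH``) carries the reference totals MOD 3625 / DRI-l 350 / SNR 25 /
RTN 400; totals scale linearly with dendritic length on smaller trees.
40% of MOD terminals are active (1450 on the full-scale cell).

Unitary conductances are calibrated by bisection against the target
postsynaptic-current amplitudes measured in the replicated voltage-clamp
experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .morphology import MorphTree
from .simulate import (CONDITIONS, CompiledCell, GABA_Q10,
                       GABA_TAU_DECAY_32, NMDA_RATIO, SimCondition,
                       psc_amplitude, run_voltage_clamp)
from .biophysics import q10_factor

__all__ = [
    "SynapseKinetics", "PlacementRule", "SynapseGroup", "GROUP_INDEX",
    "REF_TOTALS", "REF_LENGTH", "MOD_ACTIVE_FRACTION", "place_synapses",
    "default_rules", "build_groups", "synaptic_conductance",
    "calibrate_unitary_conductance", "CALIBRATION_TARGETS", "make_events",
]

#: kernel group indices
GROUP_INDEX = {"MOD": 0, "DRI-l": 1, "SNR": 2, "RTN": 3}

#: terminal totals on the full-scale reconstruction
REF_TOTALS = {"MOD": 3625, "DRI-l": 350, "SNR": 25, "RTN": 400}
#: assumed dendritic length (um) of the full-scale reconstruction that
#: carries REF_TOTALS; smaller trees get proportionally fewer terminals
REF_LENGTH = 5800.0
#: fraction of MOD terminals that are active (silent layer-6 cells excluded)
MOD_ACTIVE_FRACTION = 0.4

#: published unitary conductances (nS), used as defaults when a group is not
#: recalibrated on the present morphology
DEFAULT_G_UNIT = {"MOD": 2.2, "RTN": 0.7, "SNR": 4.8, "DRI-l": 1.3}


@dataclass(frozen=True)
class SynapseKinetics:
    """Receptor kinetics of one afferent class."""

    name: str
    e_rev: float                    # mV
    decay_tau: float                # ms at ref temp (GABA: 14 ms at 32 degC)
    q10: float = GABA_Q10
    nmda_ampa_ratio: float = 0.0    # 0 for GABAergic classes

    @property
    def excitatory(self) -> bool:
        return self.e_rev == 0.0


KINETICS = {
    "MOD": SynapseKinetics("MOD", 0.0, 2.5, 2.5, NMDA_RATIO["MOD"]),
    "DRI-l": SynapseKinetics("DRI-l", 0.0, 2.5, 2.5, NMDA_RATIO["DRI-l"]),
    "SNR": SynapseKinetics("SNR", -81.0, GABA_TAU_DECAY_32, GABA_Q10),
    "RTN": SynapseKinetics("RTN", -81.0, GABA_TAU_DECAY_32, GABA_Q10),
}


@dataclass
class PlacementRule:
    """Where one afferent class lands on the tree."""

    name: str
    sampling_spacing: float                 # um between candidate sites
    bracket_weights: tuple = (1.0, 1.0, 1.0)  # small / medium / large diameter
    dri_distance: tuple | None = None       # (gamma shape, scale um) for DRI-l
    snr_somatic_proportion: float = 0.0
    active_fraction: float = 1.0
    ref_total: int = 0

    def __post_init__(self) -> None:
        if self.sampling_spacing <= 0:
            raise ValueError("sampling spacing must be positive")
        if any(w < 0 for w in self.bracket_weights):
            raise ValueError("bracket densities must be non-negative")


def default_rules() -> dict[str, PlacementRule]:
    """Placement rules of the four classes.

    Bracket weights put MOD/RTN preferentially on thin distal dendrites and
    SNR on thick proximal ones (the published electron-microscopy source
    counts are unpublished; the weights are package defaults reproducing the
    qualitative proximal/distal split).
    """
    return {
        "MOD": PlacementRule("MOD", 0.8, (1.0, 0.8, 0.3),
                             active_fraction=MOD_ACTIVE_FRACTION,
                             ref_total=REF_TOTALS["MOD"]),
        "DRI-l": PlacementRule("DRI-l", 0.8, dri_distance=(2.0, 15.0),
                               ref_total=REF_TOTALS["DRI-l"]),
        "SNR": PlacementRule("SNR", 2.8, (0.2, 1.0, 1.5),
                             snr_somatic_proportion=0.2,
                             ref_total=REF_TOTALS["SNR"]),
        "RTN": PlacementRule("RTN", 0.8, (1.0, 0.8, 0.3),
                             ref_total=REF_TOTALS["RTN"]),
    }


@dataclass
class SynapseGroup:
    """Placed terminals of one class plus its unitary conductance."""

    name: str
    kinetics: SynapseKinetics
    g_unit: float                       # nS
    terminals: list = field(default_factory=list)  # compartment ids
    n_active: int = 0

    def __post_init__(self) -> None:
        if self.n_active > len(self.terminals):
            raise ValueError("n_active exceeds terminal count")

    @property
    def group_index(self) -> int:
        return GROUP_INDEX[self.name]


def _bracket(diameter: float) -> int:
    if diameter <= 0.5:
        return 0
    if diameter <= 1.0:
        return 1
    return 2


def place_synapses(tree: MorphTree, rule: PlacementRule, seed,
                   n_mod: int | None = None) -> SynapseGroup:
    """Place one class's terminals on a compiled tree (seeded).

    The class total is the reference total scaled by the tree's dendritic
    length (DRI-l: fixed at 10% of the MOD count, ``n_mod``); terminals are
    distributed over candidate sites (every ``sampling_spacing`` um of
    dendrite) with probabilities proportional to the diameter-bracket
    weights, except DRI-l which samples its distance-from-soma law.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dend = [c for c in tree.compartments
            if c.region in ("primary_dend", "dend")]
    if not dend:
        raise ValueError("tree has no dendritic compartments")
    length = sum(c.length for c in dend)
    if rule.name == "DRI-l":
        if n_mod is None:
            n_mod = int(round(REF_TOTALS["MOD"] * length / REF_LENGTH))
        total = int(round(0.1 * n_mod))
        shape, scale = rule.dri_distance
        dists = np.array([c.distance_from_soma for c in dend])
        ids = np.array([c.id for c in dend])
        draws = rng.gamma(shape, scale, size=total)
        terminals = [int(ids[np.argmin(np.abs(dists - d))]) for d in draws]
    else:
        total = int(round(rule.ref_total * length / REF_LENGTH))
        n_soma = 0
        if rule.snr_somatic_proportion > 0:
            n_soma = int(round(rule.snr_somatic_proportion * total))
        n_dend = total - n_soma
        sites = np.array([max(1, int(c.length / rule.sampling_spacing))
                          for c in dend], float)
        w = np.array([rule.bracket_weights[_bracket(c.diameter)]
                      for c in dend])
        p = sites * w
        p /= p.sum()
        counts = rng.multinomial(n_dend, p)
        terminals = []
        for c, k in zip(dend, counts):
            terminals.extend([c.id] * int(k))
        soma_id = next(c.id for c in tree.compartments if c.region == "soma")
        terminals.extend([soma_id] * n_soma)
    n_active = int(round(rule.active_fraction * len(terminals)))
    return SynapseGroup(rule.name, KINETICS[rule.name],
                        DEFAULT_G_UNIT[rule.name], terminals, n_active)


def build_groups(tree: MorphTree, seed: int,
                 rules: dict | None = None) -> dict[str, SynapseGroup]:
    """Place all four classes with one seed (MOD first so DRI-l can be 10%)."""
    rules = rules or default_rules()
    rng = np.random.default_rng(seed)
    groups = {"MOD": place_synapses(tree, rules["MOD"], rng)}
    groups["DRI-l"] = place_synapses(tree, rules["DRI-l"], rng,
                                     n_mod=len(groups["MOD"].terminals))
    groups["SNR"] = place_synapses(tree, rules["SNR"], rng)
    groups["RTN"] = place_synapses(tree, rules["RTN"], rng)
    return groups


def synaptic_conductance(kin: SynapseKinetics, spike_times, t, temp: float,
                         g_unit: float = 1.0):
    """Conductance waveform(s) of one synapse for given spike times.

    Returns ``g(t)`` in nS for a GABAergic class, or ``(g_ampa, g_nmda)``
    (the NMDA component at full unblock) for an excitatory one.  Events sum
    linearly; each event peaks at ``g_unit`` (AMPA) and ``g_unit * ratio``
    (NMDA).  GABA decay is Q10-scaled from its 32 degC reference.
    """
    t = np.asarray(t, float)
    if not kin.excitatory:
        tau = kin.decay_tau / q10_factor(temp, 32.0, kin.q10)
        g = np.zeros_like(t)
        for ts in spike_times:
            m = t >= ts
            g[m] += g_unit * np.exp(-(t[m] - ts) / tau)
        return g
    from .simulate import (AMPA_TAU_DECAY, AMPA_TAU_RISE, NMDA_TAU_DECAY,
                          NMDA_TAU_RISE, _dual_exp_norm)
    from . import kinetics as _kin
    qf = q10_factor(temp, _kin.REF_TEMP, _kin.KINETICS_Q10)

    def dual(tau_r, tau_d, peak):
        tau_r, tau_d = tau_r / qf, tau_d / qf
        norm = _dual_exp_norm(tau_r, tau_d)
        g = np.zeros_like(t)
        for ts in spike_times:
            m = t >= ts
            dt_ = t[m] - ts
            g[m] += peak * norm * (np.exp(-dt_ / tau_d) - np.exp(-dt_ / tau_r))
        return g

    return (dual(AMPA_TAU_RISE, AMPA_TAU_DECAY, g_unit),
            dual(NMDA_TAU_RISE, NMDA_TAU_DECAY, g_unit * kin.nmda_ampa_ratio))


#: replicated voltage-clamp configurations for conductance calibration:
#: (condition, clamp voltage mV, GABA reversal during clamp, n active
#: terminals, target PSC amplitude pA).  The RTN miniature IPSCs were
#: recorded with a cesium(high-Cl)-filled pipette, so the clamp-time GABA
#: reversal is ~0 mV there.  The DRI-l target is the published EPSC reduced
#: by 25% to absorb short-term depression.
CALIBRATION_TARGETS = {
    "MOD": ("mpsc", -79.3, None, 1, 28.4),
    "RTN": ("mpsc", -79.3, 0.0, 1, 24.43),
    "SNR": ("b26", -64.0, None, 1, 47.2),
    "DRI-l": ("b30", -68.4, None, 4, 123.7),
}


def calibrate_unitary_conductance(cell: CompiledCell, group: SynapseGroup,
                                  target_psc: float,
                                  condition: SimCondition, v_cmd: float,
                                  n_active: int = 1, seed: int = 0,
                                  e_gaba: float | None = None,
                                  tol: float = 0.01,
                                  g_bracket=(1e-3, 200.0)) -> float:
    """Bisection on the unitary conductance until the simulated PSC matches.

    ``target_psc`` is an amplitude in pA (sign ignored).  ``n_active``
    terminals (a seeded draw from the group's terminal list) fire once,
    simultaneously, under somatic voltage clamp; the PSC amplitude is the
    peak deviation of the clamp current from holding.  PSC magnitude is
    monotone in the unitary conductance, so bisection converges; a
    calibration error is raised if the target is outside the bracket.
    """
    if target_psc <= 0:
        raise ValueError("target PSC must be positive (magnitude)")
    rng = np.random.default_rng(seed)
    terms = list(group.terminals)
    chosen = rng.choice(terms, size=min(n_active, len(terms)), replace=False)
    cond = condition
    if e_gaba is not None:
        from dataclasses import replace as _replace
        cond = _replace(condition, e_gaba=e_gaba)

    def amp(g_unit: float) -> float:
        ev = [(0.0, int(c), group.group_index, g_unit) for c in chosen]
        res = run_voltage_clamp(cell, v_cmd, cond, events=ev, t_end=150.0)
        return abs(psc_amplitude(res))

    lo, hi = g_bracket
    a_lo, a_hi = amp(lo), amp(hi)
    if not (a_lo <= target_psc <= a_hi):
        raise RuntimeError(
            f"calibration target {target_psc} pA unreachable in bracket "
            f"[{a_lo:.3g}, {a_hi:.3g}] pA")
    for _ in range(60):
        mid = math.sqrt(lo * hi)  # geometric: PSC spans decades over bracket
        a = amp(mid)
        if abs(a - target_psc) <= tol * target_psc:
            group.g_unit = mid
            return mid
        if a < target_psc:
            lo = mid
        else:
            hi = mid
    group.g_unit = mid
    return mid


def calibrate_group(cell: CompiledCell, group: SynapseGroup,
                    seed: int = 0) -> float:
    """Calibrate one group against its replicated experiment."""
    cond_name, v_cmd, e_gaba, n_act, target = CALIBRATION_TARGETS[group.name]
    return calibrate_unitary_conductance(
        cell, group, target, CONDITIONS[cond_name], v_cmd,
        n_active=n_act, seed=seed, e_gaba=e_gaba)


def make_events(groups: dict[str, SynapseGroup], trains: dict[str, list],
                rng=None) -> list:
    """Map per-class spike-train lists onto active terminals.

    ``trains[name]`` must hold one spike-time array (seconds) per active
    terminal of that group; active terminals are a seeded draw when the
    group has inactive ones.  Returns kernel events (t_ms, comp, group,
    g_unit) sorted by time.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    events = []
    for name, group in groups.items():
        tr = trains.get(name, [])
        terms = np.asarray(group.terminals)
        if group.n_active < len(terms):
            terms = rng.choice(terms, size=group.n_active, replace=False)
        if len(tr) != len(terms):
            raise ValueError(
                f"{name}: {len(tr)} trains for {len(terms)} active terminals")
        gi = group.group_index
        for comp, spikes in zip(terms, tr):
            for s in np.asarray(spikes):
                events.append((s * 1e3, int(comp), gi, group.g_unit))
    events.sort()
    return events
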