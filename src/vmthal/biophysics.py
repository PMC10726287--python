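"""Membrane biophysics: parameters, ion accumulation, channel distributions.

Holds the per-state parameter sets of the thalamocortical models (normal and
parkinsonian / dopamine-depleted), the calcium microdomain shell model, the
Nernst and Goldman-Hodgkin-Katz relations, and the subcellular distribution
rules that turn a parameter set plus a compiled morphology into
per-compartment conductance densities.

Units
-----
Conductance densities are stored as printed (uS/cm2) and converted to S/cm2
with ``UNIT_SCALE`` when the density map is built; the L-type Ca
permeabilities are likewise 1e-6 cm/s.  Voltages mV, times ms, temperatures
degC, concentrations mM, currents mA/cm2.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import kinetics
from .morphology import MorphTree

__all__ = [
    "UNIT_SCALE", "FARADAY", "GAS_R", "CA_UNIT",
    "GateModifier", "ChannelSpec", "CaMicrodomain", "ModelParams",
    "CHANNEL_NAMES", "q10_factor", "nernst_potential", "ghk_flux",
    "ghk_ca_reversal", "update_calcium", "canonical_params", "apply_xe991",
    "apply_distribution", "DensityMap",
]

FARADAY = 96485.33212   # C/mol
GAS_R = 8.31446         # J/(mol K)
UNIT_SCALE = 1e-6       # printed uS/cm2 -> S/cm2
#: scale of the printed L-type permeabilities p1/p2 -> cm/s.  The printed
#: permeability unit is not interpretable as-is; the scale is chosen so the
#: Ca microdomains (with their fitted shell depths and decay constants)
#: operate in a graded sub-micromolar range during tonic firing.
PERMEABILITY_SCALE = 1e-9

#: charge-to-concentration factor of the Ca shell model:
#: d[Ca]/dt (mM/ms) = -CA_UNIT * i (mA/cm2) * delta (1/um)
CA_UNIT = 1e4 / (2.0 * FARADAY)

CHANNEL_NAMES = ["NaT", "NaP", "KDR", "KA", "KD", "KM", "IH", "CaT", "CaL",
                 "SK", "BK"]

CA_REST = 5e-5   # mM (50 nM) resting intracellular Ca
CA_OUT = 2.0     # mM extracellular Ca


@dataclass
class GateModifier:
    """Fitted kinetic modifiers of one channel."""

    tau_m: float = 1.0       # multiplicative factor on activation tau
    tau_h: float = 1.0       # ... on inactivation tau
    tau_n: float = 1.0       # ... on KDR activation tau
    v_half_shift: float = 0.0  # mV added to half-values (KD, BK)

    def __post_init__(self) -> None:
        if min(self.tau_m, self.tau_h, self.tau_n) <= 0:
            raise ValueError("tau multipliers must be positive")


@dataclass
class ChannelSpec:
    """Density parameters of one channel (uS/cm2 as printed)."""

    name: str
    g: float = 0.0
    g_extra: float = 0.0   # additional AIS density
    g_min: float = 0.0     # KM only: voltage-independent floor component
    p1: float = 0.0        # CaL only: permeability feeding microdomain L1
    p2: float = 0.0        # CaL only: permeability feeding microdomain L2
    mods: GateModifier = field(default_factory=GateModifier)

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel {self.name}")
        if min(self.g, self.g_extra, self.g_min, self.p1, self.p2) < 0:
            raise ValueError("densities must be non-negative")


@dataclass
class CaMicrodomain:
    """One Ca shell: first-order influx/decay below the membrane.

    L1 and L2 are fed by the two L-type components and drive BK and SK
    respectively; T is fed by the T-type current and drives nothing (it sets
    the T-type reversal only).
    """

    name: str
    tau: float            # ms
    delta: float          # 1/um inverse shell depth
    resting_ca: float = CA_REST
    current_ca: float = CA_REST

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class ModelParams:
    """Full per-state parameter vector of one thalamocortical model."""

    state: str
    r_i: float                  # Ohm cm
    v_rest: float               # mV
    g_leak: float               # uS/cm2
    channels: dict[str, ChannelSpec]
    ca_domains: dict[str, CaMicrodomain]
    c_m: float = 1.0            # uF/cm2, fixed
    na_branch_attenuation: float = 0.5  # Na density factor per branch point

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)

    def kinetic_mods(self) -> dict:
        """Modifier dict consumed by :mod:`vmthal.kinetics`."""
        return {
            "tm_nat": self.channels["NaT"].mods.tau_m,
            "th_nat": self.channels["NaT"].mods.tau_h,
            "tn_kdr": self.channels["KDR"].mods.tau_n,
            "tm_km": self.channels["KM"].mods.tau_m,
            "tm_bk": self.channels["BK"].mods.tau_m,
            "shift_kd": self.channels["KD"].mods.v_half_shift,
            "shift_bk": self.channels["BK"].mods.v_half_shift,
        }

    def to_dict(self) -> dict:
        """Serializable document keyed by the published symbol names."""
        doc: dict = {"state": self.state,
                     "r_i": self.r_i, "V_rest": self.v_rest,
                     "g": self.g_leak, "c_m": self.c_m}
        for name, ch in self.channels.items():
            entry: dict = {"g": ch.g}
            if ch.g_extra:
                entry["g_extra"] = ch.g_extra
            if ch.g_min:
                entry["g_min"] = ch.g_min
            if name == "CaL":
                entry = {"p_1": ch.p1, "p_2": ch.p2}
            if ch.mods.tau_m != 1.0:
                entry["T_m"] = ch.mods.tau_m
            if ch.mods.tau_h != 1.0:
                entry["T_h"] = ch.mods.tau_h
            if ch.mods.tau_n != 1.0:
                entry["T_n"] = ch.mods.tau_n
            if ch.mods.v_half_shift != 0.0:
                entry["V_1/2,shift"] = ch.mods.v_half_shift
            doc[name] = entry
        doc["Ca_buffer"] = {k: {"tau": d.tau, "delta": d.delta}
                            for k, d in self.ca_domains.items()}
        return doc

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


# ---------------------------------------------------------------------------
# canonical parameter sets (published means per state)

_TABLE = {
    "normal": dict(
        r_i=156.35, v_rest=-77.6, g_leak=13.29,
        NaT=dict(g=6235.45, g_extra=193703.0, tau_m=0.55, tau_h=0.48),
        NaP=dict(g=685.0, g_extra=14818.8),
        KDR=dict(g=14715.1, g_extra=83856.7, tau_n=0.72),
        KA=dict(g=739.57),
        KD=dict(g=129.15, v_half_shift=14.16),
        KM=dict(g=306.76, g_min=12.97, g_extra=16629.2, tau_m=8.86),
        IH=dict(g=40.97),
        CaT=dict(g=38.14),
        CaL=dict(p1=93.78, p2=498.43),
        SK=dict(g=433.52),
        BK=dict(g=10450.4, v_half_shift=-62.22, tau_m=6.23),
        L1=dict(tau=31.0, delta=2.2),
        L2=dict(tau=1639.33, delta=9.75),
        T=dict(tau=52.7, delta=17.19),
    ),
    "parkinsonian": dict(
        r_i=165.27, v_rest=-73.3, g_leak=6.64,
        NaT=dict(g=9995.27, g_extra=184569.0, tau_m=0.66, tau_h=0.36),
        NaP=dict(g=650.59, g_extra=12377.9),
        KDR=dict(g=16559.7, g_extra=57216.8, tau_n=0.64),
        KA=dict(g=1153.67),
        KD=dict(g=142.91, v_half_shift=23.43),
        KM=dict(g=9.69, g_min=18.51, g_extra=18731.6, tau_m=4.83),
        IH=dict(g=55.57),
        CaT=dict(g=82.54),
        CaL=dict(p1=119.8, p2=534.23),
        SK=dict(g=736.62),
        BK=dict(g=8339.23, v_half_shift=-47.81, tau_m=5.58),
        L1=dict(tau=23.79, delta=1.62),
        L2=dict(tau=1682.75, delta=10.42),
        T=dict(tau=48.06, delta=16.54),
    ),
}


def canonical_params(state: str) -> ModelParams:
    """Published mean parameter set for ``'normal'`` or ``'parkinsonian'``."""
    if state not in _TABLE:
        raise ValueError("state must be 'normal' or 'parkinsonian'")
    t = _TABLE[state]
    channels = {}
    for name in CHANNEL_NAMES:
        e = t[name]
        mods = GateModifier(tau_m=e.get("tau_m", 1.0),
                            tau_h=e.get("tau_h", 1.0),
                            tau_n=e.get("tau_n", 1.0),
                            v_half_shift=e.get("v_half_shift", 0.0))
        channels[name] = ChannelSpec(name, g=e.get("g", 0.0),
                                     g_extra=e.get("g_extra", 0.0),
                                     g_min=e.get("g_min", 0.0),
                                     p1=e.get("p1", 0.0), p2=e.get("p2", 0.0),
                                     mods=mods)
    domains = {k: CaMicrodomain(k, t[k]["tau"], t[k]["delta"])
               for k in ("L1", "L2", "T")}
    return ModelParams(state, t["r_i"], t["v_rest"], t["g_leak"],
                       channels, domains)


def apply_xe991(params: ModelParams, block: float = 0.7) -> ModelParams:
    """M-current blocker: scales the gated KM densities by ``1 - block``.

    The blocker acts on the gated conductance everywhere (somatodendritic and
    AIS extra); the voltage-independent floor ``g_min`` is the
    blocker-insensitive residual and is left untouched.
    """
    p = params.copy()
    km = p.channels["KM"]
    km.g *= (1.0 - block)
    km.g_extra *= (1.0 - block)
    return p


def scale_km(params: ModelParams, factor: float) -> ModelParams:
    """Multiply the gated somatodendritic KM density (the rescue manipulation)."""
    p = params.copy()
    p.channels["KM"].g *= factor
    return p


# ---------------------------------------------------------------------------
# electro-diffusion relations

def q10_factor(temp: float, ref_temp: float, q10: float) -> float:
    """``q10 ** ((temp - ref_temp)/10)``; multiplies rates, divides taus."""
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    return q10 ** ((temp - ref_temp) / 10.0)


def nernst_potential(z: int, conc_in: float, conc_out: float,
                     temp: float) -> float:
    """Nernst reversal potential in mV."""
    if conc_in <= 0 or conc_out <= 0:
        raise ValueError("concentrations must be positive")
    T = temp + 273.15
    return 1e3 * GAS_R * T / (z * FARADAY) * np.log(conc_out / conc_in)


def ghk_flux(v: float, conc_in: float, conc_out: float, temp: float,
             z: int = 2):
    """Goldman-Hodgkin-Katz flux per unit permeability.

    Returns the current density in mA/cm2 produced by a permeability of
    1 cm/s, for voltage ``v`` (mV) and concentrations in mM.  Negative values
    are inward.  The zero-flux voltage coincides with the Nernst potential.
    """
    v = np.asarray(v, float)
    T = temp + 273.15
    xi = z * FARADAY * (v * 1e-3) / (GAS_R * T)
    xi = np.clip(xi, -500, 500)
    small = np.abs(xi) < 1e-6
    with np.errstate(over="ignore", invalid="ignore"):
        frac = np.where(small,
                        conc_in - conc_out + 0.5 * xi * (conc_in + conc_out),
                        (conc_in - conc_out * np.exp(-xi))
                        / np.where(small, 1.0, 1.0 - np.exp(-xi)) * xi)
    # mM -> mol/cm3 is 1e-6; A/cm2 -> mA/cm2 is 1e3
    out = z * FARADAY * frac * 1e-3
    return out if out.ndim else float(out)


def ghk_ca_reversal(ca_in: float, ca_out: float, temp: float) -> float:
    """Effective Ca reversal potential (mV): the GHK zero-flux voltage."""
    return nernst_potential(2, ca_in, ca_out, temp)


def update_calcium(domain: CaMicrodomain, i_ca: float, dt: float) -> CaMicrodomain:
    """Advance one Ca shell by ``dt`` ms under current density ``i_ca`` (mA/cm2).

    d[Ca]/dt = -CA_UNIT * delta * i_ca - ([Ca] - [Ca]_rest)/tau, integrated
    exactly for constant current over the step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    target = domain.resting_ca - CA_UNIT * domain.delta * i_ca * domain.tau
    decay = np.exp(-dt / domain.tau)
    domain.current_ca = target + (domain.current_ca - target) * decay
    return domain


# ---------------------------------------------------------------------------
# subcellular distributions

@dataclass
class DensityMap:
    """Per-compartment channel densities (S/cm2) and CaL permeabilities (cm/s)."""

    g: np.ndarray            # (n_channels, n_comp) S/cm2, gated component
    g_km_floor: np.ndarray   # (n_comp,) S/cm2 voltage-independent KM floor
    p_cal: np.ndarray        # (2, n_comp) cm/s, components feeding L1 and L2
    g_leak: np.ndarray       # (n_comp,) S/cm2
    channel_index: dict[str, int]


def apply_distribution(params: ModelParams, tree: MorphTree) -> DensityMap:
    """Realize the subcellular distribution rules on a compiled tree.

    Rules: voltage-gated K channels uniform over soma and dendrites; Na
    densities attenuated by a constant factor per branch point; CaT doubled
    on primary dendrites and halved elsewhere; CaL halved in the proximal
    10 um of primary dendrites and set to a third elsewhere; SK/BK follow the
    CaL profile and are absent from the axon; IH uniform somatodendritically
    and absent from the AIS; AIS extra densities: NaT and KDR on the proximal
    half, NaP and KM on the distal half.
    """
    comps = tree.compartments
    if not comps:
        raise ValueError("tree must be compiled (no compartments found)")
    n = len(comps)
    idx = {name: i for i, name in enumerate(CHANNEL_NAMES)}
    g = np.zeros((len(CHANNEL_NAMES), n))
    g_floor = np.zeros(n)
    p_cal = np.zeros((2, n))
    g_leak = np.full(n, params.g_leak * UNIT_SCALE)
    ch = params.channels
    # section branch depth lookup for Na attenuation
    depth = {nd.id: nd.branch_depth for nd in tree.nodes}
    att = params.na_branch_attenuation
    for j, c in enumerate(comps):
        r = c.region
        if r not in ("soma", "primary_dend", "dend", "ais_proximal",
                     "ais_distal"):
            raise ValueError(f"unknown region tag {r!r}")
        somato = r in ("soma", "primary_dend", "dend")
        ais = not somato
        # uniform K channels
        for name in ("KDR", "KA", "KD", "KM"):
            g[idx[name], j] = ch[name].g
        g_floor[j] = ch["KM"].g_min
        # sodium: attenuate per branch point in dendrites
        na_fac = att ** depth.get(c.section_id, 0) if r in ("primary_dend", "dend") else 1.0
        g[idx["NaT"], j] = ch["NaT"].g * na_fac
        g[idx["NaP"], j] = ch["NaP"].g * na_fac
        # IH somatodendritic only
        g[idx["IH"], j] = ch["IH"].g if somato else 0.0
        # Ca channels and Ca-gated K: absent in axon
        if somato:
            if r == "soma":
                cat_f, cal_f = 1.0, 1.0
            elif r == "primary_dend":
                cat_f = 2.0
                cal_f = 0.5 if c.distance_from_soma <= 10.0 else 1.0 / 3.0
            else:
                cat_f = 0.5
                cal_f = 1.0 / 3.0
            g[idx["CaT"], j] = ch["CaT"].g * cat_f
            p_cal[0, j] = ch["CaL"].p1 * cal_f
            p_cal[1, j] = ch["CaL"].p2 * cal_f
            g[idx["SK"], j] = ch["SK"].g * cal_f
            g[idx["BK"], j] = ch["BK"].g * cal_f
        # AIS extra densities; the anatomical rules bound them at a multiple
        # of the somatic density (19x Na, 5x KDR, 50x KM), so the fitted
        # g_extra applies up to that cap
        if ais:
            def extra(name, cap):
                return min(ch[name].g_extra, cap * ch[name].g)
            if r == "ais_proximal":
                g[idx["NaT"], j] += extra("NaT", 19.0)
                g[idx["KDR"], j] += extra("KDR", 5.0)
            else:
                g[idx["NaP"], j] += extra("NaP", 19.0)
                g[idx["KM"], j] += extra("KM", 50.0)
    g *= UNIT_SCALE
    g_floor *= UNIT_SCALE
    p_cal *= PERMEABILITY_SCALE
    return DensityMap(g, g_floor, p_cal, g_leak, idx)
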