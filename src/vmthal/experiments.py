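"""In-vivo-like experiments and their analyses.

Simulations at body temperature driven by the four afferent ensembles:
baseline firing, sensitivity of the output rate to afferent parameters,
synchronous nigral bursting with post-inhibitory PSTH analysis and
per-current attribution, beta-band rate modulation with spike-phase locking
(circular statistics) and phase-resolved decomposition of synaptic and
membrane currents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter

from . import spiketrains as st
from .simulate import CONDITIONS, CompiledCell, SimResult, integrate
from .synapses import GROUP_INDEX, SynapseGroup, make_events

__all__ = [
    "InVivoConfig", "InVivoResult", "run_invivo", "psth", "firing_rate",
    "CircularStats", "circular_stats", "SensitivityResult",
    "sensitivity_sweep", "postinhibitory_analysis", "attribute_currents",
    "PhaseDecomposition", "current_decomposition",
]


@dataclass
class InVivoConfig:
    """One in-vivo-like scenario.

    ``beta`` maps class name -> :class:`~vmthal.spiketrains.BetaConfig` for
    modulated afferents; ``burst`` (with ``sync_fraction``) switches the SNR
    ensemble to bursting mode.  ``snr_g_scale`` implements the "+20% SNR
    conductance" scenario (1.2).  Temperature is fixed at 37 degC.
    """

    state: str = "normal"
    duration: float = 10.0                   # s
    rates: dict = field(default_factory=lambda: dict(st.NOMINAL_RATES))
    shape: float = 5.0
    refractory: float = 3.0                  # ms
    beta: dict = field(default_factory=dict)
    burst: st.BurstConfig | None = None
    sync_fraction: float = 1.0
    snr_g_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class InVivoResult:
    sim: SimResult
    ensembles: dict                          # class -> SpikeEnsemble
    config: InVivoConfig
    seed: int

    @property
    def rate(self) -> float:
        """Somatic firing rate in Hz."""
        return self.sim.spikes.size / (self.config.duration)

    @property
    def burst_onsets(self) -> np.ndarray | None:
        ens = self.ensembles.get("SNR")
        if ens is None:
            return None
        return ens.meta.get("shared_onsets")


def _class_trains(name: str, n: int, cfg: InVivoConfig,
                  rng: np.random.Generator) -> st.SpikeEnsemble:
    rate = cfg.rates[name]
    if name == "SNR" and cfg.burst is not None:
        return st.gen_population(n, cfg.burst, cfg.sync_fraction,
                                 cfg.duration, int(rng.integers(2**31)))
    beta = cfg.beta.get(name)
    trains = []
    for _ in range(n):
        gcfg = st.GammaTrainConfig(rate=rate, shape=cfg.shape,
                                   refractory=cfg.refractory,
                                   duration=cfg.duration, seed=rng)
        if beta is not None:
            trains.append(st.apply_beta(gcfg, beta, cfg.duration, rng))
        else:
            trains.append(st.gen_gamma_train(gcfg))
    return st.SpikeEnsemble(trains, cfg.duration, meta={"class": name})


def run_invivo(cell: CompiledCell, groups: dict[str, SynapseGroup],
               config: InVivoConfig, seed: int,
               rec_stride: int = 8) -> InVivoResult:
    """Drive the model with all four ensembles for the configured duration.

    The seed controls both the terminal subsets used (active-terminal draw)
    and the spike trains, so a fixed seed reproduces the run bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    if config.snr_g_scale != 1.0:
        g = groups["SNR"]
        groups = dict(groups)
        groups["SNR"] = SynapseGroup(g.name, g.kinetics,
                                     g.g_unit * config.snr_g_scale,
                                     g.terminals, g.n_active)
    ensembles = {name: _class_trains(name, groups[name].n_active, config, rng)
                 for name in GROUP_INDEX}
    events = make_events(groups, {k: e.trains for k, e in ensembles.items()},
                         rng)
    sim = integrate(cell, CONDITIONS["invivo"], config.duration * 1e3,
                    events=events, rec_stride=rec_stride, seed=seed)
    return InVivoResult(sim, ensembles, config, seed)


def firing_rate(spikes_ms: np.ndarray, duration_ms: float) -> float:
    return np.asarray(spikes_ms).size / (duration_ms * 1e-3)


def psth(spike_sets, bin_ms: float, window_ms: float,
         onsets_ms=None):
    """Event-aligned instantaneous-rate histogram.

    ``spike_sets`` is a list of spike-time arrays (ms).  With ``onsets_ms``
    each set is aligned to every onset and counted over [0, window); without
    onsets the histogram spans [0, window) in absolute time.  Returns
    ``(bin_centers_ms, rate_hz, counts)``; the counts sum to the total
    number of in-window spikes.
    """
    if len(spike_sets) == 0:
        raise ValueError("at least one spike set is required")
    edges = np.arange(0.0, window_ms + bin_ms / 2, bin_ms)
    counts = np.zeros(edges.size - 1)
    n_align = 0
    for spikes in spike_sets:
        spikes = np.asarray(spikes, float)
        if onsets_ms is None:
            counts += np.histogram(spikes, edges)[0]
            n_align += 1
        else:
            for t0 in np.asarray(onsets_ms, float):
                counts += np.histogram(spikes - t0, edges)[0]
                n_align += 1
    rate = counts / (n_align * bin_ms * 1e-3)
    centers = edges[:-1] + bin_ms / 2.0
    return centers, rate, counts


@dataclass
class CircularStats:
    circular_mean: float     # degrees in [0, 360)
    circular_sd: float       # degrees, sqrt(-2 ln R)
    resultant_R: float
    rayleigh_p: float
    n: int
    defined: bool = True


def circular_stats(spike_times_s, frequency: float) -> CircularStats:
    """Phase-locking statistics of spikes against an oscillation.

    Phases are spike times folded on the oscillation period (phase 0 at the
    rising zero-crossing of the modulating sinusoid).  The Rayleigh test
    gives the probability of the observed resultant under uniformity.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    t = np.asarray(spike_times_s, float)
    if t.size == 0:
        return CircularStats(np.nan, np.nan, np.nan, np.nan, 0, defined=False)
    phase = 2.0 * np.pi * np.mod(t * frequency, 1.0)
    z = np.exp(1j * phase).mean()
    R = float(np.abs(z))
    mean_deg = float(np.degrees(np.angle(z)) % 360.0)
    sd_deg = float(np.degrees(np.sqrt(max(0.0, -2.0 * np.log(max(R, 1e-300))))))
    from pingouin import circ_rayleigh
    _, p = circ_rayleigh(phase)
    return CircularStats(mean_deg, sd_deg, R, float(p), int(t.size))


def folded_rate_depth(spike_times_s, frequency: float, nbins: int = 120,
                      smooth_window: int = 15) -> float:
    """Modulation depth of the period-folded spike rate.

    Spikes (possibly pooled over repetitions) are folded on the oscillation
    period, the phase histogram is smoothed with a first-order circular
    Savitzky-Golay filter, and the depth is the half peak-to-trough excursion
    relative to the mean.
    """
    t = np.asarray(spike_times_s, float)
    if t.size == 0:
        return np.nan
    phase = np.mod(t * frequency, 1.0)
    counts = np.bincount(np.minimum((phase * nbins).astype(int), nbins - 1),
                         minlength=nbins).astype(float)
    win = min(smooth_window, nbins - 1)
    if win % 2 == 0:
        win -= 1
    sm = savgol_filter(counts, win, 1, mode="wrap")
    return float((sm.max() - sm.min()) / (2.0 * sm.mean()))


@dataclass
class SensitivityResult:
    parameter: tuple          # (kind, class)
    grid: np.ndarray          # percent variations
    rates: np.ndarray         # (n_grid, n_reps) Hz
    pearson_r: float
    p_value: float


def sensitivity_sweep(rate_fn, parameter: tuple,
                      grid=(-10.0, -5.0, 0.0, 5.0, 10.0),
                      n_reps: int = 3, seed: int = 0) -> SensitivityResult:
    """Output-rate sensitivity to one afferent parameter.

    ``rate_fn(scale, seed) -> Hz`` must realize the model response with the
    parameter multiplied by ``scale`` (1 + pct/100); the sweep pools
    ``n_reps`` seeded repetitions per grid point and reports the Pearson
    correlation between percent variation and rate (t-test significance).
    ``parameter`` is ``(kind, class)`` with kind in g_syn | n_syn | rate.
    """
    kind = parameter[0]
    if kind not in ("g_syn", "n_syn", "rate"):
        raise ValueError(f"unknown parameter kind {kind!r}")
    grid = np.asarray(grid, float)
    if not np.allclose(grid, -grid[::-1]):
        raise ValueError("grid must be symmetric about 0")
    rng = np.random.default_rng(seed)
    rates = np.empty((grid.size, n_reps))
    for i, pct in enumerate(grid):
        for j in range(n_reps):
            rates[i, j] = rate_fn(1.0 + pct / 100.0, int(rng.integers(2**31)))
    x = np.repeat(grid, n_reps)
    y = rates.ravel()
    if np.allclose(y, y[0]):
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(x, y)
    return SensitivityResult(parameter, grid, rates, float(r), float(p))


def make_invivo_rate_fn(cell: CompiledCell, groups: dict,
                        config: InVivoConfig, parameter: tuple):
    """Build a ``rate_fn`` for :func:`sensitivity_sweep` over real runs."""
    kind, cls = parameter

    def rate_fn(scale: float, seed: int) -> float:
        g = dict(groups)
        cfg = config
        if kind == "g_syn":
            grp = g[cls]
            g[cls] = SynapseGroup(grp.name, grp.kinetics, grp.g_unit * scale,
                                  grp.terminals, grp.n_active)
        elif kind == "n_syn":
            grp = g[cls]
            g[cls] = SynapseGroup(grp.name, grp.kinetics, grp.g_unit,
                                  grp.terminals,
                                  min(len(grp.terminals),
                                      int(round(grp.n_active * scale))))
        else:
            rates = dict(config.rates)
            rates[cls] = rates[cls] * scale
            cfg = replace(config, rates=rates)
        return run_invivo(cell, g, cfg, seed).rate

    return rate_fn


def postinhibitory_analysis(psth_with, psth_without, bin_ms: float,
                            sd_mult: float = 2.0, min_consecutive: int = 3,
                            offset_ms: float = 150.0,
                            late_window_ms: float = 400.0):
    """Difference PSTH around synchronized bursts and the duration of the
    post-offset rate transient.

    ``psth_with``/``psth_without`` are burst-onset-aligned rate arrays on
    identical grids (with/without synchronous bursting).  Synchronized
    bursting also changes the steady interburst inhibition, so the transient
    is measured on the difference trace against its own late-window
    (last ``late_window_ms``) mean + ``sd_mult`` * SD: the elevation duration
    is the first run of >= ``min_consecutive`` bins above that level,
    starting at the burst offset (``offset_ms`` after onset).
    """
    a = np.asarray(psth_with, float)
    b = np.asarray(psth_without, float)
    if a.shape != b.shape:
        raise ValueError("PSTH grids do not match")
    diff = a - b
    n_late = max(3, int(late_window_ms / bin_ms))
    late = diff[-n_late:]
    thresh = late.mean() + sd_mult * late.std()
    i0 = int(offset_ms / bin_ms)
    # light smoothing stabilizes the duration estimate
    k = np.ones(min_consecutive) / min_consecutive
    sm = np.convolve(diff, k, mode="same")
    post = sm[i0:]
    if post.size == 0:
        raise ValueError("offset beyond the PSTH window")
    ipk = int(np.argmax(post[:max(1, int(200.0 / bin_ms))]))
    peak = post[ipk]
    significant = bool(peak > thresh)
    duration = 0.0
    mask = np.zeros(diff.size, bool)
    if significant:
        # duration: from the offset until the transient decays below half
        # its peak height over the late-window baseline
        half = late.mean() + 0.5 * (peak - late.mean())
        j = ipk
        while j < post.size and post[j] > half:
            j += 1
        duration = j * bin_ms
        mask[i0:i0 + j] = True
    return {"difference": diff, "elevated": mask, "duration_ms": duration,
            "significant": significant, "threshold": float(thresh),
            "peak": float(peak)}


def attribute_currents(res_with: SimResult, res_without: SimResult) -> dict:
    """Per-channel current differences between burst and no-burst runs (nA)."""
    out = {}
    for name, tr in res_with.i_channel.items():
        out[name] = tr - res_without.i_channel[name]
    for name, tr in res_with.i_syn.items():
        out[f"syn_{name}"] = tr - res_without.i_syn[name]
    return out


@dataclass
class PhaseDecomposition:
    phase_deg: np.ndarray
    rate: np.ndarray            # Hz folded firing rate
    i_syn: dict                 # class -> nA folded
    i_channel: dict             # channel -> nA folded
    net_synaptic: np.ndarray    # smoothed
    net_membrane: np.ndarray    # smoothed (leak excluded)
    net_total: np.ndarray
    peaks: dict                 # up/down peak phases per net trace
    modulation_depth: float     # (max-min)/(2*mean) of the folded rate


def _fold(t_ms, x, period_ms, nbins):
    phase = np.mod(t_ms, period_ms) / period_ms
    idx = np.minimum((phase * nbins).astype(int), nbins - 1)
    sums = np.bincount(idx, weights=x, minlength=nbins)
    cnts = np.bincount(idx, minlength=nbins)
    return sums / np.maximum(cnts, 1)


def current_decomposition(res: SimResult, frequency: float,
                          spikes_ms: np.ndarray | None = None,
                          nbins: int = 120, smooth_points: int = 101,
                          t_start_ms: float = 0.0) -> PhaseDecomposition:
    """Fold recorded currents and firing on the oscillation period.

    Every per-channel and per-synapse-group current trace is first smoothed
    in time with a first-order Savitzky-Golay filter (101-sample kernel by
    default), then averaged within phase bins of the modulation period; net
    synaptic (all four afferent classes) and net membrane (all voltage/Ca
    gated channels; the leak is excluded) currents and their up/down peak
    phases are reported.  The folded spike rate is smoothed over a ~10-ms
    circular window.
    """
    period = 1e3 / frequency
    t = res.t
    keep = t >= t_start_ms
    t = t[keep]
    spikes = res.spikes if spikes_ms is None else np.asarray(spikes_ms)
    spikes = spikes[spikes >= t_start_ms]
    phase_deg = (np.arange(nbins) + 0.5) / nbins * 360.0

    def presmooth(x):
        win = min(smooth_points, x.size - 1)
        if win % 2 == 0:
            win -= 1
        return savgol_filter(x, win, 1) if win >= 3 else x

    i_syn = {k: _fold(t, presmooth(v[keep]), period, nbins)
             for k, v in res.i_syn.items()}
    i_ch = {k: _fold(t, presmooth(v[keep]), period, nbins)
            for k, v in res.i_channel.items()}
    # folded firing rate from spike phases
    sp_phase = np.mod(spikes, period) / period
    counts = np.bincount(np.minimum((sp_phase * nbins).astype(int), nbins - 1),
                         minlength=nbins)
    n_periods = (t[-1] - t[0]) / period if t.size else 1.0
    rate = counts / max(n_periods, 1e-9) / (period * 1e-3 / nbins)

    # circular smoothing of the folds over ~10 ms
    win = int(round(10.0 / (period / nbins)))
    win = max(3, min(win, nbins - 1))
    if win % 2 == 0:
        win -= 1

    def smooth(x):
        return savgol_filter(x, win, 1, mode="wrap")

    net_syn = smooth(sum(i_syn.values()))
    net_mem = smooth(sum(i_ch.values()))
    net_tot = net_syn + net_mem
    rate_smooth = smooth(rate.astype(float))

    def peaks(x):
        return {"up": float(phase_deg[int(np.argmax(x))]),
                "down": float(phase_deg[int(np.argmin(x))])}

    # modulation depth of the folded rate, measured on the smoothed fold
    # (up/down excursions from the mean, as the phase histograms are read)
    mean_rate = rate_smooth.mean()
    depth = float((rate_smooth.max() - rate_smooth.min()) / (2.0 * mean_rate)) \
        if mean_rate > 0 else np.nan
    return PhaseDecomposition(
        phase_deg, rate, i_syn, i_ch, net_syn, net_mem, net_tot,
        {"synaptic": peaks(net_syn), "membrane": peaks(net_mem),
         "total": peaks(net_tot), "rate": peaks(rate)},
        depth)
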