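"""Synthetic presynaptic spike trains for afferents to ventromedial thalamus.

All presynaptic activity driving the thalamocortical neuron models is
artificial: gamma-renewal trains with an absolute refractory period, burst
trains (a separately generated burst sequence merged onto a regular baseline),
population ensembles with a controllable fraction of trains sharing burst
onsets, and sinusoidal rate modulation in the beta band realized by
time-rescaling the renewal process.

Conventions
-----------
Spike times are in seconds, rates in Hz, refractory periods in milliseconds
(matching how the electrophysiology literature quotes them).  A gamma renewal
process with shape ``k`` has CV_ISI = 1/sqrt(k); the refractory period is
enforced by resampling intervals shorter than the refractory, which leaves the
gamma interval statistics (and hence the CV) essentially intact at
physiological rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GammaTrainConfig",
    "BurstConfig",
    "BetaConfig",
    "SpikeEnsemble",
    "gen_gamma_train",
    "gen_burst_train",
    "gen_population",
    "apply_beta",
    "train_stats",
    "NOMINAL_RATES",
]

#: Nominal presynaptic firing rates (Hz) per afferent class.
NOMINAL_RATES = {"DRI-l": 30.0, "MOD": 1.1, "RTN": 10.0, "SNR": 50.0}


@dataclass
class GammaTrainConfig:
    """Configuration of a gamma-renewal spike train.

    Parameters
    ----------
    rate : float
        Nominal firing rate in Hz.
    shape : float
        Gamma shape parameter (>= 1); expected CV_ISI = 1/sqrt(shape).
    refractory : float
        Absolute refractory period in ms.
    duration : float
        Train duration in seconds.
    seed : int or numpy Generator
        Randomness source.
    """

    rate: float = 50.0
    shape: float = 5.0
    refractory: float = 3.0
    duration: float = 10.0
    seed: int | np.random.Generator = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.shape < 1:
            raise ValueError("shape must be >= 1")
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")
        if self.rate * self.refractory * 1e-3 >= 1.0:
            raise ValueError(
                f"infeasible rate: {self.rate} Hz cannot be sustained with a "
                f"{self.refractory} ms refractory period"
            )


@dataclass
class BurstConfig:
    """Burst structure layered on a baseline train.

    Defaults are the nigral bursting configuration: ~150-ms bursts at an
    intraburst rate of ~170 Hz (gamma shape 3, 1.5-ms refractory), burst
    onsets recurring with mean interval 1 s (minimum 150 ms), and a 35-Hz
    regularized baseline between bursts.  ``interval_regularity`` is the gamma
    shape of the onset-interval distribution: 5 gives irregular (asynchronous)
    bursting, 50000 near-deterministic (synchronous) onsets.
    """

    burst_duration: float = 150.0          # ms
    intraburst_rate: float = 170.0         # Hz
    intraburst_shape: float = 3.0
    burst_refractory: float = 1.5          # ms
    interburst_rate: float = 35.0          # Hz baseline between bursts
    interburst_regularity: float = 50.0    # gamma shape of baseline ISIs
    interburst_interval_mean: float = 1.0  # s, burst onset-to-onset
    interburst_interval_min: float = 150.0  # ms
    interval_regularity: float = 5.0       # gamma shape of onset intervals
    rate_template: Sequence[float] | None = None  # intraburst rate profile

    def __post_init__(self) -> None:
        if self.interburst_interval_min * 1e-3 >= self.interburst_interval_mean:
            raise ValueError("interburst interval minimum must be below its mean")
        if self.interval_regularity <= 0 or self.interburst_regularity <= 0:
            raise ValueError("regularity must be positive")


@dataclass
class BetaConfig:
    """Sinusoidal rate modulation: lambda(t) = rate*(1 + depth*sin(2*pi*f*t + phi))."""

    frequency: float = 12.5   # Hz
    depth: float = 0.1        # fractional amplitude
    phase_offset: float = 0.0  # degrees

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth < 1.0:
            raise ValueError("depth must be in [0, 1)")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")


@dataclass
class SpikeEnsemble:
    """A set of presynaptic spike-time sequences plus generation metadata."""

    trains: list[np.ndarray]
    duration: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trains)

    def pooled(self) -> np.ndarray:
        """All spikes of all trains, sorted."""
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate(self.trains))


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _gamma_isis(rng: np.random.Generator, n: int, rate: float, shape: float,
                refractory_ms: float) -> np.ndarray:
    """Draw ``n`` ISIs (s) from gamma(shape, mean=1/rate), resampling ISIs that
    violate the refractory period."""
    scale = 1.0 / (rate * shape)
    isis = rng.gamma(shape, scale, size=n)
    refr = refractory_ms * 1e-3
    if refr > 0:
        bad = isis < refr
        # rejection: at physiological rates only a tiny fraction is redrawn
        for _ in range(100):
            nbad = int(bad.sum())
            if nbad == 0:
                break
            isis[bad] = rng.gamma(shape, scale, size=nbad)
            bad = isis < refr
        else:  # pragma: no cover - pathological configs rejected in config
            isis[isis < refr] = refr
    return isis


def gen_gamma_train(config: GammaTrainConfig) -> np.ndarray:
    """Generate one gamma-renewal spike train (times in s on [0, duration)).

    ISIs are drawn from a gamma distribution with mean 1/rate; draws below the
    refractory period are rejected and resampled, so every ISI respects the
    refractory period while CV_ISI stays at ~1/sqrt(shape).  The first spike
    is placed after an initial interval drawn from the same law (the process
    is started at an arbitrary spike, not equilibrated; the bias is negligible
    over the durations used here).
    """
    rng = _rng(config.seed)
    n_expect = int(config.rate * config.duration * 1.25) + 20
    times: list[np.ndarray] = []
    t = 0.0
    while t < config.duration:
        isis = _gamma_isis(rng, n_expect, config.rate, config.shape,
                           config.refractory)
        block = t + np.cumsum(isis)
        times.append(block)
        t = block[-1]
        n_expect = max(20, int((config.duration - t) * config.rate * 1.25) + 20)
    out = np.concatenate(times)
    return out[out < config.duration]


def _burst_onsets(rng: np.random.Generator, cfg: BurstConfig,
                  duration: float) -> np.ndarray:
    """Burst onset times: intervals = min + gamma(regularity, mean - min)."""
    lo = cfg.interburst_interval_min * 1e-3
    mean_extra = cfg.interburst_interval_mean - lo
    k = cfg.interval_regularity
    n = int(duration / cfg.interburst_interval_mean) + 10
    onsets: list[float] = []
    # first onset uniform within one mean interval so ensembles are not all
    # aligned at t=0
    t = rng.uniform(0.0, cfg.interburst_interval_mean)
    while t < duration:
        onsets.append(t)
        t += lo + rng.gamma(k, mean_extra / k)
    return np.asarray(onsets)


def _one_burst(rng: np.random.Generator, cfg: BurstConfig, onset: float) -> np.ndarray:
    """Spikes of a single burst starting at ``onset`` (s)."""
    dur_s = cfg.burst_duration * 1e-3
    if cfg.rate_template is None:
        # homogeneous intraburst rate
        isis = _gamma_isis(rng, int(cfg.intraburst_rate * dur_s * 2) + 10,
                           cfg.intraburst_rate, cfg.intraburst_shape,
                           cfg.burst_refractory)
        tt = np.cumsum(isis)
        return onset + tt[tt < dur_s]
    # template: piecewise-constant intraburst rate profile over the burst;
    # realized by time-rescaling the homogeneous generator
    prof = np.asarray(cfg.rate_template, float)
    mean_rate = float(prof.mean())
    edges = np.linspace(0.0, dur_s, prof.size + 1)
    cum = np.concatenate([[0.0], np.cumsum(prof * np.diff(edges))])  # integral of rate
    isis = _gamma_isis(rng, int(mean_rate * dur_s * 2) + 10, mean_rate,
                       cfg.intraburst_shape, cfg.burst_refractory)
    warped = np.cumsum(isis) * mean_rate  # expected-count coordinate
    tt = np.interp(warped, cum, edges)
    return onset + tt[warped < cum[-1]]


def gen_burst_train(base: GammaTrainConfig | None, bursts: BurstConfig,
                    duration: float, seed: int | np.random.Generator,
                    onsets: np.ndarray | None = None) -> np.ndarray:
    """Generate a bursty spike train (s).

    Burst sequences are generated separately and merged with a baseline train;
    baseline spikes falling inside a burst (or within the burst refractory of
    a burst spike) are removed.  ``onsets`` may be supplied to share one
    onset sequence across a synchronous population.

    ``base`` defaults to the burst config's interburst baseline (35 Hz at
    regularity 50 for the nigral configuration).
    """
    rng = _rng(seed)
    if onsets is None:
        onsets = _burst_onsets(rng, bursts, duration)
    if base is None:
        base = GammaTrainConfig(rate=bursts.interburst_rate,
                                shape=bursts.interburst_regularity,
                                refractory=bursts.burst_refractory,
                                duration=duration, seed=rng)
    else:
        base = GammaTrainConfig(rate=base.rate, shape=base.shape,
                                refractory=base.refractory,
                                duration=duration, seed=rng)
    baseline = gen_gamma_train(base)
    burst_spikes = [_one_burst(rng, bursts, t0) for t0 in onsets]
    burst_all = (np.concatenate(burst_spikes) if burst_spikes
                 else np.empty(0))
    burst_all = burst_all[burst_all < duration]
    if burst_all.size == 0:
        return baseline
    # merging removes baseline spikes colliding with burst spikes within the
    # burst refractory; other baseline spikes persist through bursts
    refr = bursts.burst_refractory * 1e-3
    j = np.searchsorted(burst_all, baseline)
    near = np.full(baseline.size, np.inf)
    ok_r = j < burst_all.size
    near[ok_r] = burst_all[j[ok_r]] - baseline[ok_r]
    ok_l = j > 0
    near[ok_l] = np.minimum(near[ok_l],
                            baseline[ok_l] - burst_all[j[ok_l] - 1])
    merged = np.sort(np.concatenate([baseline[near > refr], burst_all]))
    return merged


def gen_population(n_trains: int, bursts: BurstConfig, sync_fraction: float,
                   duration: float, seed: int,
                   base: GammaTrainConfig | None = None) -> SpikeEnsemble:
    """Ensemble of burst trains with a synchronous subset.

    ``sync_fraction`` of the trains share a single burst-onset sequence drawn
    with near-deterministic interval regularity (50000); the remainder burst
    independently with the asynchronous regularity of ``bursts``.  Baseline
    spikes are always independent across trains.
    """
    if n_trains < 1:
        raise ValueError("n_trains must be >= 1")
    if not 0.0 <= sync_fraction <= 1.0:
        raise ValueError("sync_fraction must be in [0, 1]")
    rng = _rng(seed)
    n_sync = int(round(sync_fraction * n_trains))
    sync_cfg = BurstConfig(**{**bursts.__dict__, "interval_regularity": 50000.0})
    shared = _burst_onsets(rng, sync_cfg, duration)
    trains = []
    for i in range(n_trains):
        if i < n_sync:
            trains.append(gen_burst_train(base, sync_cfg, duration, rng,
                                          onsets=shared))
        else:
            trains.append(gen_burst_train(base, bursts, duration, rng))
    return SpikeEnsemble(trains, duration,
                         meta={"sync_fraction": sync_fraction, "seed": seed,
                               "shared_onsets": shared, "n_sync": n_sync})


def apply_beta(config: GammaTrainConfig, beta: BetaConfig, duration: float,
               seed: int | np.random.Generator) -> np.ndarray:
    """Gamma-renewal train with sinusoidal rate modulation, via time-rescaling.

    The integrated rate Lambda(t) defines a warped time in which unit-mean
    gamma(shape) increments are generated; spike times are obtained by
    inverting Lambda with Newton iterations.  Folding the spikes on the
    modulation period gives a sinusoidal histogram of relative amplitude
    ~``beta.depth``, while the time-averaged rate equals the nominal rate.
    """
    rng = _rng(seed)
    r, k = config.rate, config.shape
    f, m = beta.frequency, beta.depth
    phi = np.deg2rad(beta.phase_offset)
    if m == 0.0:
        return gen_gamma_train(GammaTrainConfig(rate=r, shape=k,
                                                refractory=config.refractory,
                                                duration=duration, seed=rng))
    w = 2.0 * np.pi * f

    def lam(t: float) -> float:
        return r * (1.0 + m * np.sin(w * t + phi))

    def Lam(t: float) -> float:
        return r * (t - m / w * (np.cos(w * t + phi) - np.cos(phi)))

    refr = config.refractory * 1e-3
    times: list[float] = []
    t = 0.0
    L = 0.0
    scale = 1.0 / k
    while True:
        u = rng.gamma(k, scale)  # unit-mean increment in expected-count time
        target = L + u
        # Newton inversion of Lam(t) = target, started from constant-rate guess
        tn = t + u / r
        for _ in range(50):
            err = Lam(tn) - target
            tn -= err / lam(tn)
            if abs(err) < 1e-12 * max(1.0, target):
                break
        if refr > 0 and tn - t < refr and times:
            continue  # reject intervals violating the refractory, as unmodulated
        t, L = tn, target
        if t >= duration:
            break
        times.append(t)
    return np.asarray(times)


def train_stats(spikes: np.ndarray, duration: float | None = None) -> dict:
    """Rate, CV of ISIs and spike count of one train.

    Rate is count/duration (duration defaults to the last spike time); CV is
    SD(ISI)/mean(ISI) and is reported as nan with ``cv_defined=False`` when
    fewer than two spikes (one ISI) are available.
    """
    spikes = np.asarray(spikes, float)
    n = spikes.size
    if duration is None:
        duration = float(spikes[-1]) if n else 0.0
    out = {"n": n, "rate": n / duration if duration > 0 else np.nan}
    if n < 2:
        out.update(cv_isi=np.nan, cv_defined=False)
        return out
    isi = np.diff(spikes)
    out.update(cv_isi=float(np.std(isi) / np.mean(isi)), cv_defined=True)
    return out
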