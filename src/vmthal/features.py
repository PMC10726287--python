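"""Electrophysiology features of simulated traces, and model scoring.

The feature vocabulary follows the standard whole-cell battery used to fit
the thalamocortical models: spike shape (amplitude, width, fast/slow AHP),
spike timing (count, latency, inverse ISIs, adaptation, clustering), passive
measures (baseline, deflection, sag, input resistance, membrane time
constant).  A feature that is undefined on a given trace (e.g. ISI measures
without spikes) is reported as ``None`` rather than raising.

Model fitness is the sum over features of the absolute deviation from the
target mean normalized to the target standard deviation; missing features
contribute a fixed penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SimResult

__all__ = ["FeatureTargets", "extract_features", "score_model",
           "MISSING_PENALTY", "FEATURE_NAMES"]

MISSING_PENALTY = 250.0   # score contribution of an undefined feature

FEATURE_NAMES = [
    "AP_amplitude", "AHP_depth", "AP_width", "AP_count",
    "first_spike_latency", "inv_first_ISI", "inv_second_ISI", "inv_last_ISI",
    "adaptation_index2", "voltage_base", "voltage_after_stim",
    "AP_count_before_stim", "AP_count_after_stim", "max_amp_difference",
    "clustering_index", "fast_AHP", "AP1_amp_rev", "AP2_amp_rev",
    "time_to_first_spike", "sag_amplitude", "voltage_deflection",
    "decay_time_constant_after_stim2", "input_resistance",
]

DVDT_THRESHOLD = 20.0  # mV/ms, spike-onset detection for amplitude measures


@dataclass
class FeatureTargets:
    """Per-feature (mean, sd) targets; sd must be positive."""

    targets: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for k, (_, sd) in self.targets.items():
            if sd <= 0:
                raise ValueError(f"target sd for {k} must be positive")

    def __iter__(self):
        return iter(self.targets.items())


def _spike_shape(t, v, dt, spike_times):
    """Per-spike threshold, peak, amplitude, width, fast trough."""
    dvdt = np.gradient(v, dt)
    out = []
    n = v.size
    for k, ts in enumerate(spike_times):
        i = int(ts / dt)
        # onset: walk back to where dV/dt first exceeded the slope threshold
        j = i
        while j > 0 and dvdt[j] > DVDT_THRESHOLD:
            j -= 1
        v_on = v[j]
        # peak within 5 ms
        hi = min(n, i + int(5.0 / dt))
        pk = i + int(np.argmax(v[i:hi])) if hi > i else i
        amp = v[pk] - v_on
        # width at half amplitude
        half = v_on + amp / 2.0
        a = pk
        while a > 0 and v[a] > half:
            a -= 1
        b = pk
        while b < n - 1 and v[b] > half:
            b += 1
        width = (b - a) * dt
        # fast AHP: minimum within 10 ms of the peak (bounded by next spike)
        lim = n if k + 1 >= len(spike_times) else int(spike_times[k + 1] / dt)
        lo = min(lim, pk + int(10.0 / dt))
        trough = float(np.min(v[pk:lo])) if lo > pk else np.nan
        out.append(dict(onset=v_on, peak=v[pk], amp=amp, width=width,
                        fast_trough=trough))
    return out


def extract_features(res: SimResult, stim_on: float | None = None,
                     stim_off: float | None = None,
                     amplitude: float | None = None) -> dict:
    """Extract the feature set from one current-clamp trace.

    Stimulus window and amplitude default to the result's ``meta`` (set by
    :func:`vmthal.simulate.run_current_clamp`).  Values are mV/ms/pA-based:
    inverse ISIs in 1/ms, input resistance in MOhm, sag in percent.
    """
    meta = res.meta
    stim_on = meta.get("step_on", 0.0) if stim_on is None else stim_on
    stim_off = meta.get("step_off") if stim_off is None else stim_off
    amplitude = meta.get("amplitude") if amplitude is None else amplitude
    v, dt = res.v_soma, res.dt
    t_end = v.size * dt
    f: dict = {k: None for k in FEATURE_NAMES}

    base_lo = max(0.0, stim_on - 100.0)
    base = v[int(base_lo / dt):max(int(stim_on / dt), 1)]
    if base.size == 0:
        base = v[:1]
    f["voltage_base"] = float(base.mean())
    after = v[int(stim_off / dt):int(min(t_end, stim_off + 100.0) / dt)]
    if after.size:
        f["voltage_after_stim"] = float(after.mean())

    sp = res.spikes
    in_stim = sp[(sp >= stim_on) & (sp < stim_off)]
    f["AP_count"] = int(in_stim.size)
    f["AP_count_before_stim"] = int((sp < stim_on).sum())
    f["AP_count_after_stim"] = int((sp >= stim_off).sum())

    shapes = _spike_shape(res.t_full, v, dt, in_stim)
    if shapes:
        amps = np.array([s["amp"] for s in shapes])
        f["AP_amplitude"] = float(amps.mean())
        f["AP_width"] = float(np.mean([s["width"] for s in shapes]))
        f["max_amp_difference"] = float(amps.max() - amps.min())
        f["first_spike_latency"] = float(in_stim[0] - stim_on)
        troughs = [s["fast_trough"] for s in shapes if np.isfinite(s["fast_trough"])]
        if troughs:
            # fast AHP depth: onset voltage minus the post-spike trough
            f["fast_AHP"] = float(np.mean(
                [s["onset"] - s["fast_trough"] for s in shapes
                 if np.isfinite(s["fast_trough"])]))
        # slow AHP depth: baseline minus inter-spike minima
        if in_stim.size >= 2:
            mins = []
            for a, b in zip(in_stim[:-1], in_stim[1:]):
                seg = v[int(a / dt):int(b / dt)]
                if seg.size:
                    mins.append(seg.min())
            if mins:
                f["AHP_depth"] = float(f["voltage_base"] - np.mean(mins))
    if in_stim.size >= 2:
        isi = np.diff(in_stim)
        f["inv_first_ISI"] = float(1.0 / isi[0])
        f["inv_last_ISI"] = float(1.0 / isi[-1])
        if isi.size >= 2:
            f["inv_second_ISI"] = float(1.0 / isi[1])
            s = isi[:-1] + isi[1:]
            f["adaptation_index2"] = float(np.mean((isi[1:] - isi[:-1]) / s))
        half = stim_on + (stim_off - stim_on) / 2.0
        n1 = int((in_stim < half).sum())
        n2 = int((in_stim >= half).sum())
        if n2 > 0:
            f["clustering_index"] = n1 / n2

    # rebound (hyperpolarizing-step) measures
    reb = sp[sp >= stim_off]
    if reb.size:
        f["time_to_first_spike"] = float(reb[0] - stim_off)
        rshapes = _spike_shape(res.t_full, v, dt, reb[:2])
        f["AP1_amp_rev"] = float(rshapes[0]["amp"])
        if len(rshapes) > 1:
            f["AP2_amp_rev"] = float(rshapes[1]["amp"])

    # passive measures from the step segment (only meaningful without spikes
    # during the step, as in hyperpolarizing protocols)
    step = v[int(stim_on / dt):int(stim_off / dt)]
    if step.size and in_stim.size == 0 and amplitude is not None:
        vb = f["voltage_base"]
        peak_defl = float(step.min() - vb)
        ss = float(step[-max(1, int(100.0 / dt)):].mean() - vb)
        f["voltage_deflection"] = peak_defl
        if peak_defl < 0:
            f["sag_amplitude"] = 100.0 * (peak_defl - ss) / peak_defl
        if amplitude != 0:
            # MOhm: mV / nA
            f["input_resistance"] = ss / (amplitude * 1e-3)
    # membrane time constant from the post-pulse relaxation (brief-pulse
    # protocol): log-linear fit over the first 30 ms after offset
    if amplitude is not None and stim_off - stim_on <= 1.0 and after.size:
        seg = v[int(stim_off / dt):int((stim_off + 30.0) / dt)]
        vb = f["voltage_base"]
        dvr = np.abs(seg - vb)
        ok = dvr > 0.05 * np.abs(dvr[0]) if dvr.size and dvr[0] != 0 else None
        if ok is not None and ok.sum() > 10:
            tt = np.arange(ok.sum()) * dt
            slope = np.polyfit(tt, np.log(dvr[ok]), 1)[0]
            if slope < 0:
                f["decay_time_constant_after_stim2"] = float(-1.0 / slope)
    return f


def score_model(features: dict, targets: FeatureTargets,
                missing_penalty: float = MISSING_PENALTY,
                return_errors: bool = False):
    """Sum of normalized absolute feature errors, |f - mean| / sd.

    Only features present in ``targets`` contribute; a target whose feature
    is undefined adds ``missing_penalty``.  With ``return_errors`` the
    per-feature error dict is returned alongside the total.
    """
    errors = {}
    for name, (mean, sd) in targets:
        val = features.get(name)
        errors[name] = (missing_penalty if val is None
                        else abs(val - mean) / sd)
    total = float(sum(errors.values()))
    return (total, errors) if return_errors else total
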