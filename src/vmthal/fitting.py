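"""Model fitting and selection.

A seeded (mu+lambda) evolutionary strategy minimizes the summed normalized
feature error over a bounded parameter box (the full-scale fit used 100
individuals x 100 generations per session on a cluster; desk-scale runs use
smaller budgets).  Selection then applies the four sequential quality
filters used to build the published model populations:

1. every feature error within 3 SD of its target;
2. the whole f-I and rebound-versus-current curves within 3 SD pointwise;
3. the M-current blocker criterion: a 70% M-conductance block must shift the
   f-I curve of normal models detectably (paired Wilcoxon p < 0.1, rheobase
   shift < 100 pA) and leave parkinsonian models unchanged (p >= 0.9, no
   rheobase shift);
4. in-vivo-like firing rate within [5, 90] Hz under the baseline ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["FitResult", "fit_population", "sign_test", "fi_wilcoxon_p",
           "FilterContext", "apply_selection_filters"]


@dataclass
class FitResult:
    """Ranked outcome of an evolutionary run."""

    best_x: np.ndarray
    best_score: float
    hall_of_fame: list            # (x, score, errors) with all errors < 3 SD
    history: np.ndarray           # best score per generation
    n_evaluations: int


def fit_population(objective, bounds, pop_size: int = 50,
                   n_generations: int = 50, seed: int = 0,
                   sd_threshold: float = 3.0) -> FitResult:
    """Seeded evolutionary minimization of a summed feature score.

    ``objective(x)`` must return ``(score, errors)`` where ``errors`` is a
    per-feature array/dict of normalized deviations; candidates whose errors
    all fall below ``sd_threshold`` enter the hall of fame.  ``bounds`` is a
    sequence of (lo, hi) per parameter.  The search is (mu+lambda) with
    tournament selection, blend crossover and gaussian mutation whose scale
    anneals over generations; identical seeds give identical populations.
    """
    bounds = np.asarray(bounds, float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    rng = np.random.default_rng(seed)
    dim = lo.size
    mu = max(2, pop_size // 2)

    def evaluate(x):
        score, errors = objective(x)
        errs = np.asarray(list(errors.values()) if isinstance(errors, dict)
                          else errors, float)
        return float(score), errs

    pop = lo + span * rng.random((pop_size, dim))
    scored = []
    hof: list = []
    n_eval = 0
    for x in pop:
        s, e = evaluate(x)
        n_eval += 1
        scored.append((s, x, e))
        if e.size and e.max() < sd_threshold:
            hof.append((x.copy(), s, e))
    history = []
    for gen in range(n_generations):
        scored.sort(key=lambda se: se[0])
        history.append(scored[0][0])
        parents = scored[:mu]
        sigma = 0.25 * (1.0 - 0.9 * gen / max(1, n_generations - 1))
        children = []
        for _ in range(pop_size - mu):
            i, j = rng.integers(0, mu, size=2)
            alpha = rng.random(dim)
            child = alpha * parents[i][1] + (1 - alpha) * parents[j][1]
            child = child + rng.normal(0.0, sigma * span, size=dim)
            children.append(np.clip(child, lo, hi))
        scored = list(parents)
        for x in children:
            s, e = evaluate(x)
            n_eval += 1
            scored.append((s, x, e))
            if e.size and e.max() < sd_threshold:
                hof.append((x.copy(), s, e))
    scored.sort(key=lambda se: se[0])
    history.append(scored[0][0])
    # deduplicate hall of fame by parameter vector
    seen = set()
    hof_unique = []
    for x, s, e in sorted(hof, key=lambda h: h[1]):
        key = tuple(np.round(x, 12))
        if key not in seen:
            seen.add(key)
            hof_unique.append((x, s, e))
    return FitResult(scored[0][1].copy(), scored[0][0], hof_unique,
                     np.asarray(history), n_eval)


def sign_test(a, b) -> float:
    """Two-sided paired sign test p-value between matched count curves."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    k = int((d > 0).sum())
    return float(stats.binomtest(k, d.size, 0.5).pvalue)


def fi_wilcoxon_p(a, b) -> float:
    """Paired Wilcoxon p between two f-I curves (1.0 when identical)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.all(a == b):
        return 1.0
    return float(stats.wilcoxon(a, b).pvalue)


def _rheobase(amps, counts) -> float | None:
    """Smallest step amplitude evoking at least one spike."""
    for amp, c in zip(amps, counts):
        if c > 0:
            return float(amp)
    return None


@dataclass
class FilterContext:
    """Targets and thresholds of the selection filters.

    ``fi_targets`` / ``rebound_targets`` are (mean, sd) arrays matched to the
    candidates' ``fi_counts`` / ``rebound_counts`` grids.
    """

    fi_amps: np.ndarray
    fi_targets: tuple                    # (means, sds)
    rebound_targets: tuple | None = None
    sd_threshold: float = 3.0
    p_distinguishable: float = 0.1
    p_indistinguishable: float = 0.9
    max_rheobase_shift: float = 100.0    # pA
    rate_range: tuple = (5.0, 90.0)      # Hz


def apply_selection_filters(candidates: list, state: str,
                            ctx: FilterContext) -> list:
    """Apply the four sequential quality filters; returns the survivors.

    Each candidate is a dict with keys ``feature_errors`` (array or dict),
    ``fi_counts``, ``fi_counts_blocked`` (with the 70% M-current block),
    ``rebound_counts`` (optional), and ``invivo_rate``.  The surviving list
    preserves input order and is independent of it.
    """
    if state not in ("normal", "parkinsonian"):
        raise ValueError("state must be 'normal' or 'parkinsonian'")
    out = []
    fi_mean, fi_sd = (np.asarray(v, float) for v in ctx.fi_targets)
    for cand in candidates:
        errs = cand["feature_errors"]
        errs = np.asarray(list(errs.values()) if isinstance(errs, dict)
                          else errs, float)
        if errs.size == 0 or errs.max() >= ctx.sd_threshold:
            continue
        fi = np.asarray(cand["fi_counts"], float)
        if np.any(np.abs(fi - fi_mean) >= ctx.sd_threshold * fi_sd):
            continue
        if ctx.rebound_targets is not None and "rebound_counts" in cand:
            rb = np.asarray(cand["rebound_counts"], float)
            rm, rs = (np.asarray(v, float) for v in ctx.rebound_targets)
            if np.any(np.abs(rb - rm) >= ctx.sd_threshold * rs):
                continue
        fib = np.asarray(cand["fi_counts_blocked"], float)
        p = fi_wilcoxon_p(fi, fib)
        r0 = _rheobase(ctx.fi_amps, fi)
        r1 = _rheobase(ctx.fi_amps, fib)
        shift = None if r0 is None or r1 is None else r0 - r1
        if state == "normal":
            if p >= ctx.p_distinguishable:
                continue
            if shift is None or not 0.0 < shift < ctx.max_rheobase_shift:
                continue
        else:
            if p < ctx.p_indistinguishable or (shift or 0.0) != 0.0:
                continue
        rate = cand.get("invivo_rate")
        if rate is None or not ctx.rate_range[0] <= rate <= ctx.rate_range[1]:
            continue
        out.append(cand)
    return out
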