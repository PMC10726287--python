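# Methods

`vmthal` builds biophysically detailed multicompartment models of mouse
ventromedial motor thalamus (VM) thalamocortical (TC) neurons in a normal and
a dopamine-depleted (parkinsonian, 6-OHDA) state, drives them with synthetic
afferent activity, and reproduces the in-vitro protocols and in-vivo-like
experiments used to characterize how dopamine depletion changes synaptic
integration. This note documents the model, its assumptions, the parameters
that matter, and the choices made where the design was genuinely open.

## Morphology

A cell is a soma cylinder (36.9 × 24 µm), a two-cylinder axon initial
segment (AIS; each 1.5 × 35 µm — the axon is truncated beyond 70 µm), and a
binary dendritic tree. Dendritic diameters are assigned by three fitted laws:

* terminal sections: `diam = Q2 − M2·depth` (depth = branch points from the
  soma), clamped below at 0.1 µm (the linear law goes non-positive past
  depth 118; the clamp is configurable);
* branch points, tips-to-root: `diam = (Q1 + M1·Σ d_child^1.5)^(2/3)` — a
  Rall 3/2-power recursion (the outer exponent is the 2/3 root; diameters
  are assigned base-first, then tapered);
* primary dendrites additionally taper with path distance `d` from the soma
  surface by `max(1, C3 + A3·e^(−B3·d))`.

Defaults `M1=0.515, Q1=0.182, M2=0.004, Q2=0.473, A3=0.861, B3=0.045,
C3=0.858` are regression fits from VM reconstructions and are not re-fitted
here. For simulation the tree is compiled into cylindrical compartments of
at most 40 µm.

When no SWC reconstruction is supplied, a seeded generator builds a random
binary tree: section lengths exponential (mean 75 µm, floor 15 µm),
branching probability 0.9 decaying ×0.75 per depth level, five primary
dendrites, maximal depth 5. The defaults target the ~5.8-mm total dendritic
length of a full VM TC reconstruction — the length at which the reference
synapse totals (below) apply. The reference cell used throughout the tests
is `synth_skeleton(2)` (5853 µm of dendrite, 192 compartments). The
generator reproduces total length, branch-order statistics and the
proximal-thick/distal-thin diameter profile; it does not emulate 3-D
embedding, real path-length distributions of a specific reconstruction, or
reconstruction noise, so tests passing on it say nothing about
reconstruction-specific electrotonics.

## Membrane biophysics

Eleven Hodgkin–Huxley-type conductances: transient and persistent sodium
(NaT, NaP), delayed-rectifier/A-type/delaying/M-type potassium (KDR, KA, KD,
KM), H-current (IH), T- and L-type calcium (CaT, CaL), and the small/big
Ca-activated potassium currents (SK, BK). Gate steady states are Boltzmann
curves, time constants bell curves of voltage; all constants live in
`vmthal.kinetics`. The per-state parameter vectors (passive values, channel
densities, AIS extras, kinetic multipliers/shifts, Ca-buffer constants) are
the published fitted means and are exposed as `canonical_params(state)`.

Interpretations the printed tables leave open, resolved here:

* **Units.** Densities are µS/cm² (the printed unit header is inconsistent,
  but the running text prints the same numbers as µS/cm²). The two L-type
  permeabilities are scaled 1e-9 cm/s; at 1e-6 a single spike drives the
  Ca microdomains to ~0.1 mM and saturates SK (see below).
* **AIS extras.** The anatomical rules bound AIS densities at multiples of
  the somatic density (19× Na, 5× KDR, 50× KM); the fitted `g_extra` applies
  up to that cap. Without the cap the parkinsonian AIS KM would be ~1900×
  its somatic density and the model would respond strongly to the M-current
  blocker, contradicting its defining phenotype.
* **KM floor.** `g_min` is a voltage-independent, blocker-insensitive
  component of the M-like conductance: `i_KM = (g·m + g_min)(V − E_K)`. The
  XE991 manipulation (70% block) scales `g` and `g_extra` only.
* **NaP** is NaT with activation/inactivation half-values 14 mV lower.
* **Kinetic modifiers.** `T_m/T_h/T_n` multiply the respective time
  constants; `V_1/2,shift` adds to the KD and BK half-values.

Unprinted gate constants were calibrated so that the two canonical parameter
sets reproduce the published phenotypes — tonic firing without
depolarization block under the published bias currents, a parkinsonian f-I
everywhere above the normal one, the XE991 asymmetry, rescue of the
parkinsonian f-I by a ~40-fold KM increase, in-vivo rates inside 5–90 Hz,
and a post-inhibitory elevation that outlasts the normal model's in the
parkinsonian state. Three choices carry most of that behaviour:

* **KM** activates fast when depolarized but de-activates slowly when
  hyperpolarized (bell of the time constant centred at −75 mV). After a
  synchronized inhibitory volley the normal model's strong KM therefore
  recovers quickly, keeping its post-inhibitory boost brief.
* **BK** is voltage-gated with a Ca-dependent half-voltage and a slow base
  time constant (100 ms × the fitted `T_m`). It integrates spiking activity
  — the dominant rate-limiter at high rates — and recovers over hundreds of
  milliseconds after silence, which carries the long parkinsonian
  post-inhibitory elevation.
* **SK** reads the slow L2 microdomain (τ ≈ 1.6 s), i.e. it tracks mean
  firing rate; its half-activation (4 µM in shell units, Hill 2.5) puts it
  in a graded regime across 10–90 Hz.

Intracellular Ca is three first-order shells per compartment (L1 → BK,
L2 → SK, T → sets the T-type reversal), `d[Ca]/dt = −δ·i_Ca/(2F) −
([Ca]−[Ca]_rest)/τ`, with the fitted τ and δ per domain, resting 50 nM,
external 2 mM. L-type current uses the Goldman–Hodgkin–Katz flux with the
two permeabilities feeding L1 and L2; the T-type current uses its printed
conductance with the GHK zero-flux (Nernst) reversal of the T domain.
Gating rates scale with Q10 = 2.5 from the 34 °C reference (GABA decay uses
its own Q10 = 2.1 from 32 °C); temperature scales only time constants.

Distribution rules on the compiled tree: K channels uniform over soma and
dendrites; Na halved at each branch point (factor configurable); CaT 2× the
soma on primary dendrites and 0.5× elsewhere; CaL 0.5× within the proximal
10 µm of primary dendrites and 1/3 elsewhere, with SK/BK following that
profile and absent from the axon; IH somatodendritic only; AIS extras: NaT
and KDR on the proximal half, NaP and KM on the distal half.

## Numerics

Backward Euler on the compartment tree via Hines ordered elimination
(unconditionally stable; default dt 0.025 ms), gating by the exponential
(Rush–Larsen) rule with steady states and per-step relaxation factors
tabulated on a 0.05-mV grid, Ca-dependent gates and GHK fluxes evaluated
directly, Ca shells advanced by their exact exponential update, and the
(small) Ca currents treated explicitly. The per-step linear system is solved
exactly; the worst per-compartment charge-balance residual is tracked and
stays below 1e-6 mA/cm². Somatic voltage clamp is ideal (no series
resistance — no access resistances are published). Spikes are upward
crossings of −20 mV merged within 1 ms (detection settings are not
published; these are package defaults). Rebound spikes are counted within
300 ms of step offset. The compiled kernel runs a 2-s protocol on the
192-compartment reference cell in a few seconds.

## Synapses

Four afferent classes: glutamatergic modulators (MOD, layer-6-like) and
driver-like inputs (DRI-l, layer-5/subcortical), GABAergic nigral (SNR) and
reticular (RTN) inputs. Excitatory synapses are AMPA+NMDA
difference-of-exponentials (AMPA 0.2/1.0 ms, NMDA 2/25 ms at 34 °C; NMDA
peak ratio 1.91 for MOD and 0.6 for DRI-l at full unblock; Jahr–Stevens Mg
block with 2 mM Mg, the standard slice-aCSF concentration; reversal 0 mV).
Inhibitory synapses decay single-exponentially (14 ms at 32 °C, Q10 2.1,
reversal −81 mV). The excitatory time constants and Mg concentration are
not printed; they were chosen (fast thalamic values) so the printed terminal
counts, presynaptic rates and PSC-calibrated conductances produce a balanced
in-vivo operating point (~−60 mV, normal model ≈ 20 Hz) rather than
depolarization block.

Placement walks the dendrites at the class sampling spacing (0.8 µm MOD/RTN,
2.8 µm SNR) and distributes the class total over sites weighted by diameter
bracket (small 0–0.5 / medium 0.5–1 / large >1 µm). The bracket weights are
package defaults (the underlying electron-microscopy counts are
unpublished): MOD/RTN favour thin distal dendrites, SNR thick proximal ones,
and 20% of SNR terminals sit on the soma. DRI-l terminals are fixed at 10%
of the MOD count and placed by a proximal distance-from-soma law
(gamma, mean 30 µm). Class totals scale linearly with dendritic length and
equal the published full-scale totals (MOD 3625, DRI-l 350, SNR 25,
RTN 400) at the 5.8-mm reference length; 40% of MOD terminals are active
(1450 full-scale).

Unitary conductances are calibrated by bisection against the published PSC
amplitudes in replicas of the source voltage-clamp experiments (MOD
28.4 pA and RTN 24.43 pA miniature PSCs at −79.3 mV under TTX+cesium — the
RTN clamp uses a 0 mV GABA reversal, as the source pipette was
cesium/high-Cl; SNR 47.2 pA at −64 mV with one active terminal; DRI-l
123.7 pA — the published EPSC reduced 25% to absorb short-term depression —
at −68.4 mV with four active terminals). On the reference cell the
calibration converges to ≈1.5/0.9/2.8/0.6 nS (MOD/DRI-l/SNR/RTN); the
published full-reconstruction values (2.2/1.3/4.8/0.7 nS) differ because
dendritic filtering differs between cables — convergence to the PSC target,
not those values, is the contract.

## Presynaptic activity

Baseline trains are gamma renewal processes (shape 5 → CV_ISI = 1/√5 ≈
0.45) with a 3-ms refractory period enforced by resampling intervals below
the refractory — the convention that leaves the gamma CV intact, matching
the stated CV at the stated rates (nominal rates: DRI-l 30, MOD 1.1, RTN 10,
SNR 50 Hz). Nigral bursting merges separately generated bursts (~150 ms at
~170 Hz, gamma shape 3, 1.5-ms refractory, optional rate template) onto a
regularized 35-Hz baseline (gamma shape 50); burst onsets recur with mean
1 s (floor 150 ms) and onset-interval regularity 5 (asynchronous) or 50000
(synchronous; a population can share one onset sequence for a configurable
fraction of trains). Merging removes only baseline spikes within the burst
refractory of a burst spike; the rest persist through bursts. This
configuration yields 56.7 ± 1.2 Hz and CV_ISI 0.68 ± 0.015 (published:
55.7 ± 1.6, 0.69 ± 0.02). Beta modulation time-rescales the renewal process
through Λ(t) = ∫rate·(1 + depth·sin(2πft + φ)) (Newton inversion), which
preserves both the mean rate and the gamma irregularity while imposing a
sinusoidal folded rate of relative amplitude ≈ depth.

## Experiments and analysis conventions

In-vivo-like runs are at 37 °C with reversal potentials
temperature-extrapolated from the 27 °C slice condition; the seed controls
placement draws and all spike trains. Event-aligned PSTHs use 5–20 ms bins
(bin width is not published). The post-inhibitory transient is measured on
the difference PSTH (100% minus 0% synchronous bursting, aligned on burst
onsets over 1 s): significance is a peak above the late-window (last
400 ms) mean + 2 SD, and the duration runs from the burst offset until the
smoothed difference decays below half its peak over that baseline.
(Synchronized ensembles also inhibit less *between* bursts, so measuring
against the raw no-burst mean would count that sustained offset as
"elevation".)

Phase locking uses circular statistics: phases are spike times folded on the
modulation period (phase 0 at the rising zero-crossing of the SNR rate
sinusoid), with resultant R, circular mean, circular SD = √(−2 ln R), and
the Rayleigh test (via pingouin) for non-uniformity. Statistics are pooled
over seeded repetitions, as the source pooled models × simulations.
Amplification is the half peak-to-trough excursion of the smoothed folded
rate relative to its mean. Current decomposition smooths the recorded
per-channel and per-group current traces with the first-order 101-point
Savitzky–Golay filter in the time domain, folds them on the period, and
reports net synaptic, net membrane (leak excluded) and total currents with
their up/down peak phases; phase folds are smoothed over a ~10-ms circular
window (the 101-point kernel corresponds to ~10–20 ms at trace sampling
rates and would span most of a beta period if applied to a 120-bin fold).

Sensitivity sweeps vary one afferent parameter (unitary conductance, active
terminal count, or presynaptic rate) over a symmetric ±10% grid, pool seeded
repetitions, and report the Pearson correlation between percent variation
and output rate with its t-distribution significance (the significance test
named in the source could not be mapped to a standard procedure).

## Fitting and model selection

The trace features (spike amplitude/width/AHPs, counts, latencies, inverse
ISIs, adaptation index, clustering index, baselines, sag, deflection, input
resistance, membrane time constant) follow their standard definitions;
undefined features are flagged, not raised. Model fitness is Σ|f − mean|/SD
over target features (missing features add a fixed 250 penalty). The
optimizer is a seeded (mu+lambda) evolutionary strategy with tournament
parents, blend crossover and annealed gaussian mutation — a single-objective
stand-in for the original multiobjective fit, which ran 100 individuals ×
100 generations × 45 sessions on a cluster and is deliberately out of desk
scope. Experimental target means/SDs are not published; test fixtures
generate synthetic targets from known models, so the fitting loop is tested
as parameter recovery. Selection applies the four published filters in
order: all feature errors < 3 SD; f-I and rebound curves within 3 SD
pointwise; the M-blocker criterion (normal models shift detectably, paired
Wilcoxon p < 0.1 with rheobase shift < 100 pA; parkinsonian models do not,
p ≥ 0.9 and no rheobase shift); in-vivo rate within 5–90 Hz.

## Problem sizes

The suite runs everything at desk scale: one reference morphology per
state (not 16/17 fitted models), f-I curves over the full 15-step grid,
in-vivo runs of 5–20 s with 2–5 seeds per condition, and a 50 × 50
evolutionary fit on a passive toy cell. Published population-level numbers
(circular-statistics tables, exact post-inhibitory durations, exact
baseline rates) depend on the unpublished fitted model populations and are
reproduced as orderings and significance patterns, not values.

## Known limitations

* Channel gate equations are package calibrations within standard
  functional families, not the original (unpublished in the main text)
  kinetics; quantities that depend on exact gate shapes (absolute f-I
  slopes, exact rebound counts) differ from the source.
* The coarse 40-µm cable underestimates transient dendritic filtering, so
  calibrated unitary conductances land below the published ones.
* One synthetic morphology stands in for the reconstruction; electrotonic
  detail of the real cell is not reproduced.
* The parkinsonian in-vivo rate runs above the published mean (≈70 vs
  33 Hz) while remaining inside the published 5–90 Hz selection band and
  above the normal model, and state differences are reproduced as orderings.
* No short-term plasticity (absorbed into the DRI-l calibration target), no
  LFP model, no closed-loop cortex/RTN feedback.
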