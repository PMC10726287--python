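# vmthal

Biophysical models of mouse **ventromedial motor thalamus (VM)**
thalamocortical neurons in normal and dopamine-depleted (parkinsonian)
states, together with synthetic generators for their four afferent input
streams and the simulation experiments that probe how dopamine depletion
changes synaptic integration.

VM sits in the cortico–basal-ganglia–thalamocortical loop: it integrates
glutamatergic drive from motor cortex (layer-6-like *modulators*, MOD, and
layer-5/subcortical *driver-like* inputs, DRI-l) with GABAergic inhibition
from substantia nigra pars reticulata (SNR) and reticular thalamic nucleus
(RTN). Dopamine depletion suppresses the M-type potassium current of VM
neurons (the canonical parameter sets differ 32-fold in KM density),
increasing their excitability. The package asks what that change does under
in-vivo-like bombardment: baseline firing, sensitivity to each afferent,
responses to synchronous nigral bursting, and relay/amplification of
beta-band (12.5/25 Hz) oscillations with spike-phase locking.

The model is a multicompartment cable (soma, axon initial segment, and a
dendritic tree with diameters from fitted Rall-law recursions, compiled
into ≤40-µm compartments) carrying 11 Hodgkin–Huxley-type conductances
(NaT, NaP, KDR, KA, KD, KM, IH, CaT, CaL, SK, BK) with three intracellular
Ca²⁺ microdomains and GHK calcium fluxes, integrated by an implicit
(backward-Euler/Hines) solver with a numba-compiled kernel. Presynaptic
activity is gamma-renewal spike trains (CV_ISI = 1/√shape) with refractory
periods, burst injection with controlled population synchrony, and
sinusoidal beta rate modulation realized by time rescaling. See
`docs/methods.md` for the full model description.

## Worked example

```python
from vmthal import biophysics, morphology, simulate

tree = morphology.build_cell(morphology.synth_skeleton(2))   # ~5.8 mm dendrite
for state, bias in [("normal", 93.0), ("parkinsonian", 67.0)]:
    cell = simulate.compile_cell(tree, biophysics.canonical_params(state))
    proto = simulate.protocol("P1", state)                   # 2-s steps, 20..300 pA
    runs = simulate.run_current_clamp(cell, proto, simulate.CONDITIONS["b8"])
    counts = [len(r.spikes[r.spikes < 2000]) for r in runs]
    print(state, counts)
```

prints the f-I spike counts of the two canonical models under the slice
replication condition (27 °C, bias holding ≈ −69 mV):

```
normal       [0, 0, 1, 1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6]
parkinsonian [2, 8, 11, 13, 16, 18, 20, 21, 23, 25, 26, 28, 30, 31, 33]
```

The dopamine-depleted model fires at every current step at least as much as
the normal model and its rheobase is three 20-pA steps lower — the
excitability signature of M-current loss. Blocking 70% of the M-conductance
(`biophysics.apply_xe991`) left-shifts only the normal curve, and
multiplying the parkinsonian KM density by ~40 (`biophysics.scale_km`)
collapses its curve back onto the normal one. A hyperpolarizing −200 pA
step evokes 1 rebound spike in the normal and 5 in the parkinsonian model.

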