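# wbnet

Resting-state whole-brain network modeling with coupled Wendling
neural-mass nodes.

`wbnet` is for computational neuroscientists who want to simulate
resting-state electrophysiological activity on a structural connectome
and compare the resulting functional connectivity with a reference —
for example an empirical phase-locking matrix — without the MRI
preprocessing machinery that usually surrounds such models.  It
implements the full chain: stochastic simulation of coupled
neural-mass nodes, phase-locking-value (PLV) functional connectivity,
grid-search fitting of the global coupling coefficient, per-region
signal descriptors, and graph-theoretic / small-world characterisation
of thresholded networks.

## The model

Each of N cortical regions (by default the 68 regions of the
Desikan–Killiany atlas, 34 per hemisphere) is a Wendling neural mass:
four interacting populations — pyramidal cells, excitatory
interneurons, slow (GABA_B-like) and fast (GABA_A-like) inhibitory
interneurons.  Synaptic dynamics are second-order kernels
`h(t) = W w t e^{-wt}` with gain `W ∈ {A, B, G}` and inverse time
constant `w ∈ {a, b, g}`; membrane potential converts to firing rate
through the sigmoid

    S(v) = 2 e0 / (1 + exp(r (v0 − v))),

so each region is a 10-state ODE system.  Region *i*'s pyramidal
output `y_out^i = y1^i − y2^i − y3^i` drives other regions through the
structural connectome: the excitatory input of region *i* receives

    p_i(t) + C · Σ_j C_ij · S(y_out^j),

where `C_ij` is the max-normalised structural connectivity (symmetric,
zero diagonal, entries in [0, 1]) and `C` a single global coupling
coefficient.  `p_i(t)` is Gaussian pulse-density noise (mean μ = 90/s,
variance σ² = 30), sampled independently per region at every
integration step.  The network is integrated with fixed-step
fourth-order Runge–Kutta at 1000 Hz for 2 s; the first second is
discarded and the protocol is repeated 20 times with fresh initial
conditions — all defaults, all configurable.

Functional connectivity is the PLV matrix
`ρ_ij = |⟨e^{i(θ_i(t) − θ_j(t))}⟩_t|` of Hilbert-transform phases,
averaged over repetitions.  A simulated FC is compared to a reference
FC by the Pearson correlation of the strictly-lower-triangle entries,
and `C` is fitted by sweeping a grid and taking the argmax.
Thresholded FC graphs are described by average degree D,
characteristic path length L, clustering coefficient CC, global
efficiency E and the small-world index
`σ = (CC/CC_random) / (L/L_random)` against uniform random graphs with
matched node and edge counts.

Because empirical MRI-derived matrices are rarely redistributable, the
`wbnet.synth` module generates structurally realistic synthetic
connectomes (symmetric, max-normalised, heavier intra- than
inter-hemispheric log-normal weights) so that the entire chain is
runnable and testable out of the box.

## Worked example

```python
import numpy as np
from wbnet import (WendlingParams, SimulationConfig, CoupledSystem, SyntheticSCSpec,
                   make_synthetic_sc, simulate_repetitions, fc_matrix, average_fc,
                   compute_metrics, small_world_index, threshold_adjacency,
                   extract_features)

params = WendlingParams()                       # the standard parameter set
sc = make_synthetic_sc(SyntheticSCSpec(n_regions=12, seed=7))
system = CoupledSystem(params=params, connectome=sc, c_global=8.0)
config = SimulationConfig(seed=1)               # 1000 Hz, 2 s, 1 s discarded, 20 reps
reps = simulate_repetitions(system, config)

fc = average_fc([fc_matrix(r) for r in reps])
print(f"mean off-diagonal PLV: {fc.lower_triangle().mean():.3f}")

feats = extract_features(reps)
print(f"baseline range (mV): {feats.baseline.min():.2f} to {feats.baseline.max():.2f}")
print(f"dominant frequencies (Hz): {sorted(set(feats.dominant_freq.round(1)))}")

m = compute_metrics(fc, t=0.30)
print(f"threshold 0.30: D = {m.average_degree:.2f}, L = {m.path_length:.2f}, "
      f"CC = {m.global_clustering:.2f}, E = {m.efficiency:.2f}")
sw = small_world_index(threshold_adjacency(fc, 0.30), n_realizations=20, seed=0)
print(f"small-world sigma = {sw.sigma:.2f} (gamma = {sw.gamma:.2f}, lambda = {sw.lam:.2f})")
```

prints

```
mean off-diagonal PLV: 0.265
baseline range (mV): 1.66 to 3.47
dominant frequencies (Hz): [9.8]
threshold 0.30: D = 2.00, L = 2.69, CC = 0.21, E = 0.36
small-world sigma = 1.52 (gamma = 1.64, lambda = 1.08)
```

At this coupling every region's spectrum peaks in the alpha band
(~10 Hz, the weakly damped resonance of the driven Wendling node), the
PLV matrix carries genuine inter-regional structure above the
finite-sample floor, and the thresholded network is small-world
(σ > 1: clustering well above matched random graphs at a comparable
path length).  Uncoupled or weakly coupled regions instead sit at a
low-drive operating point producing low-amplitude broadband output —
the model's analogue of background activity in sparsely connected
regions.

The same chain is scriptable from the shell:

```sh
wbnet synth-sc --n-regions 12 --seed 7 --out sc.tsv
wbnet pipeline --sc sc.tsv --seed 1 --out-dir run/
```

`pipeline` writes the self-generated reference FC, the PCC-vs-C sweep
curve and summary, the FC at the best coupling, the per-threshold
graph-metric table and the per-region feature table, all as
tab-separated text.

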