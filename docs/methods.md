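# Methods

This note documents the model, the numerical choices, and the design
decisions behind `wbnet`, including what the synthetic data generator
does and does not emulate.

## Node model

Each region is a Wendling neural mass with 10 state variables: five
second-order synaptic kernel outputs `y0..y4` (mV) and their
derivatives `y5..y9`.  The kernel `h(t) = W w t e^{-wt}` is realised
as `ÿ = W w x − 2 w ẏ − w² y`, with `(W, w)` equal to `(A, a)` for
excitatory, `(B, b)` for slow inhibitory and `(G, g)` for fast
inhibitory synapses.  The sigmoid `S(v) = 2 e0 / (1 + exp(r (v0 − v)))`
is evaluated through `scipy.special.expit`, so it cannot overflow and
is exactly `e0` at `v = v0`.

The default parameters are the standard background-activity set:
A = 3.25 mV, B = 22 mV, G = 10 mV, a = 100/s, b = 50/s, g = 500/s,
C1 = 135, C2 = 108, C3 = C4 = 33.75, C5 = 40.5, C6 = 13.5, C7 = 108,
v0 = 6 mV, e0 = 2.5/s, r = 0.56/mV, μ = 90/s, σ² = 30.  All regions
share one parameter set; per-region heterogeneity is expressible only
by constructing separate systems, deliberately, to keep the
whole-brain model identical to its published form.

Coupling is instantaneous (the vector field contains no delayed
terms): region *i*'s excitatory input receives
`C · Σ_j C_ij · S(y_out^j)` where `y_out = y1 − y2 − y3`.  The sum
runs over all *j*; the connectome's zero diagonal enforces the absence
of self-coupling.  Units are seconds, millivolts and pulses per
second throughout, which fixes the integration step at 1 ms for the
1000 Hz protocol.

### Operating points of a node

With constant drive p ≈ 90/s the noise-free node has three fixed
points.  The two stable ones matter for interpretation:

* a **low state** (y_out ≈ 0.9 mV) with strong damping; its linearised
  transfer function peaks at 2–3 Hz, so noise-driven output is
  low-amplitude and broadband;
* an **upper state** (y_out ≈ 6.7 mV) with a weakly damped resonance
  at ≈ 10 Hz; noise-driven output there is a narrowband alpha rhythm.

Which basin a trajectory settles in depends on the initial conditions
and the early noise; with the default small random initial state
(uniform on [0, 0.1] mV per component) an *uncoupled* node usually
lands in the low state.  Long-range input shifts the effective drive
upward, so coupled, well-connected regions move to (or past) the upper
state and oscillate in the alpha band while weakly connected regions
keep producing broadband background — the behavior the worked example
in the README shows at C = 8.  A consequence worth knowing: a single
uncoupled node under the default protocol does *not* reliably show an
alpha-band dominant frequency; its spectral peak wanders over 2–12 Hz
from repetition to repetition (measured fraction in 5–12 Hz ≈ 0.45
over 100 repetitions).  The corresponding acceptance check in
`tests/test_acceptance.py` asserts the stricter in-band-for-90%-of-
repetitions property and therefore fails by design; it is kept as an
honest record of this dynamical fact rather than weakened.

## Integration and noise

The integrator is classic fixed-step RK4 with step h = 1/fs.  The
external input `p_i(t)` is sampled once per region per step from
N(μ, σ²) and held constant across the four stages of that step
(piecewise-constant drive).  σ² is the variance of those per-step
samples, with no 1/√h rescaling — the convention under which the
original single-node model's simulations are reported.  The
deterministic part of the scheme is genuinely fourth-order (the test
suite measures an error ratio of ~16 when halving h on the σ² = 0
system); the stochastic accuracy is that of piecewise-constant driving
and is not claimed to be of strong order > 1.

Randomness is organised as one `SeedSequence([seed, rep])` per
repetition, whose first child generates the initial state and whose
remaining N children generate each region's private noise stream.
Consequences, both asserted in tests: repetitions are individually
reproducible, and an uncoupled N-region run equals N single-region
runs bit for bit when fed the same streams.

Initial conditions are uniform on [0, init_scale] per state component
(default 0.1 mV).  A trajectory that leaves the finite floating-point
range raises `IntegrationDivergenceError` naming the step and regions
rather than clipping silently: extremely strong coupling is a
modelling error the user should see.  The bounded sigmoid makes true
divergence essentially impossible at physiological parameters; the
error path exists for pathological gains.

## Functional connectivity and coupling fit

Phases are Hilbert-transform angles of the demeaned broadband signal;
no band-pass is applied by default (an optional zero-phase Butterworth
band-pass exists for sensitivity analyses).  PLV matrices are computed
by one vectorised complex inner product, mirrored from the upper
triangle so symmetry is exact, diagonal set to 1.  The 20 repetitions
are aggregated by element-wise averaging of their PLV matrices —
the same convention as subject-averaging of empirical FC.

Similarity between FC matrices is the Pearson correlation over the
N(N−1)/2 strictly-lower-triangle entries; a zero-variance triangle is
an error, not a NaN.  `sweep_coupling` runs the full protocol at every
C on an inclusive grid (default 0–80 by 0.1; experiments in this
repository use coarser, shorter grids), records divergent grid points
as NaN without aborting the sweep, and breaks ties toward the smallest
C.

### The recovery experiment is a self-consistency check

The headline fitting experiment regenerates a reference FC with the
model itself at C* = 5.0 on a 12-region synthetic connectome and asks
the sweep (0–10, step 0.5) to find it, *re-using the same simulation
protocol and seeds*.  Under common random numbers the PCC-vs-C curve
peaks exactly at C* and decays to ≈ 0.70 at C = 0 and ≈ 0.39 at
C = 10, so the experiment measures the model's genuine sensitivity of
FC to C, with the noise realisation held fixed.

It is deliberately *not* a cross-seed identifiability claim: below
this small network's synchronization transition (C ≈ 6–8 for the
default synthetic connectome) the PLV pattern is dominated by the
finite-sample floor and is not reproducible across noise realisations
(cross-seed FC correlation ≈ 0 at C ≤ 5, rising to 0.8–0.9 for
C ≥ 8).  With only 1 s of retained signal per repetition that floor
is high (mean off-diagonal PLV ≈ 0.19 even for uncoupled regions,
against the i.i.d.-phase Rayleigh mean of √(π/4T) ≈ 0.028, because
the signals are strongly autocorrelated).  Users fitting real data
should sweep C into the synchronised regime and use longer
simulations than the default protocol if cross-run stability of the
FC pattern matters.

## Graph metrics

Binarisation uses the inclusive rule: off-diagonal weights ≥ t become
edges.  Metrics follow Brain-Connectivity-Toolbox conventions:

* D_i — row sums of the adjacency; D their mean.
* L — mean hop count over *reachable* ordered pairs, computed by
  unweighted shortest paths (`scipy.sparse.csgraph`); the number of
  unreachable ordered pairs is reported alongside rather than folded
  into the average.  An edgeless graph has no L.
* CC_i = 2 e_i / (k_i (k_i − 1)) with e_i the edges among neighbours
  (triangle counting via A³); nodes of degree < 2 get CC_i = 0, and CC
  is the mean over *all* N nodes.
* E — mean inverse hop distance over ordered pairs, zero for
  unreachable pairs; E of an edgeless graph is 0.
* Node strength is computed on the weighted matrix, not the binarised
  one.

The random reference for the small-world index is the uniform random
graph with identical node and edge counts (G(n, m)), not
degree-preserving rewiring: 20 realizations by default,
seed-controlled, disconnected realizations retained under the same
reachable-pair convention.  σ = (CC/CC_rand)/(L/L_rand); a zero
random-ensemble clustering makes σ undefined and raises.  All metric
implementations are cross-checked in the test suite against networkx
and against a brute-force Floyd–Warshall/triangle-enumeration oracle
on every connected graph with ≤ 7 nodes and 200 random graphs with
≤ 12 nodes.

## Signal features

The baseline potential is defined as the temporal mean of the
post-transient output (the natural reading of a mV-scale "baseline").
Spectra are Welch averaged periodograms, 512-sample Hann segments with
50% overlap by default; the dominant frequency is the in-band PSD
argmax (default band 0.5–45 Hz), ties broken toward the lower
frequency.  When several repetitions are supplied, PSDs are averaged
across repetitions before the argmax.

## Synthetic data

`make_synthetic_sc` emulates the *structure* of fiber-count
connectomes: symmetric nonnegative weights, zero diagonal,
max-normalisation, and heavier intra- than inter-hemispheric
connections.  Weight magnitudes are log-normal (heavy-tailed like
fiber counts) with linear-scale means 1.0 within and 0.35 between
hemispheres, spread σ_log = 1.0, and a default pair density of 0.6 —
dense enough that low thresholds produce complete-graph behavior.  It
does **not** emulate tractography biases, distance-dependent
connection probability, subject variability, or hemodynamics, so
passing tests demonstrate correctness of the pipeline on
structurally plausible inputs, not fidelity to any particular
empirical dataset.  `make_reference_fc` is plumbing that labels the
model's own output as a fitting target; `make_canonical_graph` wraps
the standard networkx constructions.

## Problem sizes used in the shipped experiments

The repository's experiments run at sizes chosen to make the full
chain routinely re-runnable on a laptop: 12-region connectomes for the
coupling sweep (21 grid points × 20 repetitions × 2 s at 1000 Hz),
68-node graphs for all graph-theory experiments, and 0.2 s
deterministic runs for the convergence study.  All sizes are plain
function arguments; nothing in the implementation is specific to
these choices.

## Known limitations

* Instantaneous coupling; no conduction delays.
* The stochastic integration scheme is the field's pragmatic
  convention, not a high-order SDE method.
* PLV on 1 s of broadband signal carries a high autocorrelation-
  inflated floor; cross-seed FC stability requires the synchronised
  regime or longer runs.
* The random reference for σ is G(n, m), which does not preserve the
  degree sequence; a rewiring-based reference would give somewhat
  different γ and λ on heterogeneous graphs.
* Whether a reference FC computed from band-limited empirical signals
  should be compared against band-limited simulated FC is left to the
  user via the optional `band` argument; no band is imposed.
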