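# Methods

## The model

`mrilnet` simulates a competitive network of two-compartment neurons that
learn temporal features of spike input without supervision.  Each output
neuron has

- a **dendritic compartment** whose potential is a weighted sum of filtered
  presynaptic spikes, `v_i = Σ_j w_ij e_j`, where each input spike drives a
  synaptic current with time constant `τ_syn` (5 ms by default, 50 ms in the
  slow, NMDA-like regime) that in turn evokes a PSP trace `e_j` with the
  membrane time constant `τ = 15 ms` and unit amplitude `e0 = 25`;
- a **somatic compartment** that leakily integrates the dendritic potential
  through the coupling conductance `g_D = 0.7`,
  `du_i/dt = −u_i/τ + g_D(−u_i + v_i) − Σ_j G_ij φ^som(u_j)/φ0`,
  with nonnegative lateral inhibitory weights `G`.

The soma fires as an inhomogeneous Poisson process with rate
`φ^som_i(u) = φ0 / (1 + exp(β_i(θ_i − u)))`.  The slope and threshold adapt
to running estimates of the mean `μ_i` and s.d. `σ_i` of the somatic
potential (`β_i = β0/σ_i`, `θ_i = μ_i + σ_i θ0`, `β0 = 5`), which makes the
rate a fixed sigmoid of the standardised potential `û = (u − μ)/σ`.  This
adaptation keeps firing in a fixed, informative dynamic range regardless of
the scale of the weights — and it is what rules out the trivial solution
`w = 0` of the learning rule below.

### The dendritic learning rule

Learning treats the somatic rate `φ^som(u)` and the rate implied by the
attenuated dendritic potential, `φ^dend(v*)` with `v* = αv` and
`α = g_D/(g_D + 1/τ) ≈ 0.913`, as two Poisson channels, and descends the
time-averaged KL divergence between them plus an L2 penalty:

    dw_i/dt = η { ψ(v*_i) [(φ^som_i(u_i) − φ^dend(v*_i))/φ0] e(t) − γ w_i }

with `ψ(x) = d log φ^dend/dx = β0(1 − φ^dend(x)/φ0)`.  The somatic rate is
treated as a constant of the gradient.  The rule is error-gated Hebbian:
inputs coactive with unpredicted somatic firing are potentiated, inputs
coactive with dendritic over-prediction are depressed.  A noise-augmented
variant replaces `φ^som` with `f(φ^som + φ0·g·ξ)`, `ξ ~ N(0,1)` per neuron
and step and `f` a clip to `[0, φ0]` (`g = 0.6` where used), so that
noise-dominated (negative) teaching signals are silenced rather than
converted into depression.

### Inhibitory plasticity

Lateral weights follow a symmetric anti-Hebbian spike-pairing rule,
`ΔG = Cp·exp(−|Δt|/τp) − Cd·exp(−|Δt|/τd)` with `Cp = 0.00525`,
`Cd = 0.0105`, `τp = 40 ms`, `τd = 20 ms`: near-coincident spikes
(|Δt| < 40·ln2 ≈ 27.7 ms) weaken inhibition, pairs at 28–200 ms strengthen
it, and the kernel integrates to exactly zero.  Neurons that respond to the
same feature therefore disinhibit one another and condense into assemblies,
while neurons responding to different features (which fire at systematic
lags) stay mutually inhibiting.  `G` is clipped to `[0, Gmax]` with
`Gmax = c/√N_out` (default `c = 0.7`); pairing is implemented with two
exponential traces per neuron and is exactly equivalent to the all-pairs
sum.  The sign-reversed "conventional" kernel is kept as a control.

## Numerical scheme

Forward Euler at `dt = 1 ms` (finer steps available; the stability guard
requires `dt ≤ min(τ_syn, τ)/5`).  The synaptic current uses an exact
exponential decay between spikes; a spike injects `1/(τ·τ_syn)` so that one
spike contributes area `1/τ` to `∫I dt`.  The running moments are
exponential moving averages with time constant `t0` (default 5 s) — same
fixed points as the boxcar average in O(1) memory; `σ` is clamped below at
0.01, and the moments start at `μ = 0`, `σ = 1`.  The lateral term uses
instantaneous rates; sampled somatic spikes drive only the inhibitory
plasticity.  Weight updates are applied every step (the rule is a
continuous-time SDE); `G` is clipped after every step.

The production path is a numba-compiled kernel with explicit loops (fixed
floating-point evaluation order); a pure-numpy step-by-step reference
implements the identical update sequence and consumes identical random
streams, and a test pins the two together at `rtol = 1e-9`.  All
randomness — input Poisson sampling, output-spike thinning, learning
noise — is pre-drawn from one `numpy.random.Generator`, so every result is
reproducible from a single seed.

## Synthetic stimuli and what they emulate

All experiments run on synthetic stimuli with exact ground truth:

- **Frozen patterns**: 50 ms spatiotemporal spike patterns (a single frozen
  Poisson realization, replayed identically) embedded in homogeneous
  background at matched population-mean rate (10 Hz here), occupying half
  of the timeline.  Emulates recurring motifs in population recordings;
  detection cannot rely on firing rates.  A `pattern_seed` separates
  pattern identity from background noise so long trainings can stream
  fresh-noise segments of the same task.
- **Character chunks**: random concatenations of letter strings; each input
  neuron bursts at 10 Hz for 30 ms for its preferred letter.  Optional
  distractor strings (length 3–7, letters a–z) and overlapping chunks
  (which require the 50 ms synapse).
- **Community walks**: a random walk on the standard 3×5 temporal-community
  graph (every node degree 4, all transition probabilities 0.25), nodes
  encoded like characters.  Transition statistics carry no segmentation
  cue; only community co-occurrence does.
- **Oriented bars**: 16×16 px bars at 8 orientations with truncated
  Gaussian pixel noise, 40 ms on / 30 ms off, intensities mapped linearly
  to rates.
- **Correlated sources**: two instrument-like amplitude envelopes playing
  the same score — shared note onsets/durations and score rests — with
  instrument-private note loudness, phrase-level dynamics (2–4 s), private
  rests, and per-instrument amplitude roughness at distinct rates in the
  15–30 Hz band (the beating of real sustained tones; it is the only
  structure at the timescale the spike-pairing kernel can sense).
  Dependent mode yields envelope correlation ≈ 0.42–0.51; independent mode
  |r| < 0.1.  Sources are mixed by `[[cosθ, sinθ], [sinθ, cosθ]]`
  (cross-talk `tanθ`) or the fixed `[[1, 0.5], [0.5, 1]]` preset
  (cross-talk 0.5), and mixture envelopes are encoded by two 250-neuron
  groups with rates normalized to `[0, 10 Hz]`.

What passing tests on these stimuli do **not** show: robustness to the
acoustic complexity of real audio (pitch, timbre, reverberation), to
non-stationary firing statistics of real neural data, or to image
statistics beyond isolated oriented bars.

## Evaluation conventions

Responses are smoothed somatic-rate traces (10 ms boxcar unless stated;
50–100 ms for trajectory-level analyses).  The preferred pattern of a
neuron is the one with the largest event-locked (trial-averaged) response
peak; a neuron is "others" when its second-best peak exceeds 50% of the
best.  Raw-trace maxima are not used: any neuron that ever crosses
threshold saturates at `φ0`, so raw peaks cannot rank patterns.  The
training-time learning curve correlates the *sampled somatic spike train*
(counts per 10 ms, smoothed) with `φ^dend` in 15 s windows; the rate–rate
correlation is near 1 from the outset (the soma is a low-passed copy of
the dendrite when `G = 0`) and is reported separately.  For continuous
sources, assemblies are discovered by response–envelope correlation
(argmax, with a 0.1 floor), because both sources are active in every epoch
and peak-based selectivity is undefined.  Principal-component fractions
come from the eigendecomposition of the covariance of the response traces.
The log-cosh negentropy uses `E[log cosh ρ] ≈ 0.37457` for standard-normal
ρ, computed by Gauss–Hermite quadrature (200 nodes) at import of the first
call, never hard-coded.

## Desk-scale study conditions

The figure-level experiments are scaled down to run on one CPU in minutes;
populations and durations below are the package's study conditions, chosen
once:

| task | inputs | outputs | training | learning |
|---|---|---|---|---|
| single-neuron patterns | 500 | 1 | 360 s | η=3e-5, γ=0.5 |
| assemblies (patterns) | 500 | 10 | 360 s | η=3e-5, γ=0.5, c=0.7 |
| minimal-assembly ordering | 500 | 5 | 900 s | η=1e-5, γ=0.2 |
| minimal-assembly, matched convergence | 500/1000 | 5 | 3600 s | η=2.5e-6, γ=0.2 |
| character chunks | 1000 | 10 | 300 s | η=3e-5, γ=0.5 |
| source separation | 500 | 10 | 300 s | η=3e-5, γ=0.5 |

`φ0 = 0.05 events/ms` (50 Hz) and `θ0 = 1` throughout (baseline rate
`φ0/(1+e^{β0θ0}) ≈ 0.33 Hz`, firing in the top ≈16% of the standardised
potential).  η and γ are task-tuned (as the regularization must be): γ
balances the Hebbian drive so `v*` stays in the sensitive range of the
fixed sigmoid; η trades convergence speed against the averaging needed to
lift weak recurring structure out of background (the sparse-pattern tasks
use the slowest schedules).  Long trainings stream the stimulus in ≤900 s
segments (`partial_fit`) to bound memory.

## Known limitations

- **Principal-component saturation.**  After chunk learning the top-3 PC
  fraction plateaus at ≈98.5% rather than >99%: residual variance comes
  from neurons with residual mixed selectivity and from within-assembly
  response heterogeneity, which at these training lengths never fully
  disappears.  The assemblies themselves are clean (reference correlations
  0.8+).
- **Occasional assembly collapse.**  In roughly one seed in five the
  10-neuron chunk network converges to fewer than three assemblies;
  aggregate results therefore use medians or seed majorities.
- **Separation of correlated mixtures is partial.**  The network groups
  neurons by source preference but the feedforward weights do not develop
  the negative lobe needed for true unmixing at these scales: with
  envelope-coded inputs the two mixture channels are ≈95% correlated, the
  common loudness mode dominates the input covariance, and output spikes
  carry almost no excess synchrony at the ±30 ms timescale of the
  inhibitory kernel, so competition cannot split the common mode.  Decoded
  sources correlate ≈0.4–0.6 with the truth, below the trivial mixture
  baseline (≈0.93).  The cross-talk sweep consequently does not reproduce
  the weak-cross-talk failure/rescue ordering.  Real audio carries fine
  temporal structure that the envelope stand-in cannot fully emulate; the
  machinery (mixing, encoding, decoding, negentropy, noisy rule, FastICA
  comparison) is complete and tested on its own contracts.
- Event-driven simulation is out of scope; the integrator is fixed-step.
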