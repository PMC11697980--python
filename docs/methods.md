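# Methods

This note documents the model, the numerical choices, and what the
synthetic fixtures do and do not establish.

## Neuron model

The self-inhibiting neuron is a discrete-time leaky integrate-and-fire
unit with an autapse. Five per-neuron parameters, all learnable:

| parameter | meaning | units | default init |
|---|---|---|---|
| `τ`  | membrane decay fraction per step; `(1−τ)` multiplies the previous potential | dimensionless, `[0,1]` | 0.5 |
| `γ`  | autaptic self-inhibition: subtracted from the input current one step after a spike | input-current units | 0.1 |
| `C`  | input gain (capacitance-like) | potential / current | 1.0 |
| `u_th` | firing threshold | potential | 1.0 |
| `u_re` | resting / hard-reset potential | potential | 0.0 |

Conventions fixed here (the recursions leave them open):

* **Strict threshold.** A spike requires `u − u_th > 0`; exact equality
  does not fire.
* **Hard reset.** On firing, the stored potential becomes exactly `u_re`.
* **Leaky rectifier.** The membrane update passes the full bracketed sum
  `(1−τ)u + τu_re + C·I` through LeakyReLU; negative slope 0.01
  (configurable). The rectifier is applied to the whole sum, including the
  resting term, in deep hyperpolarization.
* **Initialization.** `u(0) = u_re`, `o(0) = 0`. Homogeneous defaults are
  optionally jittered by seeded Gaussian noise (σ given by
  `alpha_jitter_sd`) to break symmetry before heterogeneous learning.
* **Time is dimensionless.** `dt_label` (nominal ms per step) is used only
  for reporting: similarity windows and the membrane time constant
  `MTC = −dt/ln(1−τ)` exported by `spike_histograms`.

## Gradients

The forward pass is binary and event-driven. For learning, the Heaviside
derivative is replaced by a triangular pseudo-derivative
`g(x) = (1/w)·max(0, 1 − |x|/w)` evaluated at the **pre-reset** membrane
potential; width `w = 1` threshold unit by default, zero outside
`|x| ≥ w`. The hard reset is treated as a non-differentiated gate.

Because no autodiff framework is used, correctness is established through
a **relaxed mode**: the Heaviside is replaced by the C¹ ramp whose exact
derivative is the triangle, the reset gate becomes differentiable, and the
hand-written backward pass then computes the *exact* gradient of that
graph. Central finite differences of the relaxed loss agree with the
backward pass to better than 1e−4 relative on every path (both readouts,
classification and generation losses, same-step and delayed inter-layer
timing, weights and all five biophysical parameters). The relaxed ramp is
C¹ but not C², so finite differences themselves carry O(h) error within h
of its kinks; the checks account for that with a denominator floor.

## Network conventions

* **Inter-layer timing.** The weighted-input recursion indexes the
  presynaptic output at `t−1`; layered unrollings can either pipeline that
  delay literally (`delayed_interlayer=True`) or propagate within the step
  (default). The same-step default matches few-step inference (`T` = 2–5),
  where a literal per-layer delay would leave deep layers silent for most
  of the window.
* **Readouts.** `membrane-accumulate` (default) averages the output
  layer's pre-threshold membrane over time — informative even when nothing
  spikes; `spike-count` sums output spikes.
* **Encodings.** Static features enter either as direct current (repeated
  real drive; counted as dense MACs in the energy model) or as seeded
  Bernoulli rate spikes; spike sequences pass through natively.
* **States are per-sample.** No leakage across a batch (asserted by a
  permutation test).

## Bi-level learning

The outer objective on the biophysics is the sub-validation loss plus
`λ·Ω(α)`; the inner is the sub-training loss on the weights. The splits
are disjoint by construction (stratified when labels exist; a class with
fewer than two members falls back to a non-stratified split with a
warning).

* **Hypergradient.** First order by default (set the inner rate to zero in
  the chain rule); second order keeps one inner step and approximates the
  mixed second derivative by a central finite difference with
  `ε = ε₀/‖∇_W L_u‖`, `ε₀ = 0.01`. A vanishing upper-gradient norm skips
  the second term and logs the event. At `ξ₁ = 0` both orders coincide
  exactly (tested elementwise).
* **Laplacian smoother.** `Ω = Σ_{(i,j)∈E} w_ij ‖α_i − α_j‖²` over a
  neuron neighbourhood graph, with each parameter field divided by a fixed
  unit scale (default 1). Dense layers have no spatial arrangement, so the
  default graph is a unit-weight chain over the neuron index; complete and
  custom graphs are available. Fixed unit scales (rather than data-driven
  standardization) keep `Ω` a deterministic function of `α` alone, with a
  well-defined gradient that does not couple all neurons through batch
  statistics.
* **Projection.** After each α step, `τ` is clipped to `[0,1]` and `γ` to
  `≥ 0`; no other constraints, and a validation report flags drifted
  `u_th ≤ u_re`.
* **Alternation.** One α step per epoch by default; per-batch alternation
  (`alpha_every_epoch=False, alternation=k`) performs an α step every `k`
  weight steps and is what the ablation experiments use — at a bad
  initialization the gradient signal per α step is weak, and more frequent
  small steps are what lets the biophysics adapt at all.
* **History.** `L_t` is the epoch-end loss on the full sub-training set
  (the running within-epoch batch mean is kept as `L_t_running`); `L_v`,
  `Ω`, validation accuracy and per-field α means/spreads are recorded per
  epoch. Identical config + seed reproduces the history bit-for-bit.

## Single-neuron fitting

Fitting a neuron to (current, spikes) trials minimizes the squared
van-Rossum distance: both trains are convolved with a causal exponential
kernel and compared in L2. Gradients flow through the hard spiking
recursion via the triangle surrogate; Adam (lr 0.02, 300 steps by
default) optimizes the free parameter fields over a vectorized population
of perturbed restarts (±50% uniform; restart 0 keeps the supplied
initialization, so initializing at the generating truth is a fixed point).

**Kernel width.** The kernel time constant defaults to 5 steps. Wider
kernels (≈ 20 steps, i.e. twice the 10-ms similarity window) were found to
blur exactly the post-spike interval that identifies the self-inhibition
strength, biasing fitted `γ` 15–25% low; at 5 steps the generating
`(τ, γ)` are recovered within 10% across fit seeds. The width is
configurable (`FitConfig.kernel_tau`).

An all-silent best fit is flagged (`FitResult.silent`) rather than
silently returned.

## Spike-train set similarity

The similarity between two sets of spike trains at window `Δt` is

    M = mean cross-set cosine / sqrt(within-A mean cosine × within-B mean cosine)

on boxcar-smoothed trains, with self-pairs excluded from the within-set
means (bias correction). When the two sets have equal size, index-matched
cross pairs are treated as trial-paired and excluded as well; this makes a
set compared with an identical copy of itself score exactly 1 and removes
the matched-trial bias in generation tasks, where trial `i` of the
generated set shares its input with trial `i` of the template set. The
statistic is symmetric, ≈ 1 in expectation for statistically identical
independent sets, and undefined (NaN + flag) for all-silent sets. As a
ratio estimator it can exceed 1 by sampling noise on small sets (the
bound tested is `[0, 1.15]` at 6 trains per set).

## Energy accounting

Event-driven (spiking) layers cost one accumulate per presynaptic spike
per fan-out; a direct-current front end costs dense multiply-accumulates
every step. Defaults `e_mac = 4.6 pJ`, `e_ac = 0.9 pJ` (conventional
45 nm floating-point figures; configurable). The dense reference is one
pass of the same architecture. On small direct-current networks the front
end dominates and the ratio can fall below 1 — the report states its
inputs so this is visible rather than hidden.

## Synthetic fixtures: what a green test establishes

All fixtures are pure functions of their seed.

* **Neuron traces**: Gaussian noise current (default mean 0.4, sd 0.5 in
  threshold units) keeps a unit-threshold neuron at an irregular
  ~0.2 spikes/step — enough spikes for the autapse to matter, far from
  saturation. Emulates noise-injection protocols; does not emulate
  electrode noise or biological non-stationarity.
* **Temporal classes**: binary class templates with *identical per-neuron
  spike counts across classes*, so time-collapsed rates are uninformative
  by construction; samples jitter each spike ±1 step with probability
  `jitter` (default 0.1). At the test geometry (2 neurons, T=5) the
  nearest-template ceiling is ≈ 0.96 while any time-permutation-invariant
  classifier caps near 0.58; the small spiking nets trained here reach
  ≈ 0.55–0.6 — above rate-chance (1/3), below the template ceiling. A
  green ablation test therefore establishes the *ordering* (heterogeneous
  ≥ homogeneous), not high absolute accuracy.
* **Expression matrices**: negative-binomial counts (dispersion 0.5), 20
  upregulated marker genes per type, configurable rare-class prevalence
  (default profile 1%; 0.09%-style prevalences are supported down to
  0.001). `n_cells` grows automatically so no class has fewer than 5
  cells. Emulates marker-driven separability, not batch effects, dropout
  structure, or cross-species shifts. The classifier uses balanced class
  weights; without them the 1% class is swallowed by the majority term of
  the loss.
* **Generation tasks**: templates are Bernoulli realizations of rates
  driven by 2 smooth sinusoidal latents, so a low-dimensional manifold
  exists by construction; inputs are one fixed Poisson noise pattern
  (plus optional per-trial Gaussian perturbation).

## Known limitations

* numpy BPTT holds the full unrolled cache in memory — fine for the
  desk-scale networks this package targets, unsuitable for
  convolutional-scale models.
* Plain SGD on the weights (the printed update rule) is deliberately
  simple; at the tiny fixture scales, accuracy ceilings reflect
  representational limits rather than optimizer failures (verified by
  training the relaxed graph).
* The second-order hypergradient keeps exactly one inner step; no
  implicit-function-theorem solver is provided.
* `Ω` penalizes only the biophysics, not the weights.
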