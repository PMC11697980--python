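# hetsnn

Heterogeneous spiking neural networks with self-inhibiting neurons and
bi-level learning, in pure numpy.

## Who this is for

Computational neuroscientists and neuromorphic-ML researchers who want a
small, fully inspectable implementation of:

* a **self-inhibiting spiking neuron** — a leaky integrate-and-fire unit
  extended with an autapse that subtracts a learnable amount `γ` from the
  neuron's input in the step after it fired, giving each neuron a one-step
  memory of its own activity;
* **heterogeneous learning** — instead of sharing one fixed neuron model
  across the network, every neuron owns five learnable biophysical
  parameters `α = [τ, γ, C, u_th, u_re]`, trained in a bi-level loop nested
  around ordinary synaptic-weight training;
* the **evaluation toolkit** around them: a bias-corrected spike-train set
  similarity, rare-class classification reports, spike-count energy
  accounting, PCA neural-manifold projection, and seeded synthetic fixtures
  for every pipeline stage (no downloads).

## The model

Per neuron `k` and time step `t`:

    S(t) = Σ_i w_ik · O_i(t−1)              weighted input from the layer below
    I(t) = S(t) − γ · O(t−1)                autaptic self-inhibition
    u(t) = f[(1−τ) u(t−1) + τ u_re + C I(t)]  leaky membrane, f = LeakyReLU
    O(t) = Θ(u(t) − u_th)                   spike iff u strictly exceeds u_th
    u(t) ← (1−O) u(t) + O u_re              hard reset

Training solves the bi-level program

    min_α  L_v(D_v; W*(α), α) + λ Ω(α)    s.t.  W*(α) = argmin_W L_t(D_t; W, α)

by alternating SGD steps on `W` (inner loop, sub-training split `D_t`) with
hypergradient steps on `α` (outer loop, disjoint sub-validation split
`D_v`). `Ω` is a graph-Laplacian smoother encouraging neighboring neurons
to share similar biophysics. The hypergradient is either first order
(drop the inner dependence) or second order (one inner step plus a central
finite difference of the mixed second derivative). Spike discontinuities
are handled with a triangular pseudo-derivative; the backward pass is
hand-written BPTT, verified against finite differences of a relaxed
(soft-spike) forward graph.

## Worked example

`python examples/02_fit_neuron_to_traces.py` recovers a neuron's
biophysics from a single 1000-step noise-current injection:

```
ground truth: tau=0.3, gamma=0.5; 221 spikes over 1000 steps
fitted      : tau=0.299, gamma=0.475, smoothed spike distance 0.0000
LIF ablation: distance 0.0295 (worse: the autapse is needed)
spike-train similarity of reproduction at a 10-step window: 1.000 (1 = identical sets)
```

The fit minimizes a van-Rossum-smoothed spike distance over five perturbed
restarts; `τ` and `γ` land within a few percent of the generating values,
while a `γ = 0` (plain LIF) ablation cannot explain the post-spike
suppression and ends with a ~30× worse distance.

`python examples/04_rare_cell_types.py` trains a spiking classifier on a
synthetic expression matrix with a 1% rare cell type (separability
certified by a nearest-centroid oracle) and reports `rare-class F1 = 1.0`
together with the event-driven energy accounting of the forward pass.

The other examples cover the autapse's effect on firing statistics (01),
bi-level training on a spike-timing task whose classes are invisible to
any rate-based readout (03), and spike-train similarity plus manifold
recovery on a generation fixture with a known 2-D latent (05).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computations from scratch on seeded synthetic
fixtures: neuron-trace fitting, bi-level training on the temporal and
expression tasks, and the evaluation metrics, writing the results JSON at
the end. All randomness derives from `--seed`.
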