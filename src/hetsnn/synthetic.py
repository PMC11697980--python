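"""Seeded synthetic fixtures for every pipeline stage.

Each generator is a pure function of its arguments (bit-reproducible given
the seed) and returns a ground-truth sidecar sufficient to score any
downstream stage without re-generation.  The fixtures emulate, at desk
scale: noise-current injections into a known neuron (trace fitting),
spatio-temporally coded class patterns (temporal classification),
negative-binomial expression matrices with rare cell types (the
transcriptomics task), and noise-to-template spike generation with a
low-dimensional latent manifold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .params import ContractError, NeuronParams, SpikeTrain, SurrogateSpec
from .neuron import simulate_neuron

KINDS = ("neuron-trace", "temporal-classes", "expression-matrix", "generation-task")


@dataclass
class FixtureSpec:
    """Declarative description of a fixture: kind + size/noise parameters + seed."""

    kind: str
    seed: int
    sizes: Dict[str, int] = field(default_factory=dict)
    noise: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ContractError(f"unknown fixture kind {self.kind!r}")
        if self.seed is None:
            raise ContractError("seed is mandatory")
        for k, v in self.sizes.items():
            if v < 1:
                raise ContractError(f"size {k} must be >= 1")


def gen_neuron_trace(
    params_true: NeuronParams,
    mean: float = 0.4,
    sd: float = 0.5,
    T: int = 1000,
    seed: int = 0,
    n_trials: int = 1,
) -> Tuple[np.ndarray, SpikeTrain, dict]:
    """Gaussian noise-current injections and the resulting ground-truth spikes.

    Returns ``(currents, spikes, sidecar)`` with currents ``(n_trials, T)``,
    spikes as a SpikeTrain with one row per trial, and a sidecar holding the
    generating parameters and a silence flag.  The default drive (mean 0.4,
    sd 0.5 in threshold units) keeps a unit-threshold neuron in an irregular
    ~0.1-0.2 spikes/step regime where the self-inhibition is exercised.
    """
    if T < 100:
        raise ContractError("need T >= 100 for a meaningful trace")
    rng = np.random.default_rng(seed)
    currents = mean + sd * rng.standard_normal((n_trials, T))
    rows = []
    for i in range(n_trials):
        rows.append(simulate_neuron(currents[i], params_true).spikes[0])
    spikes = SpikeTrain(np.stack(rows))
    sidecar = {
        "params_true": {f: params_true.as_dict()[f].tolist() for f in params_true.as_dict()},
        "mean": mean,
        "sd": sd,
        "T": T,
        "seed": seed,
        "zero_spike_warning": bool(spikes.spikes.sum() == 0),
    }
    return currents, spikes, sidecar


def _class_templates(n_classes: int, neurons: int, T: int, spikes_per_neuron: int, rng) -> np.ndarray:
    """Binary class templates with identical per-neuron spike counts across
    classes: the time-collapsed (rate) view of every class is the same, so
    class identity lives purely in spike timing."""
    templates = np.zeros((n_classes, neurons, T))
    for j in range(neurons):
        seen = set()
        for c in range(n_classes):
            while True:
                pos = tuple(sorted(rng.choice(T, size=spikes_per_neuron, replace=False)))
                if pos not in seen:
                    seen.add(pos)
                    break
            templates[c, j, list(pos)] = 1.0
    return templates


def gen_temporal_classes(
    n_classes: int = 3,
    neurons: int = 2,
    T: int = 5,
    jitter: float = 0.1,
    n_per_class: int = 40,
    seed: int = 0,
    spikes_per_neuron: int = 2,
) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Labeled spike-sequence dataset whose classes differ only in timing.

    Samples are jittered copies of class templates: each spike moves one
    step left or right with probability ``jitter`` (clipped at the edges).
    ``jitter = 0`` makes within-class samples identical.  Because per-neuron
    spike counts are equal across classes by construction, any classifier
    on time-collapsed rates is at chance, while a temporal model can
    separate the classes.  Returns ``(X, y, sidecar)`` with X of shape
    ``(n, neurons, T)``.
    """
    if n_classes < 2:
        raise ContractError("need >= 2 classes")
    if spikes_per_neuron >= T:
        raise ContractError("spikes_per_neuron must be < T")
    flags = []
    if jitter >= 1:
        flags.append("jitter >= 1 is degenerate (every spike moves)")
    rng = np.random.default_rng(seed)
    templates = _class_templates(n_classes, neurons, T, spikes_per_neuron, rng)
    X = np.zeros((n_classes * n_per_class, neurons, T))
    y = np.repeat(np.arange(n_classes), n_per_class)
    for s in range(X.shape[0]):
        base = templates[y[s]]
        out = np.zeros_like(base)
        for j in range(neurons):
            for t in np.flatnonzero(base[j]):
                if rng.random() < jitter:
                    t = int(np.clip(t + rng.choice([-1, 1]), 0, T - 1))
                out[j, t] = 1.0
        X[s] = out
    perm = rng.permutation(X.shape[0])
    sidecar = {"templates": templates, "jitter": jitter, "seed": seed, "flags": flags}
    return X[perm], y[perm], sidecar


def gen_expression_matrix(
    n_cells: int = 1000,
    n_genes: int = 100,
    type_proportions: Sequence[float] = (0.5, 0.3, 0.19, 0.01),
    marker_strength: float = 4.0,
    seed: int = 0,
    dispersion: float = 0.5,
    markers_per_type: int = 20,
    base_mean: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Negative-binomial count matrix with type-specific marker blocks.

    Each cell type upregulates its own block of ``markers_per_type`` genes
    by a factor ``marker_strength`` over the baseline mean.  The last
    proportion is conventionally the rare type (down to 0.001; a 0.0009
    profile mirrors very rare populations).  Counts use the NB(mean mu,
    dispersion r) parameterization with ``r = 1/dispersion``; log1p of
    median-normalized counts is also returned.  ``n_cells`` is adjusted
    upward if any class would receive fewer than 5 cells.

    Returns ``(counts, log1p_norm, labels, sidecar)``.
    """
    props = np.asarray(type_proportions, dtype=float)
    if props.min() <= 0 or abs(props.sum() - 1.0) > 1e-8:
        raise ContractError("type proportions must be positive and sum to 1")
    n_types = len(props)
    if n_types * markers_per_type > n_genes:
        raise ContractError("not enough genes for the marker blocks")
    min_count = 5
    if (props * n_cells).min() < min_count:
        n_cells = int(np.ceil(min_count / props.min()))
    rng = np.random.default_rng(seed)
    counts_per_type = np.floor(props * n_cells).astype(int)
    counts_per_type[0] += n_cells - counts_per_type.sum()
    labels = np.repeat(np.arange(n_types), counts_per_type)

    mu = np.full((n_types, n_genes), base_mean)
    for c in range(n_types):
        block = slice(c * markers_per_type, (c + 1) * markers_per_type)
        mu[c, block] *= 1.0 + marker_strength
    r = 1.0 / dispersion  # NB size parameter
    p = r / (r + mu[labels])
    counts = rng.negative_binomial(r, p).astype(float)

    lib = counts.sum(axis=1)
    lib[lib == 0] = 1.0
    norm = counts / lib[:, None] * np.median(lib)
    log1p = np.log1p(norm)

    perm = rng.permutation(n_cells)
    sidecar = {
        "proportions": props.tolist(),
        "counts_per_type": counts_per_type.tolist(),
        "marker_strength": marker_strength,
        "markers_per_type": markers_per_type,
        "dispersion": dispersion,
        "seed": seed,
        "marker_blocks": {int(c): [int(c * markers_per_type), int((c + 1) * markers_per_type)] for c in range(n_types)},
    }
    return counts[perm], log1p[perm], labels[perm], sidecar


def expression_to_anndata(counts: np.ndarray, log1p: np.ndarray, labels: np.ndarray, type_names=None):
    """Package an expression fixture as an AnnData for the scanpy ecosystem."""
    import anndata as ad
    import pandas as pd

    names = type_names or [f"type_{c}" for c in np.unique(labels)]
    obs = pd.DataFrame({"cell_type": pd.Categorical([names[c] for c in labels])})
    adata = ad.AnnData(X=log1p.copy(), obs=obs)
    adata.layers["counts"] = counts.copy()
    return adata


def gen_generation_task(
    neurons: int = 12,
    T: int = 200,
    trials: int = 10,
    seed: int = 0,
    latent_dim: int = 2,
    input_rate: float = 0.2,
    gaussian_sd: float = 0.0,
    max_rate: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Fixed Poisson-noise inputs and smooth-latent spike-train templates.

    Templates are Bernoulli realizations of rates driven by ``latent_dim``
    smooth sinusoidal latent trajectories mixed into the population, so a
    low-dimensional neural manifold exists by construction.  Inputs are one
    fixed seeded Poisson noise pattern shared by all trials, optionally
    perturbed per trial by Gaussian noise of sd ``gaussian_sd`` (the
    generation-phase variability).

    Returns ``(inputs, templates, sidecar)`` with shapes
    ``(trials, neurons, T)`` for both.
    """
    if trials < 2:
        raise ContractError("need >= 2 trials")
    rng = np.random.default_rng(seed)
    t = np.arange(T)
    freqs = rng.uniform(0.5, 2.0, latent_dim)
    phases = rng.uniform(0, 2 * np.pi, latent_dim)
    Z = np.stack([np.sin(2 * np.pi * f * t / T + ph) for f, ph in zip(freqs, phases)])  # (d, T)
    A = rng.standard_normal((neurons, latent_dim))
    drive = A @ Z
    rates = max_rate / (1.0 + np.exp(-2.0 * drive))  # (neurons, T), smooth in time
    templates = (rng.random((trials, neurons, T)) < rates[None]).astype(float)

    base_noise = (rng.random((neurons, T)) < input_rate).astype(float)
    inputs = np.broadcast_to(base_noise, (trials, neurons, T)).copy()
    if gaussian_sd > 0:
        inputs = inputs + gaussian_sd * rng.standard_normal(inputs.shape)
    sidecar = {
        "rates": rates,
        "latent": Z,
        "mixing": A,
        "latent_dim": latent_dim,
        "seed": seed,
        "input_rate": input_rate,
        "gaussian_sd": gaussian_sd,
    }
    return inputs, templates, sidecar


def generate(spec: FixtureSpec):
    """Dispatch a FixtureSpec to its generator."""
    kw = {**spec.sizes, **spec.noise, "seed": spec.seed}
    if spec.kind == "neuron-trace":
        n = kw.pop("neurons", 1)
        from .params import NeuronParams as NP

        params = NP(
            tau=kw.pop("tau", 0.3), gamma=kw.pop("gamma", 0.5), C=kw.pop("C", 1.0),
            u_th=kw.pop("u_th", 1.0), u_re=kw.pop("u_re", 0.0),
        )
        return gen_neuron_trace(params, **kw)
    if spec.kind == "temporal-classes":
        return gen_temporal_classes(**kw)
    if spec.kind == "expression-matrix":
        return gen_expression_matrix(**kw)
    if spec.kind == "generation-task":
        return gen_generation_task(**kw)
    raise ContractError(spec.kind)
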