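"""Layered heterogeneous spiking networks: encoding, unrolling, readout.

A network is a stack of dense layers of self-inhibiting neurons, each neuron
owning its own five biophysical parameters (the heterogeneity).  The
forward pass unrolls the per-step recursion over ``T`` time steps; the
default convention propagates a layer's output to the next layer within the
same step (depth-synchronous), which matches few-step (2-5) latencies.  The
literal one-step inter-layer delay is available via ``delayed_interlayer``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .params import (
    ContractError,
    NeuronParams,
    SpikeTrain,
    SurrogateSpec,
    default_params,
    soft_spike,
)
from .neuron import DEFAULT_LEAK_SLOPE, fire, leaky_relu

ENCODINGS = ("direct-current", "poisson-rate", "native-spikes")
READOUTS = ("spike-count", "membrane-accumulate")


@dataclass
class NetworkSpec:
    """Architecture and run conventions of a spiking network."""

    layer_sizes: Sequence[int]
    time_steps: int
    encoding: str = "direct-current"
    readout: str = "membrane-accumulate"
    delayed_interlayer: bool = False
    leak_slope: float = DEFAULT_LEAK_SLOPE

    def __post_init__(self) -> None:
        self.layer_sizes = [int(s) for s in self.layer_sizes]
        if len(self.layer_sizes) < 2:
            raise ContractError("need at least an input and an output layer")
        if self.time_steps < 1:
            raise ContractError("time_steps must be >= 1")
        if self.encoding not in ENCODINGS:
            raise ContractError(f"unknown encoding {self.encoding!r}")
        if self.readout not in READOUTS:
            raise ContractError(f"unknown readout {self.readout!r}")

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)


@dataclass
class NetworkParams:
    """Synaptic weights W (one matrix per layer pair, rows = postsynaptic)
    and per-neuron biophysics for every non-input layer."""

    W: List[np.ndarray]
    alphas: List[NeuronParams]

    def check_shapes(self, spec: NetworkSpec) -> None:
        sizes = spec.layer_sizes
        if len(self.W) != len(sizes) - 1 or len(self.alphas) != len(sizes) - 1:
            raise ContractError("wrong number of weight matrices or alpha groups")
        for l, w in enumerate(self.W):
            if w.shape != (sizes[l + 1], sizes[l]):
                raise ContractError(f"W[{l}] has shape {w.shape}, expected {(sizes[l + 1], sizes[l])}")
            if self.alphas[l].n != sizes[l + 1]:
                raise ContractError(f"alphas[{l}] covers {self.alphas[l].n} neurons, layer has {sizes[l + 1]}")

    def copy(self) -> "NetworkParams":
        return NetworkParams([w.copy() for w in self.W], [a.copy() for a in self.alphas])


def init_network_params(
    spec: NetworkSpec,
    seed: int,
    w_gain: float = 1.0,
    alpha_init: Optional[dict] = None,
    alpha_jitter_sd: float = 0.0,
) -> NetworkParams:
    """Seeded initialization: W ~ N(0, gain^2 / fan_in), homogeneous alpha
    defaults optionally jittered to break symmetry."""
    rng = np.random.default_rng(seed)
    alpha_init = dict(alpha_init or {})
    sizes = spec.layer_sizes
    W = [w_gain * rng.standard_normal((sizes[l + 1], sizes[l])) / np.sqrt(sizes[l]) for l in range(len(sizes) - 1)]
    alphas = [default_params(sizes[l + 1], jitter_sd=alpha_jitter_sd, rng=rng, **alpha_init) for l in range(len(sizes) - 1)]
    params = NetworkParams(W, alphas)
    params.check_shapes(spec)
    return params


def encode_static(x: np.ndarray, T: int, mode: str = "direct-current", seed: int = 0, dt_scale: float = 1.0) -> np.ndarray:
    """Turn a static feature vector/matrix into a ``[..., features, T]`` drive.

    direct-current repeats the (real-valued) features at every step;
    poisson-rate draws seeded Bernoulli(x * dt_scale) spikes per step.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ContractError("features must be finite")
    if mode == "direct-current":
        return np.repeat(x[..., None], T, axis=-1)
    if mode == "poisson-rate":
        p = x * dt_scale
        if np.any(p < 0) or np.any(p > 1):
            raise ContractError("poisson-rate encoding needs rates in [0, 1] after scaling")
        rng = np.random.default_rng(seed)
        return (rng.random(x.shape + (T,)) < p[..., None]).astype(float)
    if mode == "native-spikes":
        raise ContractError("native-spikes inputs are already sequences; do not encode")
    raise ContractError(f"unknown encoding {mode!r}")


@dataclass
class ForwardRecord:
    """Everything a forward pass produced: logits, per-layer activity, and
    spike / synaptic-operation accounting used for energy estimates."""

    logits: np.ndarray
    layer_spikes: List[np.ndarray]  # per non-input layer, (B, n_l, T)
    total_spikes: int
    ac_ops: int          # spike-driven accumulates, summed over batch and time
    mac_ops: int         # dense multiply-accumulates (real-valued first layer), batch total
    batch_size: int
    time_steps: int

    def spike_trains(self, sample: int = 0, dt_label: Optional[float] = None) -> List[SpikeTrain]:
        return [SpikeTrain(s[sample], dt_label=dt_label) for s in self.layer_spikes]


@dataclass
class ForwardCache:
    """Intermediate arrays retained for backpropagation through time."""

    spec: NetworkSpec
    params: NetworkParams
    surrogate: SurrogateSpec
    inputs: np.ndarray                 # (B, n0, T)
    input_is_real: bool
    relaxed: bool
    O: List[np.ndarray] = field(default_factory=list)       # (B, n_l, T)
    u_pre: List[np.ndarray] = field(default_factory=list)
    u_post: List[np.ndarray] = field(default_factory=list)
    a: List[np.ndarray] = field(default_factory=list)       # pre-rectifier activation
    I: List[np.ndarray] = field(default_factory=list)
    logits: Optional[np.ndarray] = None


def forward(
    spec: NetworkSpec,
    params: NetworkParams,
    inputs: np.ndarray,
    surrogate: SurrogateSpec = SurrogateSpec(),
    relaxed: bool = False,
    return_cache: bool = False,
):
    """Unroll the network over time.

    Parameters
    ----------
    inputs
        ``(B, n0, T)`` drive for the input layer — real-valued for
        direct-current encoding, binary for spike inputs.
    relaxed
        Replace the hard spike/reset with the differentiable soft ramp;
        used only to validate gradients.

    Returns
    -------
    ForwardRecord (and the ForwardCache when ``return_cache``).
    """
    params.check_shapes(spec)
    x = np.asarray(inputs, dtype=float)
    if x.ndim == 2:
        x = x[None]
    B, n0, T = x.shape
    if n0 != spec.layer_sizes[0] or T != spec.time_steps:
        raise ContractError(f"input shape {x.shape[1:]} does not match spec {(spec.layer_sizes[0], spec.time_steps)}")
    if not np.all(np.isfinite(x)):
        raise ContractError("non-finite network input")

    input_is_real = spec.encoding == "direct-current"
    nL = len(params.W)
    cache = ForwardCache(spec, params, surrogate, x, input_is_real, relaxed)
    for l in range(nL):
        n = spec.layer_sizes[l + 1]
        for lst in (cache.O, cache.u_pre, cache.u_post, cache.a, cache.I):
            lst.append(np.zeros((B, n, T)))

    u = [np.broadcast_to(params.alphas[l].u_re, (B, spec.layer_sizes[l + 1])).copy() for l in range(nL)]
    o = [np.zeros((B, spec.layer_sizes[l + 1])) for l in range(nL)]
    ac_ops = 0
    mac_ops = 0

    for t in range(T):
        below = x[:, :, t]
        o_new = []
        for l in range(nL):
            al = params.alphas[l]
            if spec.delayed_interlayer and l > 0:
                presyn = cache.O[l - 1][:, :, t - 1] if t > 0 else np.zeros_like(cache.O[l - 1][:, :, 0])
            else:
                presyn = below
            S = presyn @ params.W[l].T
            if l == 0 and input_is_real:
                mac_ops += B * params.W[l].size
            else:
                ac_ops += int(np.sum(presyn)) * params.W[l].shape[0]
            I = S - al.gamma * o[l]
            a = (1.0 - al.tau) * u[l] + al.tau * al.u_re + al.C * I
            u_pre = leaky_relu(a, spec.leak_slope)
            if not np.all(np.isfinite(u_pre)):
                raise FloatingPointError(f"non-finite membrane in layer {l + 1} at step {t}")
            if relaxed:
                O = soft_spike(u_pre - al.u_th, surrogate.width)
            else:
                O = fire(u_pre, al.u_th)
            u_post = (1.0 - O) * u_pre + O * al.u_re
            cache.O[l][:, :, t] = O
            cache.u_pre[l][:, :, t] = u_pre
            cache.u_post[l][:, :, t] = u_post
            cache.a[l][:, :, t] = a
            cache.I[l][:, :, t] = I
            u[l] = u_post
            o_new.append(O)
            if not spec.delayed_interlayer:
                below = O  # same-step stacking: next layer sees this output at t
        o = o_new

    if spec.readout == "membrane-accumulate":
        logits = cache.u_pre[-1].mean(axis=2)
    else:
        logits = cache.O[-1].sum(axis=2)
    cache.logits = logits

    total_spikes = int(sum(np.sum(O if not relaxed else (O > 0.5)) for O in cache.O))
    record = ForwardRecord(
        logits=logits,
        layer_spikes=[O.copy() for O in cache.O],
        total_spikes=total_spikes,
        ac_ops=ac_ops,
        mac_ops=mac_ops,
        batch_size=B,
        time_steps=T,
    )
    if return_cache:
        return record, cache
    return record


# ---------------------------------------------------------------------------
# Losses


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray, class_weight: Optional[np.ndarray] = None):
    """Mean (optionally class-weighted) cross-entropy; returns (loss, dL/dlogits)."""
    logits = np.atleast_2d(logits)
    labels = np.atleast_1d(labels).astype(int)
    B, K = logits.shape
    if labels.min() < 0 or labels.max() >= K:
        raise ContractError("label out of range")
    p = softmax(logits)
    w = np.ones(B) if class_weight is None else np.asarray(class_weight, dtype=float)[labels]
    nll = -np.log(np.clip(p[np.arange(B), labels], 1e-12, None))
    loss = float(np.sum(w * nll) / np.sum(w))
    grad = p.copy()
    grad[np.arange(B), labels] -= 1.0
    grad *= (w / np.sum(w))[:, None]
    return loss, grad


def mse_spike_loss(generated: np.ndarray, template: np.ndarray):
    """Elementwise mean squared error between spike arrays; (loss, dL/dgenerated)."""
    g = np.asarray(generated, dtype=float)
    tpl = np.asarray(template, dtype=float)
    if g.shape != tpl.shape:
        raise ContractError(f"shape mismatch {g.shape} vs {tpl.shape}")
    diff = g - tpl
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


def loss(record: ForwardRecord, target, kind: str = "auto", class_weight: Optional[np.ndarray] = None) -> float:
    """Task loss on a forward record: cross-entropy on logits for class labels,
    MSE between output-layer spikes and a template train otherwise."""
    if kind == "auto":
        kind = "mse" if np.asarray(target).ndim >= 2 else "ce"
    if kind == "ce":
        return cross_entropy(record.logits, target, class_weight)[0]
    if kind == "mse":
        return mse_spike_loss(record.layer_spikes[-1].squeeze(), np.asarray(target).squeeze())[0]
    raise ContractError(f"unknown loss kind {kind!r}")


# ---------------------------------------------------------------------------
# Parameter export


def membrane_time_constant(tau: np.ndarray, dt_label: float = 1.0) -> np.ndarray:
    """Map the per-step decay fraction to a nominal time constant.

    Between spikes the membrane relaxes as (1 - tau)^t, so the continuous
    time constant under a step of ``dt_label`` ms is -dt / ln(1 - tau).
    """
    tau = np.clip(np.asarray(tau, dtype=float), 1e-9, 1 - 1e-12)
    return -dt_label / np.log1p(-tau)


def spike_histograms(params: NetworkParams, dt_label: float = 1.0) -> pd.DataFrame:
    """Histogram-ready table of per-neuron derived biophysics.

    One row per hidden/output neuron with its layer index, membrane time
    constant (nominal ms), resting potential and self-inhibition strength —
    the quantities whose trained distributions are compared with
    experimentally observed neuron populations.
    """
    rows = []
    for l, al in enumerate(params.alphas):
        mtc = membrane_time_constant(al.tau, dt_label)
        for k in range(al.n):
            rows.append(
                {
                    "layer": l + 1,
                    "neuron": k,
                    "tau": al.tau[k],
                    "mtc_ms": mtc[k],
                    "u_re": al.u_re[k],
                    "gamma": al.gamma[k],
                    "u_th": al.u_th[k],
                    "C": al.C[k],
                }
            )
    return pd.DataFrame(rows)
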