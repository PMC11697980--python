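"""Reverse-mode backpropagation through time for spiking networks.

No autodiff framework is used: the backward pass is written directly
against the unrolled recursion.  Two differentiation contracts exist:

* hard mode (training): the forward emitted binary spikes; wherever the
  Heaviside appears in a differentiation path its derivative is replaced by
  the triangle pseudo-derivative evaluated at the pre-reset membrane
  potential, and the hard reset is treated as a non-differentiated gate.
* relaxed mode (verification): the forward used the C1 soft-spike ramp
  everywhere, and the backward computes the *exact* gradient of that graph
  (including the reset-gate term), so it can be checked against central
  finite differences of the relaxed loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .params import PARAM_FIELDS, NeuronParams, SurrogateSpec, triangle_grad
from .network import (
    ForwardCache,
    ForwardRecord,
    NetworkParams,
    NetworkSpec,
    cross_entropy,
    forward,
    mse_spike_loss,
)


@dataclass
class Grads:
    """Gradients of a scalar loss w.r.t. synaptic weights and biophysics."""

    dW: List[np.ndarray]
    dalpha: List[Dict[str, np.ndarray]]

    def scale(self, c: float) -> "Grads":
        return Grads([c * w for w in self.dW], [{k: c * v for k, v in d.items()} for d in self.dalpha])

    def w_norm(self) -> float:
        return float(np.sqrt(sum(np.sum(w**2) for w in self.dW)))

    def alpha_flat(self) -> np.ndarray:
        return np.concatenate([d[f] for d in self.dalpha for f in PARAM_FIELDS])


def zeros_like_grads(params: NetworkParams) -> Grads:
    return Grads(
        [np.zeros_like(w) for w in params.W],
        [{f: np.zeros(a.n) for f in PARAM_FIELDS} for a in params.alphas],
    )


def backward(
    cache: ForwardCache,
    grad_logits: Optional[np.ndarray] = None,
    grad_out_spikes: Optional[np.ndarray] = None,
) -> Grads:
    """Backpropagate upstream gradients through a cached forward pass.

    ``grad_logits`` is dL/dlogits for the spec's readout; ``grad_out_spikes``
    is dL/dO of the output layer per time step (generation tasks).  Both may
    be supplied and are accumulated.
    """
    spec, params, x = cache.spec, cache.params, cache.inputs
    width = cache.surrogate.width
    slope = spec.leak_slope
    gate = cache.relaxed  # differentiate the reset gate only in the exact relaxed graph
    B, _, T = x.shape
    nL = len(params.W)

    grads = zeros_like_grads(params)
    gu = [np.zeros((B, params.alphas[l].n)) for l in range(nL)]       # dL/du_post(t)
    go_rec = [np.zeros((B, params.alphas[l].n)) for l in range(nL)]   # dL/dO(t) via gamma at t+1
    go_delay = [np.zeros((B, params.alphas[l].n)) for l in range(nL)] # delayed inter-layer path

    for t in range(T - 1, -1, -1):
        go_above = [np.zeros((B, params.alphas[l].n)) for l in range(nL)]
        # delayed inter-layer gradients produced at step t belong to step t-1
        go_delay_pending = [np.zeros((B, params.alphas[l].n)) for l in range(nL)]
        for l in range(nL - 1, -1, -1):
            al = params.alphas[l]
            O = cache.O[l][:, :, t]
            u_pre = cache.u_pre[l][:, :, t]
            a = cache.a[l][:, :, t]
            I = cache.I[l][:, :, t]
            u_prev = cache.u_post[l][:, :, t - 1] if t > 0 else np.broadcast_to(al.u_re, O.shape)
            o_prev = cache.O[l][:, :, t - 1] if t > 0 else np.zeros_like(O)

            gO = go_rec[l] + go_above[l] + go_delay[l]
            if l == nL - 1:
                if spec.readout == "spike-count" and grad_logits is not None:
                    gO = gO + grad_logits
                if grad_out_spikes is not None:
                    gO = gO + grad_out_spikes[:, :, t]
            gu_post = gu[l]

            g = triangle_grad(u_pre - al.u_th, width)
            du_pre = gu_post * (1.0 - O) + gO * g
            du_th = -gO * g
            if gate:
                gate_term = gu_post * (al.u_re - u_pre) * g
                du_pre = du_pre + gate_term
                du_th = du_th - gate_term
            du_re_local = gu_post * O  # reset target
            if l == nL - 1 and spec.readout == "membrane-accumulate" and grad_logits is not None:
                du_pre = du_pre + grad_logits / T

            da = du_pre * np.where(a >= 0, 1.0, slope)
            dI = da * al.C
            gu_prev = da * (1.0 - al.tau)
            if t == 0:
                du_re_local = du_re_local + gu_prev  # u(0) = u_re initialization
            else:
                gu[l] = gu_prev
            go_rec[l] = -dI * al.gamma if t > 0 else np.zeros_like(dI)

            grads.dalpha[l]["tau"] += np.sum(da * (al.u_re - u_prev), axis=0)
            grads.dalpha[l]["u_re"] += np.sum(da * al.tau + du_re_local, axis=0)
            grads.dalpha[l]["C"] += np.sum(da * I, axis=0)
            grads.dalpha[l]["gamma"] += np.sum(-dI * o_prev, axis=0)
            grads.dalpha[l]["u_th"] += np.sum(du_th, axis=0)

            dS = dI
            if spec.delayed_interlayer and l > 0:
                presyn = cache.O[l - 1][:, :, t - 1] if t > 0 else np.zeros((B, params.W[l].shape[1]))
            else:
                presyn = x[:, :, t] if l == 0 else cache.O[l - 1][:, :, t]
            grads.dW[l] += dS.T @ presyn
            if l > 0:
                d_presyn = dS @ params.W[l]
                if spec.delayed_interlayer:
                    if t > 0:
                        go_delay_pending[l - 1] += d_presyn
                else:
                    go_above[l - 1] = go_above[l - 1] + d_presyn
        go_delay = go_delay_pending
    return grads


def loss_and_grads(
    spec: NetworkSpec,
    params: NetworkParams,
    inputs: np.ndarray,
    target,
    kind: str = "ce",
    surrogate: SurrogateSpec = SurrogateSpec(),
    class_weight: Optional[np.ndarray] = None,
    relaxed: bool = False,
):
    """Forward + backward in one call.

    Returns ``(loss, record, grads)``.  ``kind`` is "ce" (labels against the
    readout logits) or "mse" (template spike array against the output layer).
    """
    record, cache = forward(spec, params, inputs, surrogate, relaxed=relaxed, return_cache=True)
    if kind == "ce":
        value, dlogits = cross_entropy(record.logits, target, class_weight)
        grads = backward(cache, grad_logits=dlogits)
    elif kind == "mse":
        tpl = np.asarray(target, dtype=float)
        out = cache.O[-1]
        if tpl.shape != out.shape:
            tpl = np.broadcast_to(tpl, out.shape)
        value, dout = mse_spike_loss(out, tpl)
        grads = backward(cache, grad_out_spikes=dout)
    else:
        raise ValueError(f"unknown loss kind {kind!r}")
    return value, record, grads


# ---------------------------------------------------------------------------
# Single-neuron BPTT (used by the trace-fitting loop)


def neuron_bptt(
    current: np.ndarray,
    params: NeuronParams,
    dL_dO: np.ndarray,
    surrogate: SurrogateSpec = SurrogateSpec(),
    slope: float = 0.01,
) -> Dict[str, np.ndarray]:
    """Gradients of a spike-train loss w.r.t. each neuron's own parameters.

    ``current`` and ``dL_dO`` are ``(n, T)``; neurons are independent (one
    candidate parameter set per row), so this also serves to fit many random
    restarts in a single vectorized pass.  Hard-mode contract: surrogate
    derivative at the pre-reset membrane, reset gate detached.
    """
    cur = np.asarray(current, dtype=float)
    n, T = cur.shape
    # replay the forward, caching what the backward needs
    u = np.broadcast_to(params.u_re, (n,)).astype(float).copy()
    o = np.zeros(n)
    a_c = np.empty((n, T))
    I_c = np.empty((n, T))
    upre_c = np.empty((n, T))
    upost_c = np.empty((n, T))
    O_c = np.empty((n, T))
    for t in range(T):
        I = cur[:, t] - params.gamma * o
        a = (1.0 - params.tau) * u + params.tau * params.u_re + params.C * I
        u_pre = np.where(a >= 0, a, slope * a)
        O = (u_pre - params.u_th > 0).astype(float)
        u = (1.0 - O) * u_pre + O * params.u_re
        o = O
        a_c[:, t], I_c[:, t], upre_c[:, t], upost_c[:, t], O_c[:, t] = a, I, u_pre, u, O

    g_out = {f: np.zeros(n) for f in PARAM_FIELDS}
    gu = np.zeros(n)
    go_rec = np.zeros(n)
    for t in range(T - 1, -1, -1):
        O = O_c[:, t]
        u_prev = upost_c[:, t - 1] if t > 0 else np.broadcast_to(params.u_re, (n,))
        o_prev = O_c[:, t - 1] if t > 0 else np.zeros(n)
        gO = dL_dO[:, t] + go_rec
        g = triangle_grad(upre_c[:, t] - params.u_th, surrogate.width)
        du_pre = gu * (1.0 - O) + gO * g
        du_re_local = gu * O
        da = du_pre * np.where(a_c[:, t] >= 0, 1.0, slope)
        dI = da * params.C
        gu_prev = da * (1.0 - params.tau)
        if t == 0:
            du_re_local = du_re_local + gu_prev
            gu = np.zeros(n)
        else:
            gu = gu_prev
        go_rec = -dI * params.gamma if t > 0 else np.zeros(n)
        g_out["tau"] += da * (params.u_re - u_prev)
        g_out["u_re"] += da * params.tau + du_re_local
        g_out["C"] += da * I_c[:, t]
        g_out["gamma"] += -dI * o_prev
        g_out["u_th"] += -gO * g
    return g_out
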