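"""Single-step dynamics of the self-inhibiting neuron and a trace simulator.

The per-step recursion, applied elementwise over a population:

    S(t)  = sum_i w_i O_i(t-1)                 (weighted input)
    I(t)  = S(t) - gamma * O(t-1)              (autaptic self-inhibition)
    u(t)  = f[(1 - tau) u(t-1) + tau u_re + C I(t)]   (leaky membrane, f = LeakyReLU)
    O(t)  = Theta(u(t) - u_th)                 (strict: spike iff u > u_th)
    u(t) <- (1 - O(t)) u(t) + O(t) u_re        (hard reset)

The subtraction of ``gamma * O(t-1)`` is the self-inhibiting autapse: a
spike at t-1 suppresses the neuron's own input at t, giving each neuron a
one-step memory of its recent activity.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .params import (
    ContractError,
    NeuronParams,
    NeuronState,
    SpikeTrain,
    SurrogateSpec,
    soft_spike,
)

DEFAULT_LEAK_SLOPE = 0.01


def weighted_input(w_row: np.ndarray, presyn_spikes: np.ndarray) -> float:
    """External stimulus S = sum_i w_i O_i of one neuron from its presynaptic layer."""
    w = np.asarray(w_row, dtype=float)
    o = np.asarray(presyn_spikes, dtype=float)
    if w.shape != o.shape:
        raise ContractError(f"weight/spike shape mismatch: {w.shape} vs {o.shape}")
    return float(w @ o)


def self_inhibit(S, gamma, o_prev):
    """Effective input I = S - gamma * o_prev; identity when the neuron was silent."""
    return np.asarray(S, dtype=float) - np.asarray(gamma, dtype=float) * np.asarray(o_prev, dtype=float)


def leaky_relu(x: np.ndarray, slope: float = DEFAULT_LEAK_SLOPE) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, x, slope * x)


def membrane_update(u_prev, params: NeuronParams, I, slope: float = DEFAULT_LEAK_SLOPE):
    """u = f[(1 - tau) u_prev + tau u_re + C I] with f a leaky rectifier."""
    if not (0 < slope < 1):
        raise ContractError("leak slope must lie in (0, 1)")
    a = (1.0 - params.tau) * np.asarray(u_prev, dtype=float) + params.tau * params.u_re + params.C * np.asarray(I, dtype=float)
    u = leaky_relu(a, slope)
    if not np.all(np.isfinite(u)):
        bad = np.flatnonzero(~np.isfinite(np.atleast_1d(u)))
        raise FloatingPointError(f"non-finite membrane potential at neuron index {bad[:5]}")
    return u


def fire(u, u_th) -> np.ndarray:
    """Heaviside spike: O = 1 iff u - u_th > 0 (strictly; equality does not fire)."""
    return (np.asarray(u, dtype=float) - np.asarray(u_th, dtype=float) > 0).astype(float)


def reset(u, O, u_re):
    """Hard reset: u' = (1 - O) u + O u_re."""
    O = np.asarray(O, dtype=float)
    return (1.0 - O) * np.asarray(u, dtype=float) + O * np.asarray(u_re, dtype=float)


def neuron_step(
    state: NeuronState,
    S: np.ndarray,
    params: NeuronParams,
    surrogate: SurrogateSpec = SurrogateSpec(),
    slope: float = DEFAULT_LEAK_SLOPE,
    relaxed: bool = False,
) -> Tuple[NeuronState, np.ndarray]:
    """One synchronous update of a population given its stimuli ``S``.

    Forward output is exactly binary (``relaxed=False``).  With
    ``relaxed=True`` the Heaviside is replaced by the C1 ramp whose
    derivative is the triangle pseudo-derivative, making the whole step
    differentiable; this mode exists to verify surrogate gradients against
    finite differences and is never used for spiking inference.
    """
    S = np.asarray(S, dtype=float)
    if S.shape != state.u.shape:
        raise ContractError(f"stimulus shape {S.shape} does not match state {state.u.shape}")
    I = self_inhibit(S, params.gamma, state.o_prev)
    u_pre = membrane_update(state.u, params, I, slope)
    if relaxed:
        O = soft_spike(u_pre - params.u_th, surrogate.width)
    else:
        O = fire(u_pre, params.u_th)
    u_post = reset(u_pre, O, params.u_re)
    return NeuronState(u_post, O), O


def simulate_neuron(
    current: np.ndarray,
    params: NeuronParams,
    surrogate: SurrogateSpec = SurrogateSpec(),
    slope: float = DEFAULT_LEAK_SLOPE,
    dt_label: Optional[float] = None,
    record_membrane: bool = False,
):
    """Drive a population with an injected current trace; S(t) = current(t).

    Parameters
    ----------
    current
        Shape ``(T,)`` (shared by all neurons) or ``(n, T)`` per-neuron
        traces.  This plays the role of the weighted input of a network
        layer, so a standalone neuron under current injection is exactly
        one network neuron with a frozen identity synapse.

    Returns
    -------
    SpikeTrain, or ``(SpikeTrain, membrane)`` with the post-reset membrane
    history when ``record_membrane`` is set.
    """
    cur = np.asarray(current, dtype=float)
    if cur.size == 0:
        raise ContractError("empty current trace")
    if not np.all(np.isfinite(cur)):
        raise ContractError("current trace contains non-finite values")
    if cur.ndim == 1:
        cur = np.broadcast_to(cur, (params.n, cur.shape[0]))
    if cur.shape[0] != params.n:
        raise ContractError(f"current has {cur.shape[0]} rows for {params.n} neurons")
    T = cur.shape[1]
    state = NeuronState.resting(params)
    spikes = np.empty((params.n, T))
    u_hist = np.empty((params.n, T)) if record_membrane else None
    for t in range(T):
        state, O = neuron_step(state, cur[:, t], params, surrogate, slope)
        spikes[:, t] = O
        if record_membrane:
            u_hist[:, t] = state.u
    train = SpikeTrain(spikes, dt_label=dt_label)
    if record_membrane:
        return train, u_hist
    return train
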