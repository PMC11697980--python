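"""Bi-level heterogeneous learning.

The outer (neuron-level) objective over the biophysics ``alpha`` is the
validation loss plus a Laplacian smoother,

    min_alpha  L_v(D_v; W*(alpha), alpha) + lam * Omega(alpha)
    s.t.       W*(alpha) = argmin_W  L_t(D_t; W, alpha),

solved by alternating a network-level SGD loop on the synaptic weights W
with neuron-level hypergradient steps on alpha.  The hypergradient either
ignores the inner dependence (first order: grad_alpha L_u at the current W,
obtained by setting the inner learning rate to zero) or approximates it by
one inner step plus a central finite difference of the mixed second
derivative (second order).  Sub-training and sub-validation sets are
disjoint ("orthogonal") splits of the training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from sklearn.model_selection import train_test_split

from .params import PARAM_FIELDS, ContractError, NeuronParams, SpikeTrain, SurrogateSpec
from .network import NetworkParams, NetworkSpec, init_network_params, cross_entropy, forward
from ._grad import Grads, loss_and_grads, neuron_bptt
from .neuron import simulate_neuron


@dataclass
class BilevelConfig:
    """Hyperparameters of the two alternating loops.

    ``alternation`` is the number of network-level (W) batch steps taken per
    neuron-level (alpha) step; ``alpha_every_epoch=True`` overrides it with
    one alpha step at the end of each epoch.
    """

    xi1: float = 0.1          # network-level learning rate
    xi2: float = 0.05         # neuron-level learning rate
    lam: float = 0.01         # Laplacian penalty weight
    eps0: float = 0.01        # finite-difference scalar (scaled by 1/||grad||)
    order: str = "first"
    split_fraction: float = 0.8
    alternation: int = 1
    alpha_every_epoch: bool = True
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    class_weight: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.xi1 < 0 or self.xi2 < 0:
            raise ContractError("learning rates must be >= 0")
        if self.lam < 0 or self.eps0 <= 0:
            raise ContractError("need lam >= 0 and eps0 > 0")
        if not (0 < self.split_fraction < 1):
            raise ContractError("split_fraction must lie in (0, 1)")
        if self.order not in ("first", "second"):
            raise ContractError("order must be 'first' or 'second'")


# ---------------------------------------------------------------------------
# Orthogonal splits


def split_orthogonal(
    n_or_labels, split_fraction: float, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, seeded index split; stratified when labels exist.

    Pass an integer sample count for an unlabeled split, or the label vector
    for a stratified one.  A class with fewer than 2 samples triggers a
    warning and a non-stratified fallback.
    """
    if np.isscalar(n_or_labels):
        n, labels = int(n_or_labels), None
    else:
        labels = np.asarray(n_or_labels)
        n = labels.shape[0]
    if n < 2:
        raise ContractError("dataset must contain at least 2 samples")
    stratify = labels
    if labels is not None:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < 2:
            warnings.warn("a class has < 2 samples; falling back to a non-stratified split")
            stratify = None
    idx_t, idx_v = train_test_split(
        np.arange(n), train_size=split_fraction, random_state=seed, shuffle=True, stratify=stratify
    )
    return np.sort(idx_t), np.sort(idx_v)


# ---------------------------------------------------------------------------
# Laplacian smoother over a neuron neighbourhood graph


@dataclass
class NeighborGraph:
    """Undirected weighted graph over the neurons of one layer."""

    edges: np.ndarray            # (m, 2) int
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.edges = np.atleast_2d(np.asarray(self.edges, dtype=int))
        if self.edges.size == 0:
            self.edges = np.zeros((0, 2), dtype=int)
        if self.weights is None:
            self.weights = np.ones(self.edges.shape[0])
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ContractError("edge weights must be nonnegative")
        if self.edges.shape[0] and np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ContractError("self-loops are not allowed")

    @classmethod
    def chain(cls, n: int) -> "NeighborGraph":
        """Unit-weight chain over the neuron index — the default surrogate
        for spatial adjacency, which a dense layer does not have."""
        if n < 2:
            return cls(np.zeros((0, 2), dtype=int))
        return cls(np.column_stack([np.arange(n - 1), np.arange(1, n)]))

    @classmethod
    def complete(cls, n: int) -> "NeighborGraph":
        i, j = np.triu_indices(n, k=1)
        return cls(np.column_stack([i, j]))


DEFAULT_FIELD_SCALES = {f: 1.0 for f in PARAM_FIELDS}


def laplacian_penalty(
    alphas: NeuronParams, graph: NeighborGraph, field_scales: Optional[Dict[str, float]] = None
) -> float:
    """Omega = sum_over_edges w_ij * || alpha_i - alpha_j ||^2 in scaled units.

    Each parameter field is divided by a fixed unit scale (default 1) before
    the squared difference, so fields of different magnitude can be balanced
    without data-dependent renormalization.
    """
    scales = field_scales or DEFAULT_FIELD_SCALES
    if graph.edges.shape[0] == 0:
        return 0.0
    if graph.edges.max() >= alphas.n:
        raise ContractError("graph references a neuron outside the layer")
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    total = 0.0
    for f in PARAM_FIELDS:
        v = getattr(alphas, f) / scales[f]
        total += float(np.sum(graph.weights * (v[i] - v[j]) ** 2))
    return total


def laplacian_penalty_grad(
    alphas: NeuronParams, graph: NeighborGraph, field_scales: Optional[Dict[str, float]] = None
) -> Dict[str, np.ndarray]:
    scales = field_scales or DEFAULT_FIELD_SCALES
    out = {f: np.zeros(alphas.n) for f in PARAM_FIELDS}
    if graph.edges.shape[0] == 0:
        return out
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    for f in PARAM_FIELDS:
        s = scales[f]
        v = getattr(alphas, f) / s
        d = 2.0 * graph.weights * (v[i] - v[j]) / s
        np.add.at(out[f], i, d)
        np.add.at(out[f], j, -d)
    return out


def network_omega(alphas: List[NeuronParams], graphs: List[NeighborGraph]) -> float:
    return sum(laplacian_penalty(a, g) for a, g in zip(alphas, graphs))


def neuron_objective(
    v_loss: float, alphas: List[NeuronParams], lam: float, graphs: List[NeighborGraph]
) -> float:
    """Upper-level objective L_u = L_v + lam * Omega(alpha)."""
    return v_loss + lam * network_omega(alphas, graphs)


# ---------------------------------------------------------------------------
# Hypergradients (generic over a bi-level problem adapter)


class BilevelProblem:
    """Adapter protocol: a bi-level instance with alpha held fixed.

    ``W`` is an opaque list of arrays.  Implementations provide the three
    gradient oracles the hypergradient formulas need.
    """

    def grad_W_t(self, W: List[np.ndarray]) -> Tuple[float, List[np.ndarray]]:
        raise NotImplementedError

    def grad_alpha_t(self, W: List[np.ndarray]) -> np.ndarray:
        raise NotImplementedError

    def grads_u(self, W: List[np.ndarray]) -> Tuple[float, np.ndarray, List[np.ndarray]]:
        """Return (L_u, grad_alpha L_u, grad_W L_u) at (W, alpha)."""
        raise NotImplementedError


def _w_axpy(W: List[np.ndarray], c: float, G: List[np.ndarray]) -> List[np.ndarray]:
    return [w + c * g for w, g in zip(W, G)]


def _w_norm(G: List[np.ndarray]) -> float:
    return float(np.sqrt(sum(np.sum(g**2) for g in G)))


def alpha_grad(
    problem: BilevelProblem,
    W: List[np.ndarray],
    xi1: float,
    eps0: float = 0.01,
    order: str = "first",
    log: Optional[list] = None,
) -> np.ndarray:
    """Hypergradient of the upper objective w.r.t. the biophysics.

    first order:  grad_alpha L_u(W, alpha)  (the inner step is dropped by
    taking xi1 = 0 in the chain rule).

    second order: with W' = W - xi1 * grad_W L_t, the chain-rule term
    involving the mixed second derivative of L_t is approximated by the
    central finite difference

        grad_alpha L_u(W', alpha)
          - xi1 * [grad_alpha L_t(W+) - grad_alpha L_t(W-)] / (2 eps),

    W-+ = W -+ eps * grad_W L_u(W', alpha), with eps = eps0 / ||grad_W L_u||.
    A vanishing ||grad_W L_u|| skips the second term (logged).
    """
    if order == "first":
        _, g_alpha, _ = problem.grads_u(W)
        return g_alpha
    _, gW_t = problem.grad_W_t(W)
    W1 = _w_axpy(W, -xi1, gW_t)
    _, g_alpha_u, gW_u = problem.grads_u(W1)
    norm = _w_norm(gW_u)
    if xi1 == 0.0 or norm == 0.0:
        if norm == 0.0 and log is not None:
            log.append("zero upper-gradient norm: finite-difference term skipped")
        return g_alpha_u
    eps = eps0 / norm
    g_plus = problem.grad_alpha_t(_w_axpy(W, eps, gW_u))
    g_minus = problem.grad_alpha_t(_w_axpy(W, -eps, gW_u))
    return g_alpha_u - xi1 * (g_plus - g_minus) / (2.0 * eps)


class SNNBilevelProblem(BilevelProblem):
    """Bi-level adapter around an unrolled spiking network.

    alpha (all layers' biophysics) is fixed at construction; the oracles
    evaluate L_t on the sub-training batch and L_u = L_v + lam * Omega on
    the sub-validation batch, with gradients from the surrogate BPTT.
    """

    def __init__(
        self,
        spec: NetworkSpec,
        alphas: List[NeuronParams],
        train_batch: Tuple[np.ndarray, np.ndarray],
        val_batch: Tuple[np.ndarray, np.ndarray],
        lam: float = 0.0,
        graphs: Optional[List[NeighborGraph]] = None,
        surrogate: SurrogateSpec = SurrogateSpec(),
        loss_kind: str = "ce",
        class_weight: Optional[np.ndarray] = None,
    ):
        self.spec, self.alphas = spec, alphas
        self.train_batch, self.val_batch = train_batch, val_batch
        self.lam = lam
        self.graphs = graphs if graphs is not None else [NeighborGraph.chain(a.n) for a in alphas]
        self.surrogate, self.loss_kind, self.class_weight = surrogate, loss_kind, class_weight

    def _loss_grads(self, W, batch):
        params = NetworkParams(list(W), self.alphas)
        x, y = batch
        return loss_and_grads(
            self.spec, params, x, y, self.loss_kind, self.surrogate, self.class_weight
        )

    def grad_W_t(self, W):
        value, _, grads = self._loss_grads(W, self.train_batch)
        return value, grads.dW

    def grad_alpha_t(self, W):
        _, _, grads = self._loss_grads(W, self.train_batch)
        return grads.alpha_flat()

    def grads_u(self, W):
        v_loss, _, grads = self._loss_grads(W, self.val_batch)
        g_alpha = grads.alpha_flat()
        if self.lam > 0:
            pen = 0.0
            pieces = []
            for a, g in zip(self.alphas, self.graphs):
                pen += laplacian_penalty(a, g)
                pg = laplacian_penalty_grad(a, g)
                pieces.append(np.concatenate([pg[f] for f in PARAM_FIELDS]))
            g_alpha = g_alpha + self.lam * np.concatenate(pieces)
            v_loss = v_loss + self.lam * pen
        return v_loss, g_alpha, grads.dW


def _unflatten_alpha(flat: np.ndarray, alphas: List[NeuronParams]) -> List[Dict[str, np.ndarray]]:
    out, pos = [], 0
    for a in alphas:
        d = {}
        for f in PARAM_FIELDS:
            d[f] = flat[pos : pos + a.n]
            pos += a.n
        out.append(d)
    return out


def _project_alpha(alphas: List[NeuronParams]) -> None:
    """Feasibility projection after an alpha step: tau in [0,1], gamma >= 0."""
    for a in alphas:
        np.clip(a.tau, 0.0, 1.0, out=a.tau)
        np.maximum(a.gamma, 0.0, out=a.gamma)


def network_step(
    spec: NetworkSpec,
    params: NetworkParams,
    batch: Tuple[np.ndarray, np.ndarray],
    xi1: float,
    surrogate: SurrogateSpec = SurrogateSpec(),
    loss_kind: str = "ce",
    class_weight: Optional[np.ndarray] = None,
) -> float:
    """One SGD step on the synaptic weights, W <- W - xi1 * grad_W L_t.

    Only W changes; the biophysics are treated as constants.  Returns the
    pre-step batch loss.  Non-finite gradients abort with diagnostics.
    """
    x, y = batch
    value, _, grads = loss_and_grads(spec, params, x, y, loss_kind, surrogate, class_weight)
    for w, g in zip(params.W, grads.dW):
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite weight gradient; aborting step")
        w -= xi1 * g
    return value


@dataclass
class TrainResult:
    params: NetworkParams
    history: pd.DataFrame
    events: List[str]
    config: BilevelConfig


def _accuracy(spec, params, x, y, surrogate):
    logits = forward(spec, params, x, surrogate).logits
    return float(np.mean(np.argmax(logits, axis=1) == y))


def hifi_train(
    spec: NetworkSpec,
    data: Tuple[np.ndarray, np.ndarray],
    config: BilevelConfig,
    surrogate: SurrogateSpec = SurrogateSpec(),
    alpha_init: Optional[dict] = None,
    alpha_jitter_sd: float = 0.02,
    w_gain: float = 1.0,
    graphs: Optional[List[NeighborGraph]] = None,
    loss_kind: str = "ce",
) -> TrainResult:
    """Alternating bi-level training of a heterogeneous spiking network.

    ``data`` is ``(inputs, labels)`` with inputs already encoded as
    ``(n, n0, T)`` sequences.  With ``xi2 = 0`` the biophysics are frozen at
    initialization and the run degenerates to homogeneous training (only
    the synaptic weights are learned).

    History records, per epoch, the sub-training loss, sub-validation loss,
    validation accuracy, the penalty Omega, and per-field alpha spreads.
    """
    x, y = data
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    ss = np.random.SeedSequence(config.seed)
    seed_split, seed_init, seed_batch = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

    idx_t, idx_v = split_orthogonal(y if loss_kind == "ce" else x.shape[0], config.split_fraction, seed_split)
    x_t, x_v = x[idx_t], x[idx_v]
    y_t, y_v = y[idx_t], y[idx_v]

    params = init_network_params(spec, seed_init, w_gain=w_gain, alpha_init=alpha_init, alpha_jitter_sd=alpha_jitter_sd)
    if graphs is None:
        graphs = [NeighborGraph.chain(a.n) for a in params.alphas]
    rng = np.random.default_rng(seed_batch)

    rows: List[dict] = []
    events: List[str] = []
    best = params.copy()
    n_t = x_t.shape[0]
    steps_since_alpha = 0

    for epoch in range(config.epochs):
        order_idx = rng.permutation(n_t)
        batch_losses = []
        for start in range(0, n_t, config.batch_size):
            b = order_idx[start : start + config.batch_size]
            lt = network_step(spec, params, (x_t[b], y_t[b]), config.xi1, surrogate, loss_kind, config.class_weight)
            if not np.isfinite(lt):
                events.append(f"divergence at epoch {epoch}; reverting to last good checkpoint")
                return TrainResult(best, pd.DataFrame(rows), events, config)
            batch_losses.append(lt)
            steps_since_alpha += 1
            if config.xi2 > 0 and not config.alpha_every_epoch and steps_since_alpha >= config.alternation:
                _alpha_update(spec, params, (x_t[b], y_t[b]), (x_v, y_v), config, graphs, surrogate, loss_kind, events)
                steps_since_alpha = 0
        if config.xi2 > 0 and config.alpha_every_epoch:
            b = order_idx[: config.batch_size]
            _alpha_update(spec, params, (x_t[b], y_t[b]), (x_v, y_v), config, graphs, surrogate, loss_kind, events)

        v_loss, _, _ = loss_and_grads(spec, params, x_v, y_v, loss_kind, surrogate, config.class_weight)
        t_loss, _, _ = loss_and_grads(spec, params, x_t, y_t, loss_kind, surrogate, config.class_weight)
        omega = network_omega(params.alphas, graphs)
        row = {
            "epoch": epoch,
            "L_t": float(t_loss),          # epoch-end loss on the full sub-training set
            "L_t_running": float(np.mean(batch_losses)),
            "L_v": float(v_loss),
            "omega": omega,
            "L_u": float(v_loss) + config.lam * omega,
        }
        if loss_kind == "ce":
            row["val_acc"] = _accuracy(spec, params, x_v, y_v, surrogate)
        for f in PARAM_FIELDS:
            vals = np.concatenate([getattr(a, f) for a in params.alphas])
            row[f"{f}_mean"] = float(vals.mean())
            row[f"{f}_std"] = float(vals.std())
        rows.append(row)
        best = params.copy()

    return TrainResult(params, pd.DataFrame(rows), events, config)


def _alpha_update(spec, params, train_batch, val_batch, config, graphs, surrogate, loss_kind, events):
    problem = SNNBilevelProblem(
        spec, params.alphas, train_batch, val_batch,
        lam=config.lam, graphs=graphs, surrogate=surrogate,
        loss_kind=loss_kind, class_weight=config.class_weight,
    )
    g = alpha_grad(problem, params.W, config.xi1, config.eps0, config.order, log=events)
    for a, d in zip(params.alphas, _unflatten_alpha(g, params.alphas)):
        for f in PARAM_FIELDS:
            getattr(a, f)[:] -= config.xi2 * d[f]
    _project_alpha(params.alphas)


# ---------------------------------------------------------------------------
# Single-neuron fitting to recorded traces


def van_rossum_loss(spikes: np.ndarray, target: np.ndarray, kernel_tau: float):
    """Squared van-Rossum-style distance between spike trains.

    Both trains are convolved with a causal exponential kernel of time
    constant ``kernel_tau`` (steps) and compared in L2; returns the mean
    squared filtered difference and its gradient w.r.t. ``spikes``.
    """
    a = float(np.exp(-1.0 / kernel_tau))
    diff = np.atleast_2d(np.asarray(spikes, dtype=float) - np.asarray(target, dtype=float))
    filt = lfilter([1.0], [1.0, -a], diff, axis=1)
    n_el = diff.shape[1]
    value = np.mean(filt**2, axis=1)
    # adjoint of the causal filter = anticausal filter of the upstream grad
    up = 2.0 * filt / n_el
    grad = lfilter([1.0], [1.0, -a], up[:, ::-1], axis=1)[:, ::-1]
    return value, grad


@dataclass
class FitConfig:
    n_restarts: int = 5
    steps: int = 300
    lr: float = 0.02
    kernel_tau: float = 5.0
    rel_perturb: float = 0.5
    free_fields: Sequence[str] = PARAM_FIELDS
    seed: int = 0
    leak_slope: float = 0.01
    surrogate: SurrogateSpec = field(default_factory=SurrogateSpec)


@dataclass
class FitResult:
    params: NeuronParams          # best restart
    loss: float
    restart_losses: np.ndarray
    all_params: NeuronParams      # population over restarts
    silent: bool                  # best fit emits no spikes on the training trace
    history: np.ndarray           # (steps,) best-restart loss trajectory


def _perturbed_population(init: NeuronParams, n: int, rel: float, rng) -> NeuronParams:
    vecs = {}
    for f in PARAM_FIELDS:
        base = np.repeat(getattr(init, f), n)
        vecs[f] = base * (1.0 + rel * rng.uniform(-1.0, 1.0, n))
    vecs["tau"] = np.clip(vecs["tau"], 0.01, 0.99)
    vecs["gamma"] = np.maximum(vecs["gamma"], 0.0)
    return NeuronParams(**vecs)


def fit_single_neuron(
    currents: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],
    init: NeuronParams,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Fit the five biophysical parameters of one neuron to recorded trials.

    Each trial pairs an injected-current trace with the observed spike
    train.  The loss is the exponential-kernel-smoothed (van Rossum) spike
    distance, minimized with Adam; gradients flow through the hard spiking
    recursion via the triangle pseudo-derivative.  ``n_restarts`` perturbed
    initializations run as one vectorized population; the best final loss
    wins.  The first restart starts exactly at ``init`` (fixed-point check:
    initializing at the generating truth leaves parameters in place).
    """
    currents = [np.asarray(c, dtype=float).ravel() for c in currents]
    targets = [np.asarray(t, dtype=float).reshape(-1) for t in targets]
    if len(currents) != len(targets) or len(currents) == 0:
        raise ContractError("need >= 1 matched (current, spikes) trial")
    rng = np.random.default_rng(config.seed)
    n = config.n_restarts
    pop = _perturbed_population(init, n, config.rel_perturb, rng)
    for f in PARAM_FIELDS:  # restart 0 is the unperturbed init
        getattr(pop, f)[0] = getattr(init, f)[0]

    free = [f for f in PARAM_FIELDS if f in config.free_fields]
    m = {f: np.zeros(n) for f in free}
    v = {f: np.zeros(n) for f in free}
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    history = np.zeros(config.steps)
    losses = np.zeros(n)

    for step in range(config.steps):
        losses[:] = 0.0
        g_tot = {f: np.zeros(n) for f in free}
        for cur, tgt in zip(currents, targets):
            T = cur.shape[0]
            cur_pop = np.broadcast_to(cur, (n, T))
            spikes = simulate_neuron(cur_pop, pop, config.surrogate, config.leak_slope).spikes.astype(float)
            val, dO = van_rossum_loss(spikes, np.broadcast_to(tgt, (n, T)), config.kernel_tau)
            losses += val
            g = neuron_bptt(cur_pop, pop, dO, config.surrogate, config.leak_slope)
            for f in free:
                g_tot[f] += g[f]
        for f in free:
            m[f] = b1 * m[f] + (1 - b1) * g_tot[f]
            v[f] = b2 * v[f] + (1 - b2) * g_tot[f] ** 2
            mh = m[f] / (1 - b1 ** (step + 1))
            vh = v[f] / (1 - b2 ** (step + 1))
            getattr(pop, f)[:] -= config.lr * mh / (np.sqrt(vh) + adam_eps)
        np.clip(pop.tau, 0.01, 0.99, out=pop.tau)
        np.maximum(pop.gamma, 0.0, out=pop.gamma)
        history[step] = losses.min()

    # final evaluation at the converged parameters
    losses[:] = 0.0
    for cur, tgt in zip(currents, targets):
        T = cur.shape[0]
        spikes = simulate_neuron(np.broadcast_to(cur, (n, T)), pop, config.surrogate, config.leak_slope).spikes.astype(float)
        val, _ = van_rossum_loss(spikes, np.broadcast_to(tgt, (n, T)), config.kernel_tau)
        losses += val
    k = int(np.argmin(losses))
    best = NeuronParams(**{f: getattr(pop, f)[k : k + 1].copy() for f in PARAM_FIELDS})
    spikes_best = simulate_neuron(currents[0], best, config.surrogate, config.leak_slope).spikes
    return FitResult(
        params=best,
        loss=float(losses[k]),
        restart_losses=losses.copy(),
        all_params=pop,
        silent=bool(spikes_best.sum() == 0),
        history=history,
    )
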