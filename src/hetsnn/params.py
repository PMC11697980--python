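"""Core data types for self-inhibiting spiking neurons.

A neuron population is described by five per-neuron biophysical parameters
(:class:`NeuronParams`), its running state (:class:`NeuronState`), and the
binary activity it emits (:class:`SpikeTrain`).  The spike nonlinearity is a
hard Heaviside step in the forward pass; gradients flow through a triangular
pseudo-derivative configured by :class:`SurrogateSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

PARAM_FIELDS = ("tau", "gamma", "C", "u_th", "u_re")


class ContractError(ValueError):
    """Raised when an operation's input contract is violated."""


def _as_vec(x, n: Optional[int] = None) -> np.ndarray:
    a = np.atleast_1d(np.asarray(x, dtype=float))
    if a.ndim != 1:
        raise ContractError(f"expected a per-neuron vector, got shape {a.shape}")
    if n is not None and a.shape[0] == 1 and n > 1:
        a = np.repeat(a, n)
    return a


@dataclass
class NeuronParams:
    """Per-neuron learnable biophysical parameters.

    Attributes
    ----------
    tau
        Membrane decay, dimensionless per-step fraction in ``[0, 1]``.
        ``tau = 0`` means a perfect integrator, ``tau = 1`` full decay to
        rest every step.
    gamma
        Autaptic self-inhibition strength: the amount of input current
        subtracted in the step after the neuron fired.  Nonnegative at
        initialization.
    C
        Input gain (capacitance-like): membrane-potential units per unit of
        input current.
    u_th
        Firing threshold potential.
    u_re
        Resting potential, also the hard-reset target after a spike.
    """

    tau: np.ndarray
    gamma: np.ndarray
    C: np.ndarray
    u_th: np.ndarray
    u_re: np.ndarray

    def __post_init__(self) -> None:
        n = np.atleast_1d(np.asarray(self.tau)).shape[0]
        for f in PARAM_FIELDS:
            setattr(self, f, _as_vec(getattr(self, f), n))
        shapes = {getattr(self, f).shape for f in PARAM_FIELDS}
        if len(shapes) != 1:
            raise ContractError(f"parameter fields have mismatched shapes: {shapes}")

    @property
    def n(self) -> int:
        return self.tau.shape[0]

    def copy(self) -> "NeuronParams":
        return NeuronParams(*(getattr(self, f).copy() for f in PARAM_FIELDS))

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in PARAM_FIELDS}

    def validate(self, at_init: bool = True) -> list[str]:
        """Return a list of human-readable invariant violations.

        ``at_init=True`` applies the initialization-time constraints
        (``tau`` in [0,1], ``gamma >= 0``, ``u_th > u_re``); trained values
        may drift, in which case the report flags rather than forbids.
        """
        issues: list[str] = []
        for f in PARAM_FIELDS:
            v = getattr(self, f)
            if not np.all(np.isfinite(v)):
                issues.append(f"{f}: non-finite entries at {np.flatnonzero(~np.isfinite(v))[:5]}")
        if at_init:
            if np.any((self.tau < 0) | (self.tau > 1)):
                issues.append("tau outside [0, 1]")
            if np.any(self.gamma < 0):
                issues.append("gamma negative")
            if np.any(self.u_th <= self.u_re):
                issues.append("u_th <= u_re for some neurons")
        return issues


def default_params(
    n: int,
    tau: float = 0.5,
    gamma: float = 0.1,
    C: float = 1.0,
    u_th: float = 1.0,
    u_re: float = 0.0,
    jitter_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> NeuronParams:
    """Homogeneous defaults, optionally perturbed by seeded Gaussian jitter.

    Jitter breaks homogeneity at initialization so that heterogeneous
    learning does not start from a symmetric saddle.  ``tau`` is clipped to
    [0.01, 0.99] and ``gamma`` to >= 0 after jittering.
    """
    base = {"tau": tau, "gamma": gamma, "C": C, "u_th": u_th, "u_re": u_re}
    vecs = {k: np.full(n, v, dtype=float) for k, v in base.items()}
    if jitter_sd > 0:
        if rng is None:
            raise ContractError("jitter_sd > 0 requires a seeded rng")
        for k in vecs:
            vecs[k] = vecs[k] + jitter_sd * rng.standard_normal(n)
        vecs["tau"] = np.clip(vecs["tau"], 0.01, 0.99)
        vecs["gamma"] = np.maximum(vecs["gamma"], 0.0)
    return NeuronParams(**vecs)


@dataclass
class NeuronState:
    """Membrane potential and last-step output of a population."""

    u: np.ndarray
    o_prev: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.o_prev = np.asarray(self.o_prev, dtype=float)
        if self.u.shape != self.o_prev.shape:
            raise ContractError("u and o_prev shapes differ")

    @classmethod
    def resting(cls, params: NeuronParams, batch: Optional[int] = None) -> "NeuronState":
        shape = (params.n,) if batch is None else (batch, params.n)
        return cls(np.broadcast_to(params.u_re, shape).copy(), np.zeros(shape))


@dataclass
class SpikeTrain:
    """Binary activity array, neurons x time steps.

    ``dt_label`` is a nominal step duration in milliseconds used only for
    reporting (time-window metrics, membrane time constants); the dynamics
    themselves are dimensionless per-step recursions.
    """

    spikes: np.ndarray
    dt_label: Optional[float] = None

    def __post_init__(self) -> None:
        s = np.asarray(self.spikes)
        if s.ndim == 1:
            s = s[None, :]
        if s.ndim != 2 or s.shape[1] < 1:
            raise ContractError(f"spikes must be [neurons x time], got {s.shape}")
        if not np.isin(np.unique(s), (0, 1)).all():
            raise ContractError("spike entries must be binary")
        self.spikes = s.astype(np.uint8)

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[1]

    def rate(self) -> np.ndarray:
        """Per-neuron mean firing probability per step."""
        return self.spikes.mean(axis=1)


@dataclass(frozen=True)
class SurrogateSpec:
    """Triangle pseudo-derivative for the spike Heaviside.

    ``width`` is the half-support in membrane-potential units around the
    threshold: g(x) = (1/width) * max(0, 1 - |x|/width), which integrates
    to 1 and is zero for |x| >= width.
    """

    width: float = 1.0
    shape: str = "triangle"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ContractError("surrogate width must be > 0")
        if self.shape != "triangle":
            raise ContractError(f"unsupported surrogate shape {self.shape!r}")


def triangle_grad(x: np.ndarray, width: float = 1.0) -> np.ndarray:
    """Triangular pseudo-derivative g(x) evaluated at x = u - u_th."""
    x = np.asarray(x, dtype=float)
    return np.maximum(0.0, 1.0 - np.abs(x) / width) / width


def soft_spike(x: np.ndarray, width: float = 1.0) -> np.ndarray:
    """Antiderivative of :func:`triangle_grad`: a C1 ramp from 0 to 1.

    Used by the relaxed (fully differentiable) forward pass whose exact
    gradient the surrogate backward computes; the hard forward replaces it
    with a strict Heaviside.
    """
    x = np.asarray(x, dtype=float) / width
    out = np.empty_like(x)
    lo, hi = x <= -1.0, x >= 1.0
    mid_neg = (~lo) & (x < 0)
    mid_pos = (~hi) & (x >= 0)
    out[lo] = 0.0
    out[hi] = 1.0
    out[mid_neg] = 0.5 * (x[mid_neg] + 1.0) ** 2
    out[mid_pos] = 1.0 - 0.5 * (1.0 - x[mid_pos]) ** 2
    return out
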