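"""Energy functions and relaxation dynamics of the continuous Hopfield network.

The network state is a vector ``u`` of neuron activations partitioned into a
clamped input block ``x`` (the first ``p`` entries) and free units
``s = (h, y)`` (hidden then output).  The free units evolve by forward Euler
gradient descent on the total energy

    F(u; beta) = E(u) + beta * C(y),
    E(u) = 1/2 u'u - 1/2 rho(u)' W rho(u) - b' rho(u),
    C(y) = 1/2 ||y - y_d||^2,

where ``rho`` is the hard sigmoid (identity on [0,1], clamped outside) with
its derivative defined to be 1 on the *closed* interval [0,1].  ``beta = 0``
gives the free phase; a small nonzero ``beta`` weakly nudges the output
toward the target (weakly-clamped phase).

Two bias conventions exist in the literature: ``-b' rho(u)`` (the default,
under which the bias correction rule is the exact parameter gradient of F)
and the ``-b' u`` variant, selectable with ``bias_on_rho=False``.

After every Euler step the free units are clipped to [0,1] (configurable),
which keeps states inside the hard sigmoid's linear region; there
``rho(u) = u`` and ``rho'(u) = 1`` exactly, and a cheaper update rule
applies (used automatically when valid).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .topology import LayerSpec, Parameters

__all__ = [
    "NetworkState",
    "RelaxationConfig",
    "activation",
    "activation_prime",
    "energy",
    "cost",
    "total_energy",
    "state_gradient",
    "relax",
    "gradient_inf_norm",
]


def activation(x):
    """Hard sigmoid: 0 below 0, identity on [0,1], 1 above 1 (elementwise)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("activation input must be finite")
    return np.clip(x, 0.0, 1.0)


def activation_prime(x):
    """Derivative of the hard sigmoid; defined to be 1 at both corners.

    Returns 1 on the closed interval [0,1] and 0 outside, so neurons sitting
    exactly on a clipping boundary still pass gradient.
    """
    x = np.asarray(x, dtype=float)
    return ((x >= 0.0) & (x <= 1.0)).astype(float)


@dataclass
class NetworkState:
    """Activations ``u`` of all neurons, with the input block clamped.

    ``u`` may be a single state ``(n,)`` or a batch ``(n, m)`` with one
    column per example.  Views ``x``, ``s``, ``h``, ``y`` address the input,
    free, hidden and output blocks.
    """

    layers: LayerSpec
    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape[0] != self.layers.n:
            raise ValueError(
                f"state has {self.u.shape[0]} rows, network has {self.layers.n} neurons"
            )

    @classmethod
    def cold_start(cls, layers: LayerSpec, x: np.ndarray) -> "NetworkState":
        """Clamp ``x`` (shape ``(p,)`` or ``(p, m)``) and zero all free units."""
        x = np.asarray(x, dtype=float)
        if x.shape[0] != layers.n_input:
            raise ValueError("input block has wrong width")
        u = np.zeros((layers.n,) + x.shape[1:])
        u[: layers.n_input] = x
        return cls(layers, u)

    @property
    def x(self) -> np.ndarray:
        return self.u[: self.layers.n_input]

    @property
    def s(self) -> np.ndarray:
        return self.u[self.layers.n_input :]

    @property
    def h(self) -> np.ndarray:
        return self.u[self.layers.n_input : self.layers.n - self.layers.n_output]

    @property
    def y(self) -> np.ndarray:
        return self.u[self.layers.n - self.layers.n_output :]

    @property
    def clamped_mask(self) -> np.ndarray:
        m = np.zeros(self.layers.n, dtype=bool)
        m[: self.layers.n_input] = True
        return m

    def copy(self) -> "NetworkState":
        return NetworkState(self.layers, self.u.copy())


@dataclass
class RelaxationConfig:
    """Forward-Euler settings: step size, iteration count, clamping factor."""

    eps: float
    n_iterations: int
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("Euler step size must be positive")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")


def _as_2d(a: np.ndarray) -> np.ndarray:
    return a if a.ndim == 2 else a[:, None]


def energy(state: NetworkState, params: Parameters, bias_on_rho: bool = True):
    """Hopfield energy E(u); scalar for a single state, per-column for a batch."""
    u = _as_2d(state.u)
    rho = activation(u)
    quad = 0.5 * np.sum(u * u, axis=0)
    inter = 0.5 * np.sum(rho * (params.W @ rho), axis=0)
    bias = params.b @ (rho if bias_on_rho else u)
    e = quad - inter - bias
    return float(e[0]) if state.u.ndim == 1 else e


def cost(y: np.ndarray, y_d: np.ndarray):
    """Quadratic cost 1/2 ||y - y_d||^2, per example for batched inputs."""
    y = np.asarray(y, dtype=float)
    y_d = np.asarray(y_d, dtype=float)
    if y.shape != y_d.shape:
        raise ValueError(f"output {y.shape} and target {y_d.shape} shapes differ")
    c = 0.5 * np.sum((y - y_d) ** 2, axis=0)
    return float(c) if y.ndim == 1 else c


def total_energy(
    state: NetworkState,
    params: Parameters,
    beta: float,
    y_d: Optional[np.ndarray] = None,
    bias_on_rho: bool = True,
):
    """Total energy F = E + beta * C."""
    e = energy(state, params, bias_on_rho=bias_on_rho)
    if beta == 0.0:
        return e
    if y_d is None:
        raise ValueError("a target is required when beta != 0")
    return e + beta * cost(state.y, y_d)


def _gradient_free(
    u: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    p: int,
    r: int,
    beta: float,
    y_d: Optional[np.ndarray],
    bias_on_rho: bool,
) -> np.ndarray:
    """dF/ds for 2-D ``u`` of shape (n, m); returns (n-p, m)."""
    rho = np.clip(u, 0.0, 1.0)
    rprime = ((u >= 0.0) & (u <= 1.0)).astype(float)
    drive = W @ rho
    if bias_on_rho:
        g = u - rprime * (drive + b[:, None])
    else:
        g = u - rprime * drive - b[:, None]
    g = g[p:]
    if beta != 0.0:
        if y_d is None:
            raise ValueError("a target is required when beta != 0")
        g[-r:] += beta * (u[-r:] - y_d)
    return g


def state_gradient(
    state: NetworkState,
    params: Parameters,
    beta: float = 0.0,
    y_d: Optional[np.ndarray] = None,
    bias_on_rho: bool = True,
) -> np.ndarray:
    """Analytic dF/ds over the free units (clamped inputs excluded).

    The cost term contributes ``beta * (y - y_d)`` on the output coordinates
    only.  Shape matches ``state.s``.
    """
    u = _as_2d(state.u)
    yd = None if y_d is None else _as_2d(np.asarray(y_d, dtype=float))
    g = _gradient_free(
        u,
        params.W,
        params.b,
        state.layers.n_input,
        state.layers.n_output,
        beta,
        yd,
        bias_on_rho,
    )
    return g[:, 0] if state.u.ndim == 1 else g


def gradient_inf_norm(
    state: NetworkState,
    params: Parameters,
    beta: float = 0.0,
    y_d: Optional[np.ndarray] = None,
    bias_on_rho: bool = True,
) -> float:
    """Max-norm of dF/ds — a convergence diagnostic (0 at equilibrium)."""
    g = state_gradient(state, params, beta, y_d, bias_on_rho)
    return float(np.max(np.abs(g))) if g.size else 0.0


def relax(
    state: NetworkState,
    params: Parameters,
    config: RelaxationConfig,
    y_d: Optional[np.ndarray] = None,
    bias_on_rho: bool = True,
    clip: bool = True,
) -> NetworkState:
    """Run ``n_iterations`` forward-Euler steps ``s <- clip(s - eps dF/ds)``.

    The input block is never touched.  Returns a new state; the argument is
    not modified.  When clipping is on and the state starts inside [0,1]
    the hard sigmoid is the identity with unit derivative throughout, and a
    fused cheaper update is used; otherwise the generic gradient is
    evaluated each step.  Both paths produce identical trajectories on the
    states where they are both valid.
    """
    if config.beta != 0.0 and y_d is None:
        raise ValueError("a target is required for the weakly-clamped phase")
    layers = state.layers
    p, r = layers.n_input, layers.n_output
    single = state.u.ndim == 1
    u = _as_2d(state.u).copy()
    yd = None if y_d is None else _as_2d(np.asarray(y_d, dtype=float))
    if yd is not None and yd.shape != (r, u.shape[1]):
        raise ValueError(
            f"target shape {yd.shape} does not match output block ({r}, {u.shape[1]})"
        )
    eps, beta = config.eps, config.beta

    fast = clip and np.all(u >= 0.0) and np.all(u <= 1.0)
    if fast:
        # rho(u) = u, rho'(u) = 1 for the whole trajectory
        Wf = params.W[p:]
        bf = params.b[p:][:, None]
        s = u[p:]
        for _ in range(config.n_iterations):
            drive = Wf @ u
            drive += bf
            g = s - drive
            if beta != 0.0:
                g[-r:] += beta * (s[-r:] - yd)
            s -= eps * g
            np.clip(s, 0.0, 1.0, out=s)
    else:
        for _ in range(config.n_iterations):
            g = _gradient_free(u, params.W, params.b, p, r, beta, yd, bias_on_rho)
            s = u[p:] - eps * g
            if clip:
                np.clip(s, 0.0, 1.0, out=s)
            u[p:] = s
    return NetworkState(layers, u[:, 0] if single else u)
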