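"""Independent numerical oracles shared by the test suite.

These deliberately avoid the package's analytic-gradient code paths: cost
gradients come from central finite differences through the full relaxation,
and energy gradients from finite differences of the energy value.
"""
from __future__ import annotations

import numpy as np

from eqprop.dynamics import NetworkState, RelaxationConfig, cost, relax, total_energy


def free_equilibrium(params, layers, X, eps=0.5, n_iter=2000):
    state = NetworkState.cold_start(layers, np.atleast_2d(X).T)
    return relax(state, params, RelaxationConfig(eps, n_iter, 0.0))


def mean_free_cost(params, layers, X, Y, eps=0.5, n_iter=2000) -> float:
    """Mean cost over the batch at the free-phase fixed point."""
    state = free_equilibrium(params, layers, X, eps, n_iter)
    return float(np.mean(cost(state.y, np.atleast_2d(Y).T)))


def fd_cost_gradient(
    params, topology, X, Y, eps=0.5, n_iter=2000, delta=1e-4
) -> np.ndarray:
    """Central finite-difference gradient of the free-fixed-point cost with
    respect to each undirected weight (canonical edge order)."""
    ii, jj = topology.edge_index
    g = np.zeros(len(ii))
    for k in range(len(ii)):
        i, j = ii[k], jj[k]
        vals = []
        for sign in (1.0, -1.0):
            p2 = params.copy()
            p2.W[i, j] += sign * delta
            p2.W[j, i] += sign * delta
            vals.append(mean_free_cost(p2, topology.layers, X, Y, eps, n_iter))
        g[k] = (vals[0] - vals[1]) / (2 * delta)
    return g


def gradient_theorem_cosines(
    make_seed,
    n_networks: int = 10,
    max_attempts: int = 30,
    beta: float = 0.005,
    n_iter: int = 2000,
    margin: float = 0.01,
) -> list[float]:
    """Cosine between -dW and the finite-difference cost gradient on random
    3-5-4-2 instances.

    The small-beta gradient theorem assumes the cost is locally smooth in
    the weights.  At the hard sigmoid's corners it is not: an output unit
    sitting *at* a corner with a drive margin smaller than the probes
    (|beta| for the clamped nudge, the finite-difference step for the
    oracle) puts the cost at a kink, where the two estimators legitimately
    disagree or return 0/0.  A candidate instance is valid when every
    free-phase output coordinate is either solidly interior (more than
    ``margin`` from both corners) or solidly pinned (recurrent drive at
    least ``margin`` beyond the corner, so neither probe can unpin it —
    its cost contribution is locally constant for both estimators).
    Cosines come from the first ``n_networks`` valid instances;
    ``make_seed(k)`` supplies the seed for the k-th candidate.
    """
    from eqprop import (
        Hyperparameters,
        LayerSpec,
        PersistentStore,
        build_mlff,
        initialize_parameters,
        train_batch,
    )

    hp = Hyperparameters(
        alpha=0.0, beta_magnitude=beta, n_free=n_iter, n_clamped=n_iter,
        randomize_beta_sign=False,
    )
    topo = build_mlff(LayerSpec((3, 5, 4, 2)))
    ii, jj = topo.edge_index
    cosines: list[float] = []
    for k in range(max_attempts):
        if len(cosines) >= n_networks:
            break
        rng = np.random.default_rng(make_seed(k))
        params = initialize_parameters(topo, rng)
        X = rng.uniform(0.1, 0.9, (4, 3))
        Y = np.eye(2)[rng.integers(0, 2, 4)]
        free = free_equilibrium(params, topo.layers, X, n_iter=n_iter)
        y = free.y
        drive = (params.W @ np.clip(free.u, 0, 1) + params.b[:, None])[
            -topo.layers.n_output :
        ]
        interior = (y > margin) & (y < 1 - margin)
        pinned_low = (y <= margin) & (drive <= -margin)
        pinned_high = (y >= 1 - margin) & (drive >= 1 + margin)
        if not np.all(interior | pinned_low | pinned_high):
            continue  # some output sits in the kink band: cost not smooth
        if np.all(pinned_low | pinned_high):
            continue  # cost locally constant: nothing to compare (0/0)
        res = train_batch(
            params, topo, X, Y, PersistentStore(), hp, np.random.default_rng(0)
        )
        est = -res.corrections.dW[ii, jj]
        g = fd_cost_gradient(params, topo, X, Y, n_iter=n_iter)
        cosines.append(
            float(np.dot(est, g) / (np.linalg.norm(est) * np.linalg.norm(g)))
        )
    return cosines


def fd_state_gradient(state, params, beta, y_d, bias_on_rho=True, delta=1e-6):
    """Central finite-difference dF/ds at a (single-example) state."""
    layers = state.layers
    p = layers.n_input
    g = np.zeros(layers.n_free)
    for k in range(layers.n_free):
        vals = []
        for sign in (1.0, -1.0):
            s2 = state.copy()
            s2.u[p + k] += sign * delta
            vals.append(total_energy(s2, params, beta, y_d, bias_on_rho=bias_on_rho))
        g[k] = (vals[0] - vals[1]) / (2 * delta)
    return g
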