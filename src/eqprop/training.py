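"""Two-phase equilibrium-propagation training loop.

For each batch: clamp the inputs, relax the free units to the free-phase
equilibrium ``u0`` (beta = 0), then continue relaxing with the output weakly
nudged toward the target (signed clamping factor beta) to reach ``u_beta``.
The parameter corrections are purely local contrasts between the two
equilibria,

    dW_ij = (1/beta) * (rho(u_beta_i) rho(u_beta_j) - rho(u0_i) rho(u0_j)),
    db_i  = (1/beta) * (rho(u_beta_i) - rho(u0_i)),

averaged over the batch and applied once per batch with learning rate alpha
(either a single global rate or one rate per adjacent layer pair).  In the
small-beta limit ``-dW`` approaches the gradient of the free-equilibrium
cost with respect to the weights, which is the correctness oracle the test
suite checks by finite differences.

Two stabilizers from the reference training procedure are implemented:
the sign of beta is randomized before each batch (a regularizer), and
*persistent particles* — each batch's free-phase equilibrium is cached and
reused as that batch's initial state in the next epoch, so far fewer Euler
iterations are needed per phase.

Error conventions: training error is recorded on each batch from the
free-phase outputs *before* the parameter update; test error is computed by
free-phase relaxation over the test set after each full epoch.  Early in
training this can make the training error exceed the test error, since test
batches see a fully updated network.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .data import Dataset
from .dynamics import NetworkState, RelaxationConfig, activation, relax
from .topology import Parameters, TopologyGraph

__all__ = [
    "Hyperparameters",
    "CorrectionPair",
    "PersistentStore",
    "TrainBatchResult",
    "TrainingLog",
    "weight_corrections",
    "bias_corrections",
    "apply_updates",
    "draw_beta",
    "train_batch",
    "evaluate",
    "fit",
]


@dataclass
class Hyperparameters:
    """Training settings.

    ``alpha`` is either one global learning rate or a per-adjacent-pair list
    of length N+1 for N hidden layers (rate ``alpha_l`` scales updates to
    the weights between layers l and l+1 and to the biases of layer l+1).
    ``beta_magnitude`` is |beta|; the sign is redrawn per batch when
    ``randomize_beta_sign`` is set.  ``eps`` is the Euler step, ``n_free``
    and ``n_clamped`` the per-phase iteration counts.
    """

    alpha: Union[float, Sequence[float]] = 0.02
    beta_magnitude: float = 1.0
    eps: float = 0.5
    n_free: int = 500
    n_clamped: int = 8
    batch_size: int = 20
    epochs: int = 1
    randomize_beta_sign: bool = True
    bias_on_rho: bool = True
    clip_states: bool = True

    def __post_init__(self) -> None:
        if self.per_layer:
            self.alpha = tuple(float(a) for a in self.alpha)
            if any(a <= 0 for a in self.alpha):
                raise ValueError("all per-layer learning rates must be positive")
        elif self.alpha < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.beta_magnitude <= 0:
            raise ValueError("beta magnitude must be positive")
        if self.eps <= 0:
            raise ValueError("Euler step must be positive")
        if self.n_free < 1 or self.n_clamped < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be >= 1")

    @property
    def per_layer(self) -> bool:
        return not np.isscalar(self.alpha)


@dataclass
class CorrectionPair:
    """Batch-averaged corrections: symmetric ``dW`` (zero off-mask) and ``db``."""

    dW: np.ndarray
    db: np.ndarray


class PersistentStore:
    """Cache of free-phase equilibria keyed by batch identifier."""

    def __init__(self) -> None:
        self._states: dict = {}

    def get(self, batch_id) -> Optional[np.ndarray]:
        return self._states.get(batch_id)

    def put(self, batch_id, u: np.ndarray) -> None:
        self._states[batch_id] = np.array(u, copy=True)

    def __len__(self) -> int:
        return len(self._states)

    def __contains__(self, batch_id) -> bool:
        return batch_id in self._states

    def save(self, path) -> None:
        np.savez(path, **{f"batch_{k}": v for k, v in self._states.items()})

    @classmethod
    def load(cls, path) -> "PersistentStore":
        store = cls()
        with np.load(path) as data:
            for key in data.files:
                store._states[int(key.removeprefix("batch_"))] = data[key]
        return store


def _phase_states(u) -> np.ndarray:
    if isinstance(u, NetworkState):
        u = u.u
    return np.asarray(u, dtype=float)


def weight_corrections(u0, ubeta, beta: float, mask: np.ndarray) -> np.ndarray:
    """Per-connection weight corrections contrasting the two equilibria.

    Accepts states as ``(n,)`` vectors or ``(n, m)`` batches (averaged over
    the ``m`` examples).  The result is symmetric, zero on the diagonal and
    zero wherever ``mask`` is false.
    """
    if beta == 0.0:
        raise ValueError("weight corrections are undefined at beta = 0")
    r0 = activation(_phase_states(u0))
    rb = activation(_phase_states(ubeta))
    if r0.ndim == 1:
        r0 = r0[:, None]
        rb = rb[:, None]
    m = r0.shape[1]
    dW = (rb @ rb.T - r0 @ r0.T) / (beta * m)
    dW[~mask] = 0.0
    return dW


def bias_corrections(u0, ubeta, beta: float, n_input: int) -> np.ndarray:
    """Per-neuron bias corrections; input-neuron entries are forced to zero
    (inputs are clamped, their biases untrainable)."""
    if beta == 0.0:
        raise ValueError("bias corrections are undefined at beta = 0")
    r0 = activation(_phase_states(u0))
    rb = activation(_phase_states(ubeta))
    diff = (rb - r0) / beta
    if diff.ndim == 2:
        diff = diff.mean(axis=1)
    db = np.asarray(diff, dtype=float)
    db[:n_input] = 0.0
    return db


def _per_layer_rate_arrays(
    hp: Hyperparameters, topology: TopologyGraph
) -> tuple[np.ndarray, np.ndarray]:
    layers = topology.layers
    rates = np.asarray(hp.alpha, dtype=float)
    if rates.shape != (layers.n_layers - 1,):
        raise ValueError(
            f"per-layer mode needs {layers.n_layers - 1} rates "
            f"(N+1 for N hidden layers), got {rates.shape[0]}"
        )
    if topology.skip_edges:
        raise ValueError(
            "per-layer learning rates are defined for strictly layered (MLFF) "
            "topologies only"
        )
    lof = layers.layer_of  # 1-based
    # weight between layers l, l+1 gets alpha_l; lower endpoint's layer = l
    # (entries off the adjacent-pair mask carry zero corrections, so the
    # clip below only keeps indexing in range)
    lower = np.clip(np.minimum.outer(lof, lof), 1, len(rates))
    w_rate = rates[lower - 1]
    # biases of layer l+1 get alpha_l; input biases are untrainable anyway
    b_rate = np.zeros(layers.n)
    b_rate[layers.n_input :] = rates[lof[layers.n_input :] - 2]
    return w_rate, b_rate


def apply_updates(
    params: Parameters,
    corr: CorrectionPair,
    hp: Hyperparameters,
    topology: TopologyGraph,
) -> Parameters:
    """Return new parameters ``W + alpha dW``, ``b + alpha db``.

    Global mode scales everything by one rate; per-layer mode scales each
    adjacent-pair weight group and the downstream layer's biases by its own
    rate (rejected when the topology has skip edges).  Symmetry, the zero
    diagonal and the mask are preserved.
    """
    if hp.per_layer:
        w_rate, b_rate = _per_layer_rate_arrays(hp, topology)
        W = params.W + w_rate * corr.dW
        b = params.b + b_rate * corr.db
    else:
        W = params.W + hp.alpha * corr.dW
        b = params.b + hp.alpha * corr.db
    W[~topology.mask] = 0.0
    b[: topology.layers.n_input] = 0.0
    return Parameters(W, b, params.topology_checksum)


def draw_beta(hp: Hyperparameters, rng: np.random.Generator) -> float:
    """Signed clamping factor for the next batch: ±|beta|, sign uniform."""
    if not hp.randomize_beta_sign:
        return hp.beta_magnitude
    sign = 1.0 if rng.uniform() < 0.5 else -1.0
    return sign * hp.beta_magnitude


@dataclass
class TrainBatchResult:
    params: Parameters
    corrections: CorrectionPair
    predictions: np.ndarray  # free-phase outputs, (examples x r), pre-update
    error: float
    beta: float


def _batch_error(y_pred: np.ndarray, y_true: np.ndarray, task_kind: str) -> float:
    if task_kind == "classification":
        return _metrics.classification_error(y_pred, y_true)
    return _metrics.regression_error(y_pred, y_true)


def train_batch(
    params: Parameters,
    topology: TopologyGraph,
    X: np.ndarray,
    Y: np.ndarray,
    store: PersistentStore,
    hp: Hyperparameters,
    rng: np.random.Generator,
    batch_id=0,
    task_kind: str = "classification",
) -> TrainBatchResult:
    """One two-phase pass over a batch; applies the averaged corrections once.

    The batch error is computed from the free-phase outputs *before* the
    update.  The free-phase equilibrium is stored under ``batch_id`` for
    reuse next epoch (persistent particles).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    layers = topology.layers
    p = layers.n_input

    u_init = store.get(batch_id)
    if u_init is None:
        state = NetworkState.cold_start(layers, X.T)
    else:
        u = u_init.copy()
        u[:p] = X.T  # re-clamp, in case parameters of the batch moved
        state = NetworkState(layers, u)

    free_cfg = RelaxationConfig(hp.eps, hp.n_free, 0.0)
    state0 = relax(
        state, params, free_cfg, bias_on_rho=hp.bias_on_rho, clip=hp.clip_states
    )
    y0 = state0.y.T.copy()
    error = _batch_error(y0, Y, task_kind)

    beta = draw_beta(hp, rng)
    clamped_cfg = RelaxationConfig(hp.eps, hp.n_clamped, beta)
    state_b = relax(
        state0,
        params,
        clamped_cfg,
        y_d=Y.T,
        bias_on_rho=hp.bias_on_rho,
        clip=hp.clip_states,
    )

    dW = weight_corrections(state0.u, state_b.u, beta, topology.mask)
    db = bias_corrections(state0.u, state_b.u, beta, p)
    corr = CorrectionPair(dW, db)
    new_params = apply_updates(params, corr, hp, topology)
    store.put(batch_id, state0.u)
    return TrainBatchResult(new_params, corr, y0, error, beta)


def _iter_batches(n_examples: int, batch_size: int):
    for start in range(0, n_examples, batch_size):
        yield start // batch_size, slice(start, min(start + batch_size, n_examples))


def evaluate(
    params: Parameters,
    topology: TopologyGraph,
    X: np.ndarray,
    Y: np.ndarray,
    hp: Hyperparameters,
    task_kind: str = "classification",
) -> float:
    """Free-phase error over a dataset (cold start, ``n_free`` iterations)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    layers = topology.layers
    cfg = RelaxationConfig(hp.eps, hp.n_free, 0.0)
    wrong = 0.0
    for _, sl in _iter_batches(X.shape[0], hp.batch_size):
        state = NetworkState.cold_start(layers, X[sl].T)
        state = relax(
            state, params, cfg, bias_on_rho=hp.bias_on_rho, clip=hp.clip_states
        )
        err = _batch_error(state.y.T, Y[sl], task_kind)
        wrong += err * (sl.stop - sl.start)
    return wrong / X.shape[0]


@dataclass
class TrainingLog:
    """Everything a run produces besides the final parameters.

    ``batch_log`` has one row per batch (epoch, batch, beta, error, one RMS
    column per adjacent layer pair, one for the skip group); ``epoch_log``
    has per-epoch train/test error.  ``w_adjacent`` holds the per-pair RMS
    corrections averaged per epoch then over epochs — the inputs to the
    log-spread.
    """

    batch_log: pd.DataFrame
    epoch_log: pd.DataFrame
    w_adjacent: np.ndarray
    w_skip: Optional[float]
    log_spread: float
    params: Parameters
    correction_matrix: Optional[np.ndarray] = None

    #: RMS corrections below this are floating-point dust, not training:
    #: any actually-training layer pair sits orders of magnitude above it.
    DUST_THRESHOLD = 1e-8

    @property
    def is_degenerate(self) -> bool:
        """True when some layer pair received no real corrections.

        In strongly-coupled regimes (narrow layers, |beta| comparable to 1)
        an initialization can saturate the output so hard that the clamped
        phase cannot move it; both equilibria then coincide and the network
        never trains.  Such a run's per-pair RMS values are numerical noise
        and its log-spread is meaningless.
        """
        return bool(np.min(self.w_adjacent) < self.DUST_THRESHOLD)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.batch_log.to_csv(outdir / "batch_log.csv", index=False)
        self.epoch_log.to_csv(outdir / "epoch_log.csv", index=False)
        summary = pd.DataFrame(
            {
                "group": [str(l + 1) for l in range(len(self.w_adjacent))]
                + (["skip"] if self.w_skip is not None else []),
                "w_rms": list(self.w_adjacent)
                + ([self.w_skip] if self.w_skip is not None else []),
            }
        )
        summary.to_csv(outdir / "w_rms.csv", index=False)
        (outdir / "log_spread.txt").write_text(f"{self.log_spread}\n")
        if self.correction_matrix is not None:
            np.savetxt(
                outdir / "correction_matrix.csv", self.correction_matrix, delimiter=","
            )


def fit(
    params: Parameters,
    topology: TopologyGraph,
    dataset: Dataset,
    hp: Hyperparameters,
    rng: np.random.Generator,
    track_correction_matrix: bool = False,
) -> TrainingLog:
    """Run the full training loop and collect the diagnostic statistics.

    Batches are fixed consecutive slices of the training set (no
    reshuffling between epochs, so persistent-particle identity is stable).
    Per-epoch training error is the example-weighted mean of the pre-update
    batch errors; test error is evaluated by free-phase relaxation after
    each epoch.
    """
    if dataset.n_train == 0:
        raise ValueError("empty training set")
    params = params.copy()
    store = PersistentStore()
    groups = _metrics.layer_pair_groups(topology)
    adjacent = groups[:-1]
    skip_group = groups[-1]
    acc = (
        _metrics.CorrectionMatrixAccumulator(topology.layers.n)
        if track_correction_matrix
        else None
    )

    batch_rows = []
    epoch_rows = []
    X, Y = dataset.X_train, dataset.Y_train
    for epoch in range(1, hp.epochs + 1):
        wrong = 0.0
        for bi, sl in _iter_batches(X.shape[0], hp.batch_size):
            res = train_batch(
                params,
                topology,
                X[sl],
                Y[sl],
                store,
                hp,
                rng,
                batch_id=bi,
                task_kind=dataset.task_kind,
            )
            params = res.params
            if acc is not None:
                acc.update(res.corrections.dW)
            row = {
                "epoch": epoch,
                "batch": bi,
                "beta": res.beta,
                "error": res.error,
            }
            for g in adjacent:
                row[f"rms_{g.label}"] = _metrics.rms_correction(res.corrections.dW, g)
            row["rms_skip"] = _metrics.rms_correction(res.corrections.dW, skip_group)
            batch_rows.append(row)
            wrong += res.error * (sl.stop - sl.start)
        train_error = wrong / X.shape[0]
        test_error = (
            evaluate(
                params, topology, dataset.X_test, dataset.Y_test, hp, dataset.task_kind
            )
            if dataset.n_test
            else np.nan
        )
        epoch_rows.append(
            {"epoch": epoch, "train_error": train_error, "test_error": test_error}
        )

    batch_log = pd.DataFrame(batch_rows)
    epoch_log = pd.DataFrame(epoch_rows)
    # per-batch RMS -> mean within epoch -> mean across epochs
    adj_cols = [f"rms_{g.label}" for g in adjacent]
    w_adjacent = (
        batch_log.groupby("epoch")[adj_cols].mean().mean(axis=0).to_numpy()
    )
    if skip_group.n_edges:
        w_skip = float(batch_log.groupby("epoch")["rms_skip"].mean().mean())
    else:
        w_skip = None
    # a layer pair with literally zero corrections (fully dead run) has no
    # finite log-spread; report NaN rather than refuse to return the log
    spread = (
        _metrics.log_spread(w_adjacent) if np.all(w_adjacent > 0) else float("nan")
    )
    return TrainingLog(
        batch_log=batch_log,
        epoch_log=epoch_log,
        w_adjacent=w_adjacent,
        w_skip=w_skip,
        log_spread=spread,
        params=params,
        correction_matrix=acc.mean if acc is not None else None,
    )
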