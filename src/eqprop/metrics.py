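"""Diagnostics for how evenly a layered network trains.

The central quantities:

* per-layer-pair RMS weight-correction magnitude — for adjacent layer pair
  ``l`` (1-based from the input), the root mean square of the corrections to
  the weights connecting layers ``l`` and ``l+1``, each undirected edge
  counted once;
* the **log-spread** — the standard deviation of ``log10`` of the
  run-averaged per-pair RMS values.  A perfectly evenly-training network has
  log-spread 0; a strong vanishing gradient shows up as a large log-spread
  because corrections attenuate multiplicatively with distance from the
  output.

Layer-skipping edges are excluded from the adjacent-pair groups and from the
log-spread; they are tracked as a separate "skip" series.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .topology import TopologyGraph

__all__ = [
    "LayerPairGroup",
    "layer_pair_groups",
    "rms_correction",
    "log_spread",
    "classification_error",
    "regression_error",
    "CorrectionMatrixAccumulator",
]


@dataclass(frozen=True)
class LayerPairGroup:
    """A named set of undirected edges (index arrays with rows < cols)."""

    label: str  # "1".."N+1" for adjacent pairs, or "skip"
    rows: np.ndarray
    cols: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.rows)


def layer_pair_groups(
    topology: TopologyGraph, include_skip: bool = True
) -> list[LayerPairGroup]:
    """Partition the edge set into adjacent-pair groups plus one skip group.

    Group ``l`` holds exactly the non-skip edges between layers ``l`` and
    ``l+1``; together the adjacent groups cover all interlayer edges.  The
    skip group (always last, possibly empty) holds every layer-skipping edge.
    """
    n_pairs = topology.layers.n_layers - 1
    buckets: dict[str, list[tuple[int, int]]] = {
        str(l): [] for l in range(1, n_pairs + 1)
    }
    skips: list[tuple[int, int]] = []
    for e in topology.edges:
        if e.is_skip:
            skips.append(e.pair)
        else:
            buckets[str(e.layer_i)].append(e.pair)
    groups = []
    for label, pairs in buckets.items():
        arr = np.array(pairs, dtype=np.intp).reshape(-1, 2)
        groups.append(LayerPairGroup(label, arr[:, 0], arr[:, 1]))
    if include_skip:
        arr = np.array(skips, dtype=np.intp).reshape(-1, 2)
        groups.append(LayerPairGroup("skip", arr[:, 0], arr[:, 1]))
    return groups


def rms_correction(dW: np.ndarray, group: LayerPairGroup) -> Optional[float]:
    """Root mean square of the corrections to the group's edges.

    Each undirected edge contributes once (via its upper-triangular entry).
    An empty group has no defined RMS and yields ``None`` — an explicit
    absent marker, never 0.
    """
    if group.n_edges == 0:
        return None
    vals = dW[group.rows, group.cols]
    return float(np.sqrt(np.mean(vals**2)))


def log_spread(w: Sequence[float], ddof: int = 0) -> float:
    """Standard deviation of log10 of the per-pair averaged RMS corrections.

    ``w`` must contain the adjacent-pair values only (skip edges are a
    separate series) and be strictly positive — a zero entry means a layer
    received no corrections at all, which the logarithm cannot represent.
    Population convention (``ddof=0``) by default.
    """
    w = np.asarray(list(w), dtype=float)
    if w.size == 0:
        raise ValueError("log-spread of an empty sequence is undefined")
    if np.any(w <= 0):
        raise ValueError(
            "log-spread undefined: a layer pair has nonpositive RMS correction "
            "(dead layer)"
        )
    return float(np.std(np.log10(w), ddof=ddof))


def classification_error(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Fraction of examples whose argmax prediction misses the one-hot target.

    ``outputs`` and ``targets`` are (examples x r); argmax ties break toward
    the lowest index.
    """
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if outputs.shape != targets.shape:
        raise ValueError("outputs and targets must have the same shape")
    if outputs.shape[0] == 0:
        raise ValueError("empty batch")
    pred = np.argmax(outputs, axis=1)
    truth = np.argmax(targets, axis=1)
    return float(np.mean(pred != truth))


def regression_error(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared error of the outputs — the error metric for 1-output
    regression tasks, playing the role classification error plays elsewhere."""
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if outputs.shape != targets.shape:
        raise ValueError("outputs and targets must have the same shape")
    if outputs.size == 0:
        raise ValueError("empty batch")
    return float(np.mean((outputs - targets) ** 2))


class CorrectionMatrixAccumulator:
    """Running elementwise mean of |dW| over all batches seen.

    Visualized as an image, attenuation of this matrix with distance from
    the output block is the pixel-level signature of the vanishing gradient.
    """

    def __init__(self, n: int):
        self._sum = np.zeros((n, n))
        self._count = 0

    def update(self, dW: np.ndarray) -> None:
        if dW.shape != self._sum.shape:
            raise ValueError(
                f"shape mismatch: accumulator {self._sum.shape}, got {dW.shape}"
            )
        self._sum += np.abs(dW)
        self._count += 1

    @property
    def n_batches(self) -> int:
        return self._count

    @property
    def mean(self) -> np.ndarray:
        if self._count == 0:
            raise ValueError("no batches accumulated yet")
        return self._sum / self._count

    def to_csv(self, path) -> None:
        np.savetxt(path, self.mean, delimiter=",")
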