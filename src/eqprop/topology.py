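"""Layered Hopfield-network topologies and their initialization.

A network is a set of ``n`` neurons partitioned into ordered layers: layer 1
is the input layer, the last layer is the output layer, and everything
between is hidden.  Neuron indices are assigned contiguously by layer
(input neurons first, output neurons last).  Connections are undirected,
never within a layer and never from a neuron to itself.

Two connectivity patterns are provided:

* **MLFF** (multilayer feedforward): all-to-all connections between every
  pair of adjacent layers — the strictly layered topology in which the
  vanishing gradient problem appears under equilibrium propagation.
* **SW** (small-world inspired): start from MLFF and replace each interlayer
  connection, independently with probability ``p``, by a random
  *layer-skipping* connection (one whose endpoints are two or more layers
  apart), in the spirit of Watts–Strogatz rewiring.

Weight initialization follows the Glorot uniform scheme for interlayer
connections; layer-skipping connections draw from a single uniform range
derived from the per-pair Glorot bounds (see :func:`skip_init_bound`).
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LayerSpec",
    "Edge",
    "TopologyGraph",
    "Parameters",
    "build_mlff",
    "rewire_small_world",
    "glorot_bound",
    "skip_init_bound",
    "initialize_parameters",
    "save_parameters",
    "load_parameters",
]


@dataclass(frozen=True)
class LayerSpec:
    """Ordered layer widths of a layered network.

    ``sizes[0]`` is the input width, ``sizes[-1]`` the output width.  Layer
    indices are 1-based throughout; neuron indices are 0-based and assigned
    contiguously by layer.
    """

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        if len(sizes) < 2:
            raise ValueError("a network needs at least an input and an output layer")
        if any(s < 1 for s in sizes):
            raise ValueError(f"every layer must have at least one neuron, got {sizes}")
        object.__setattr__(self, "sizes", sizes)

    @property
    def n_layers(self) -> int:
        return len(self.sizes)

    @property
    def n_hidden_layers(self) -> int:
        return len(self.sizes) - 2

    @property
    def n(self) -> int:
        """Total neuron count."""
        return sum(self.sizes)

    @property
    def n_input(self) -> int:
        return self.sizes[0]

    @property
    def n_output(self) -> int:
        return self.sizes[-1]

    @property
    def n_free(self) -> int:
        """Hidden plus output neurons (everything not clamped to the input)."""
        return self.n - self.sizes[0]

    def offset(self, layer: int) -> int:
        """Index of the first neuron in 1-based ``layer``."""
        if not 1 <= layer <= self.n_layers:
            raise ValueError(f"layer {layer} out of range 1..{self.n_layers}")
        return sum(self.sizes[: layer - 1])

    def layer_slice(self, layer: int) -> slice:
        start = self.offset(layer)
        return slice(start, start + self.sizes[layer - 1])

    def neurons(self, layer: int) -> range:
        s = self.layer_slice(layer)
        return range(s.start, s.stop)

    @cached_property
    def layer_of(self) -> np.ndarray:
        """1-based layer index of each neuron, shape ``(n,)``."""
        out = np.repeat(np.arange(1, self.n_layers + 1), self.sizes)
        out.setflags(write=False)
        return out


@dataclass(frozen=True)
class Edge:
    """Undirected connection between neurons ``i < j`` in distinct layers."""

    i: int
    j: int
    layer_i: int
    layer_j: int

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("self-connections are not allowed")
        if self.i > self.j:
            raise ValueError("edges are stored with i < j")
        if self.layer_i >= self.layer_j:
            raise ValueError("edges within a layer are not allowed")

    @property
    def is_skip(self) -> bool:
        """True iff the endpoints are two or more layers apart."""
        return self.layer_j - self.layer_i >= 2

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


def _make_edge(i: int, j: int, layers: LayerSpec) -> Edge:
    if i > j:
        i, j = j, i
    lo = layers.layer_of
    return Edge(i, j, int(lo[i]), int(lo[j]))


def _canonical_key(e: Edge) -> tuple[int, int, int]:
    return (e.layer_i, e.i, e.j)


@dataclass(frozen=True)
class TopologyGraph:
    """Immutable connectivity of a layered network.

    ``edges`` are held in canonical order (by lower layer, then endpoint
    indices); the symmetric boolean ``mask`` is derived from them.
    ``rewire_p`` records the rewiring probability the topology was generated
    with (``None`` for plain MLFF) — generation metadata, not a live dial.
    """

    layers: LayerSpec
    edges: tuple[Edge, ...]
    rewire_p: float | None = None
    rewire_mode: str | None = None

    def __post_init__(self) -> None:
        edges = tuple(sorted(self.edges, key=_canonical_key))
        pairs = [e.pair for e in edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate undirected edges")
        n = self.layers.n
        for e in edges:
            if not (0 <= e.i < n and 0 <= e.j < n):
                raise ValueError(f"edge {e.pair} out of range for n={n}")
        object.__setattr__(self, "edges", edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def skip_edges(self) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.is_skip)

    @property
    def interlayer_edges(self) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if not e.is_skip)

    @cached_property
    def mask(self) -> np.ndarray:
        """Symmetric boolean incidence matrix with an all-false diagonal."""
        n = self.layers.n
        m = np.zeros((n, n), dtype=bool)
        if self.edges:
            ii = np.array([e.i for e in self.edges])
            jj = np.array([e.j for e in self.edges])
            m[ii, jj] = True
            m[jj, ii] = True
        m.setflags(write=False)
        return m

    @cached_property
    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Canonical ``(rows, cols)`` arrays with ``rows < cols``, one entry
        per undirected edge."""
        ii = np.array([e.i for e in self.edges], dtype=np.intp)
        jj = np.array([e.j for e in self.edges], dtype=np.intp)
        ii.setflags(write=False)
        jj.setflags(write=False)
        return ii, jj

    # -- serialization -----------------------------------------------------

    def serialize(self) -> str:
        """Line-oriented text form; round-trips the graph losslessly.

        Only the graph itself is written (layer sizes and edges), not the
        generation metadata, so a rewired topology that happens to equal an
        MLFF one serializes identically; experiment configs archive the
        rewiring probability separately.
        """
        lines = ["# layers: " + ",".join(str(s) for s in self.layers.sizes)]
        lines.append("i,j,layer_i,layer_j,is_skip")
        for e in self.edges:
            lines.append(f"{e.i},{e.j},{e.layer_i},{e.layer_j},{int(e.is_skip)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def deserialize(cls, text: str) -> "TopologyGraph":
        edges: list[Edge] = []
        spec: LayerSpec | None = None
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("# layers:"):
                sizes = tuple(int(t) for t in line.split(":", 1)[1].split(","))
                spec = LayerSpec(sizes)
            elif line.startswith("#") or line.startswith("i,j,"):
                continue
            else:
                if spec is None:
                    raise ValueError("edge line before layer header")
                i, j, *_ = (int(t) for t in line.split(","))
                edges.append(_make_edge(i, j, spec))
        if spec is None:
            raise ValueError("missing '# layers:' header")
        return cls(spec, tuple(edges))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.serialize())

    @classmethod
    def load(cls, path: str | Path) -> "TopologyGraph":
        return cls.deserialize(Path(path).read_text())

    @property
    def checksum(self) -> str:
        return hashlib.sha256(self.serialize().encode()).hexdigest()

    def summary(self) -> dict:
        by_pair: dict[str, int] = {}
        for e in self.interlayer_edges:
            key = f"L{e.layer_i}-L{e.layer_j}"
            by_pair[key] = by_pair.get(key, 0) + 1
        return {
            "sizes": list(self.layers.sizes),
            "n_edges": self.n_edges,
            "n_skip": len(self.skip_edges),
            "interlayer_by_pair": by_pair,
            "rewire_p": self.rewire_p,
        }


def build_mlff(layers: LayerSpec | Sequence[int]) -> TopologyGraph:
    """All-to-all connectivity between adjacent layers, nothing else.

    Edge count is ``sum(n_l * n_{l+1})`` over adjacent pairs.
    """
    if not isinstance(layers, LayerSpec):
        layers = LayerSpec(tuple(layers))
    edges = []
    for l in range(1, layers.n_layers):
        for i in layers.neurons(l):
            for j in layers.neurons(l + 1):
                edges.append(Edge(i, j, l, l + 1))
    return TopologyGraph(layers, tuple(edges))


def _skip_candidates(
    kept: int,
    kept_layer: int,
    layers: LayerSpec,
    existing: set[tuple[int, int]],
    allow_output_skips: bool,
) -> list[int]:
    """Legal partners for a layer-skipping edge anchored at ``kept``."""
    out: list[int] = []
    for l in range(1, layers.n_layers + 1):
        if abs(l - kept_layer) < 2:
            continue
        if not allow_output_skips and l == layers.n_layers:
            continue
        for cand in layers.neurons(l):
            a, b = (kept, cand) if kept < cand else (cand, kept)
            if (a, b) not in existing:
                out.append(cand)
    return out


def rewire_small_world(
    topology: TopologyGraph,
    p: float,
    rng: np.random.Generator,
    mode: str = "single",
    allow_output_skips: bool = True,
) -> TopologyGraph:
    """Replace interlayer connections by random layer-skipping ones.

    Each interlayer edge is visited in canonical order and independently
    selected with probability ``p``.  A selected edge is removed and replaced
    one-for-one by a layer-skipping edge: in ``"single"`` mode the endpoint in
    the lower-numbered layer is kept and the other endpoint is drawn uniformly
    from all neurons two or more layers away; in ``"free"`` mode both
    endpoints are drawn fresh.  Draws that would produce a self edge or a
    duplicate are rejected and redrawn (implemented as a uniform choice over
    the legal candidate set).  If no legal placement exists — possible in very
    small networks once the skip pairs are exhausted — the original edge is
    kept, so the total edge count is always conserved.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"rewiring probability must lie in [0,1], got {p}")
    if mode not in ("single", "free"):
        raise ValueError(f"unknown rewire mode {mode!r}")
    layers = topology.layers
    if p > 0 and layers.n_layers < 3:
        raise ValueError("layer-skipping requires at least 3 layers")

    existing = {e.pair for e in topology.edges}
    new_edges: list[Edge] = list(topology.skip_edges)
    for e in sorted(topology.interlayer_edges, key=_canonical_key):
        if rng.uniform() >= p:
            new_edges.append(e)
            continue
        replacement: Edge | None = None
        if mode == "free":
            # draw unordered pairs until one is a legal skip edge
            pool = [
                (a, b)
                for a in range(layers.n)
                for b in range(a + 1, layers.n)
                if layers.layer_of[b] - layers.layer_of[a] >= 2
                and (a, b) not in existing
                and (allow_output_skips or layers.layer_of[b] < layers.n_layers)
            ]
            if pool:
                replacement = _make_edge(*pool[rng.integers(len(pool))], layers)
        else:
            anchors = [(e.i, e.layer_i), (e.j, e.layer_j)]
            for kept, kept_layer in anchors:
                if not allow_output_skips and kept_layer == layers.n_layers:
                    continue
                cands = _skip_candidates(
                    kept, kept_layer, layers, existing, allow_output_skips
                )
                if cands:
                    partner = cands[rng.integers(len(cands))]
                    replacement = _make_edge(kept, partner, layers)
                    break
        if replacement is None:
            new_edges.append(e)  # no legal skip placement left
            continue
        existing.discard(e.pair)
        existing.add(replacement.pair)
        new_edges.append(replacement)
    return TopologyGraph(
        layers, tuple(new_edges), rewire_p=float(p), rewire_mode=mode
    )


def glorot_bound(n1: int, n2: int) -> float:
    """Half-width sqrt(6/(n1+n2)) of the Glorot uniform range for a layer pair."""
    if n1 < 1 or n2 < 1:
        raise ValueError("layer widths must be positive")
    return float(np.sqrt(6.0 / (n1 + n2)))


def skip_init_bound(layers: LayerSpec | Sequence[int], divisor: str = "layers") -> float:
    """Uniform half-width for layer-skipping connection weights.

    The sum of the Glorot bounds of the adjacent layer pairs divided by the
    number of layers N (default).  ``divisor="pairs"`` divides by N-1
    instead, giving the plain mean over pairs.
    """
    if not isinstance(layers, LayerSpec):
        layers = LayerSpec(tuple(layers))
    sizes = layers.sizes
    total = sum(glorot_bound(sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1))
    if divisor == "layers":
        return total / len(sizes)
    if divisor == "pairs":
        return total / (len(sizes) - 1)
    raise ValueError(f"unknown divisor convention {divisor!r}")


@dataclass
class Parameters:
    """Symmetric weight matrix and bias vector of a Hopfield network.

    ``W`` is dense ``n x n``, exactly symmetric, zero on the diagonal and
    zero wherever the topology mask is false; ``b`` has length ``n`` with
    input-neuron entries fixed at zero (inputs are clamped, their biases are
    untrainable).
    """

    W: np.ndarray
    b: np.ndarray
    topology_checksum: str | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = self.b.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("W must be square and match b's length")

    def copy(self) -> "Parameters":
        return Parameters(self.W.copy(), self.b.copy(), self.topology_checksum)

    def validate(self, topology: TopologyGraph) -> None:
        if not np.array_equal(self.W, self.W.T):
            raise ValueError("W is not symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W has nonzero diagonal entries")
        if np.any(self.W[~topology.mask] != 0):
            off = ~topology.mask
            np.fill_diagonal(off, False)
            if np.any(self.W[off] != 0):
                raise ValueError("W has weight off the topology mask")


def initialize_parameters(
    topology: TopologyGraph, rng: np.random.Generator
) -> Parameters:
    """Glorot-uniform interlayer weights, uniform skip weights, zero biases.

    Each interlayer edge between layers of widths ``n_a`` and ``n_b`` draws
    from ``U[-sqrt(6/(n_a+n_b)), +sqrt(6/(n_a+n_b))]``; every skip edge draws
    from ``U[-a, a]`` with ``a = skip_init_bound(layers)``.  Draws happen in
    canonical edge order so a fixed seed reproduces parameters exactly.
    """
    layers = topology.layers
    n = layers.n
    W = np.zeros((n, n))
    a_skip = skip_init_bound(layers)
    for e in topology.edges:
        if e.is_skip:
            bound = a_skip
        else:
            bound = glorot_bound(
                layers.sizes[e.layer_i - 1], layers.sizes[e.layer_j - 1]
            )
        w = rng.uniform(-bound, bound)
        W[e.i, e.j] = w
        W[e.j, e.i] = w
    b = np.zeros(n)
    return Parameters(W, b, topology_checksum=topology.checksum)


def save_parameters(params: Parameters, path: str | Path) -> None:
    """Write ``W``, ``b`` and the topology checksum to an ``.npz`` archive."""
    np.savez(
        path,
        W=params.W,
        b=params.b,
        topology_checksum=np.array(params.topology_checksum or "", dtype="U64"),
    )


def load_parameters(path: str | Path) -> Parameters:
    with np.load(path) as data:
        checksum = str(data["topology_checksum"]) or None
        return Parameters(data["W"], data["b"], checksum)
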