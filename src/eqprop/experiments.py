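"""Reproducible experiment driver: one config wires topology -> training -> metrics.

An :class:`ExperimentConfig` fully determines a run — layer sizes, topology
kind and rewiring probability, all hyperparameters, the dataset, two seeds
(one for topology generation and weight init, one for training), and the
convention switches.  ``run_experiment`` executes it and, when given an
output directory, archives the config verbatim beside the metric CSVs so
any archived run re-executes bit-identically.

``sweep_p`` repeats a run over a list of rewiring probabilities (and
several derived seeds per probability), recording final train/test error
and the run-averaged log-spread for each — the protocol behind the
"log-spread shrinks as p grows" trend.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import data as _data
from .topology import (
    LayerSpec,
    Parameters,
    TopologyGraph,
    build_mlff,
    initialize_parameters,
    rewire_small_world,
)
from .training import Hyperparameters, TrainingLog, fit

__all__ = ["ExperimentConfig", "build_topology", "build_network",
           "load_dataset", "run_experiment", "sweep_p", "RunResult",
           "TOY_BENCHMARKS", "run_toy_benchmark"]


@dataclass
class ExperimentConfig:
    sizes: Sequence[int] = (8, 20, 20, 20, 4)
    topology: str = "mlff"  # "mlff" | "sw"
    p: float = 0.0
    alpha: Union[float, Sequence[float]] = 0.02
    beta_magnitude: float = 1.0
    eps: float = 0.5
    n_free: int = 500
    n_clamped: int = 8
    batch_size: int = 20
    epochs: int = 1
    randomize_beta_sign: bool = True
    dataset: dict = field(
        default_factory=lambda: {
            "kind": "synthetic",
            "classes": 4,
            "dim": 8,
            "n_per_class": 50,
            "separation": 1.0,
            "noise_sd": 0.05,
            "seed": 0,
        }
    )
    topology_seed: int = 0
    training_seed: int = 0
    rewire_mode: str = "single"
    allow_output_skips: bool = True
    bias_on_rho: bool = True
    clip_states: bool = True
    track_correction_matrix: bool = False

    def hyperparameters(self) -> Hyperparameters:
        return Hyperparameters(
            alpha=self.alpha,
            beta_magnitude=self.beta_magnitude,
            eps=self.eps,
            n_free=self.n_free,
            n_clamped=self.n_clamped,
            batch_size=self.batch_size,
            epochs=self.epochs,
            randomize_beta_sign=self.randomize_beta_sign,
            bias_on_rho=self.bias_on_rho,
            clip_states=self.clip_states,
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sizes"] = list(d["sizes"])
        if not np.isscalar(d["alpha"]):
            d["alpha"] = list(d["alpha"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def build_topology(config: ExperimentConfig) -> TopologyGraph:
    """Build the configured topology using the topology seed."""
    mlff = build_mlff(LayerSpec(tuple(config.sizes)))
    if config.topology == "mlff":
        return mlff
    if config.topology == "sw":
        return rewire_small_world(
            mlff,
            config.p,
            _rng(config.topology_seed),
            mode=config.rewire_mode,
            allow_output_skips=config.allow_output_skips,
        )
    raise ValueError(f"unknown topology kind {config.topology!r}")


def build_network(config: ExperimentConfig) -> tuple[TopologyGraph, Parameters]:
    """Topology plus initialized parameters.

    Rewiring and weight initialization draw from two independent streams
    derived from the topology seed, so an SW network generated with p = 0
    starts with exactly the same weights as the MLFF network from the same
    seed, and rewiring draws never shift the initialization.
    """
    rng_rewire = np.random.default_rng([config.topology_seed, 0])
    rng_init = np.random.default_rng([config.topology_seed, 1])
    mlff = build_mlff(LayerSpec(tuple(config.sizes)))
    if config.topology == "sw":
        topology = rewire_small_world(
            mlff, config.p, rng_rewire,
            mode=config.rewire_mode,
            allow_output_skips=config.allow_output_skips,
        )
    elif config.topology == "mlff":
        topology = mlff
    else:
        raise ValueError(f"unknown topology kind {config.topology!r}")
    params = initialize_parameters(topology, rng_init)
    return topology, params


def load_dataset(config: ExperimentConfig) -> _data.Dataset:
    spec = dict(config.dataset)
    kind = spec.pop("kind")
    if kind == "synthetic":
        return _data.make_synthetic(**spec)
    if kind == "csv":
        return _data.load_csv(**spec)
    if kind == "sklearn":
        return _data.load_sklearn_toy(**spec)
    raise ValueError(f"unknown dataset kind {kind!r}")


@dataclass
class RunResult:
    config: ExperimentConfig
    topology: TopologyGraph
    log: TrainingLog

    @property
    def final_train_error(self) -> float:
        return float(self.log.epoch_log["train_error"].iloc[-1])

    @property
    def final_test_error(self) -> float:
        return float(self.log.epoch_log["test_error"].iloc[-1])

    @property
    def log_spread(self) -> float:
        return self.log.log_spread


def run_experiment(
    config: ExperimentConfig, outdir: Optional[Union[str, Path]] = None
) -> RunResult:
    """Execute a full configured run; optionally archive it to ``outdir``."""
    topology, params = build_network(config)
    dataset = load_dataset(config)
    if dataset.n_features != topology.layers.n_input:
        raise ValueError(
            f"dataset has {dataset.n_features} features but the input layer "
            f"has {topology.layers.n_input} neurons"
        )
    if dataset.n_outputs != topology.layers.n_output:
        raise ValueError(
            f"dataset has {dataset.n_outputs} targets but the output layer "
            f"has {topology.layers.n_output} neurons"
        )
    log = fit(
        params,
        topology,
        dataset,
        config.hyperparameters(),
        _rng(config.training_seed),
        track_correction_matrix=config.track_correction_matrix,
    )
    result = RunResult(config, topology, log)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        topology.save(outdir / "topology.txt")
        log.save(outdir)
    return result


#: Benchmark configurations for the bundled scikit-learn toy tasks:
#: architecture, learning rate and per-phase iteration counts per task
#: (shallow: 5 hidden layers at 1000/12; deep: 8 hidden layers at 5000/18).
TOY_BENCHMARKS = {
    "diabetes": dict(
        dataset="diabetes", sizes=(10, 10, 10, 10, 10, 10, 1),
        alpha=0.01, n_free=1000, n_clamped=12,
    ),
    "wine": dict(
        dataset="wine", sizes=(13, 10, 10, 10, 10, 10, 3),
        alpha=0.01, n_free=1000, n_clamped=12,
    ),
    "diabetes_deep": dict(
        dataset="diabetes", sizes=(10,) * 9 + (1,),
        alpha=0.01, n_free=5000, n_clamped=18,
    ),
    "wine_deep": dict(
        dataset="wine", sizes=(13,) + (10,) * 8 + (3,),
        alpha=0.01, n_free=5000, n_clamped=18,
    ),
}


def run_toy_benchmark(
    name: str,
    topology: str,
    p: float = 0.1,
    n_runs: int = 3,
    base_seed: int = 0,
    epochs: int = 100,
    max_attempts: int = 10,
) -> pd.DataFrame:
    """Train on a bundled toy task over several seeds; report per-run stats.

    Runs the configuration in :data:`TOY_BENCHMARKS` under ``name`` with
    MLFF or SW (probability ``p``) connectivity, over seed pairs derived
    from ``base_seed``, until ``n_runs`` *non-degenerate* runs complete (or
    ``max_attempts`` seeds are exhausted).  A degenerate run is one whose
    network never trains — some layer pair's RMS correction stays at
    floating-point dust because the output saturated beyond the clamping
    factor's reach (see :attr:`TrainingLog.is_degenerate`); its log-spread
    measures noise, not gradient attenuation, so it is recorded but
    excluded from the returned table.  The number skipped is available as
    ``table.attrs["n_degenerate"]``.
    """
    if name not in TOY_BENCHMARKS:
        raise ValueError(f"unknown benchmark {name!r}; pick from {sorted(TOY_BENCHMARKS)}")
    bench = TOY_BENCHMARKS[name]
    rows = []
    n_degenerate = 0
    for attempt in range(max_attempts):
        if len(rows) >= n_runs:
            break
        cfg = ExperimentConfig(
            sizes=bench["sizes"],
            topology=topology,
            p=p if topology == "sw" else 0.0,
            alpha=bench["alpha"],
            beta_magnitude=1.0,
            eps=0.5,
            n_free=bench["n_free"],
            n_clamped=bench["n_clamped"],
            batch_size=20,
            epochs=epochs,
            dataset={"kind": "sklearn", "name": bench["dataset"], "seed": 0},
            topology_seed=derived_seed(base_seed, attempt, 0),
            training_seed=derived_seed(base_seed, attempt, 1),
        )
        res = run_experiment(cfg)
        if res.log.is_degenerate:
            n_degenerate += 1
            continue
        rows.append(
            {
                "attempt": attempt,
                "topology_seed": cfg.topology_seed,
                "log_spread": res.log_spread,
                "train_error": res.final_train_error,
                "test_error": res.final_test_error,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["n_degenerate"] = n_degenerate
    table.attrs["benchmark"] = name
    table.attrs["topology"] = topology
    return table


def derived_seed(base: int, *streams: int) -> int:
    """Deterministic sub-seed below 2^31 for sweep branches."""
    ss = np.random.SeedSequence([base, *streams])
    return int(ss.generate_state(1)[0] % (2**31))


def sweep_p(
    config: ExperimentConfig,
    p_values: Sequence[float],
    n_seeds: int = 1,
) -> pd.DataFrame:
    """Train an SW network for each rewiring probability in ``p_values``.

    For each p and seed index a fresh (topology, training) seed pair is
    derived deterministically from the config's base seeds.  Returns one
    row per (p, seed) with final train/test error and the run log-spread.
    """
    p_values = list(p_values)
    if not p_values:
        raise ValueError("empty p list")
    rows = []
    for pi, p in enumerate(p_values):
        for s in range(n_seeds):
            cfg = replace(
                config,
                topology="sw",
                p=float(p),
                topology_seed=derived_seed(config.topology_seed, pi, s, 0),
                training_seed=derived_seed(config.training_seed, pi, s, 1),
            )
            res = run_experiment(cfg)
            rows.append(
                {
                    "p": float(p),
                    "seed_index": s,
                    "train_error": res.final_train_error,
                    "test_error": res.final_test_error,
                    "log_spread": res.log_spread,
                    "n_skip_edges": len(res.topology.skip_edges),
                }
            )
    return pd.DataFrame(rows)
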