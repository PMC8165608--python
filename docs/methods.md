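# Methods

## Model

The network is a continuous Hopfield network: `n` neurons with activations
`u ∈ ℝⁿ`, symmetric weights `W = Wᵀ` (zero diagonal, masked to a topology),
biases `b`, and hard-sigmoid nonlinearity `ρ(x) = min(max(x, 0), 1)` whose
derivative is defined to be 1 on the *closed* interval `[0, 1]` so units
sitting exactly on a corner still pass gradient. Neurons are partitioned
into an input block `x` (clamped to the data) and free units `s = (h, y)`.
The free units do gradient descent on the total energy

    F(u; β) = ½ uᵀu − ½ ρ(u)ᵀ W ρ(u) − bᵀρ(u) + β · ½‖y − y_d‖²,

integrated by forward Euler with step `ε` for a fixed number of
iterations. Equilibrium propagation contrasts two equilibria — free
(β = 0, state `u⁰`) and weakly clamped (small signed β, state `u^β`) — and
updates each parameter from purely local quantities:

    ΔW_ij = (1/β)(ρ(u_i^β)ρ(u_j^β) − ρ(u_i⁰)ρ(u_j⁰)),
    Δb_i  = (1/β)(ρ(u_i^β) − ρ(u_i⁰)).

In the β → 0 limit the batch-averaged `−ΔW` converges to the gradient of
the free-equilibrium cost with respect to the weights; the test suite
verifies this against central finite differences through the full
relaxation (cosine ≥ 0.95 on random small networks).

**Bias-term convention.** With the `−bᵀu` variant of the energy, Δb above
is not the exact parameter gradient of F; with `−bᵀρ(u)` it is. The
default is therefore `−bᵀρ(u)` (`bias_on_rho=True`), with the other
variant selectable. Inside `[0, 1]` — where clipped trajectories live —
the two coincide exactly.

## Topologies

* **MLFF**: all-to-all between adjacent layers, no intra-layer and no
  skipping connections.
* **SW**: every interlayer edge of an MLFF network is independently
  selected with probability `p` (visited in canonical order, one uniform
  draw each); a selected edge is removed and replaced one-for-one by a
  layer-skipping edge (endpoints ≥ 2 layers apart). Default `"single"`
  mode keeps the endpoint in the lower layer and draws the partner
  uniformly from all legal neurons (no self edges, no duplicates),
  mirroring single-endpoint Watts–Strogatz rewiring; `"free"` mode redraws
  both endpoints. If the legal skip pairs are exhausted (possible only in
  very small networks) the original edge is kept, so the edge count is
  conserved unconditionally. Skips may attach to input- and output-layer
  neurons by default; `allow_output_skips=False` forbids output-layer
  attachment.

**Initialization.** Interlayer weights are Glorot-uniform,
`U[±√(6/(n₁+n₂))]` per layer pair. Skip weights draw from `U[±a]` with
`a = (1/N) Σ_{i=1}^{N−1} √(6/(nᵢ+nᵢ₊₁))` for `N` layers, exactly as this
rule is usually stated (the sum has `N−1` terms but divides by `N`; a
`divisor="pairs"` variant divides by `N−1`). Biases start at zero — the
conventional companion of Glorot init; no bias scheme is prescribed by the
update rule itself. Topology generation/init and training consume two
independent seeded streams so a fixed starting network can be trained
under many training seeds, and an SW topology generated with `p = 0` is
bit-identical (serialized form, initial weights, training log) to the MLFF
network from the same seed.

## Numerical choices

* **State clipping**: after every Euler step free units are clipped to
  `[0, 1]`. This bounds the energy and keeps the trajectory in the hard
  sigmoid's linear region, where `ρ(u) = u`, `ρ'(u) = 1`, and a cheaper
  fused update applies (used automatically; the generic gradient path
  handles unclipped or out-of-range states, and the two are unit-tested to
  agree). Clipping can be disabled per run.
* **Fixed iteration counts**, not tolerance-based stopping; a diagnostic
  (`gradient_inf_norm`) reports how far from equilibrium a state is. At a
  *projected* equilibrium on the clipping boundary the unconstrained
  gradient need not vanish — only its interior components do.
* **Cold start**: a batch never seen before starts with all free units at
  0 (deterministic and inside the admissible box); thereafter *persistent
  particles* reuse the batch's previous free equilibrium, which is why a
  few hundred iterations per phase suffice.
* **β-sign randomization**: the sign of the clamping factor is redrawn
  uniformly per batch (a regularizer); the signed β is used consistently
  in the clamped-phase energy and in both update denominators. The ±β
  average cancels the O(β) bias of either sign alone (tested).
* **Error conventions**: training error is recorded on each batch from the
  free-phase outputs *before* that batch's update; test error is computed
  by cold-start free relaxation after each epoch. Early in training the
  training error can therefore exceed the test error. Batches are fixed
  consecutive slices (no reshuffling), keeping persistent-particle
  identity trivial. For 1-output regression tasks "error" means the mean
  squared error of the free-phase output; classification error is the
  argmax mismatch rate with ties broken toward the lowest index.
* **Per-layer learning rates** (MLFF only): rate `α_l` scales updates to
  weights between layers `l, l+1` and to the biases of layer `l+1`, so
  output biases train and (nonexistent) input biases do not.

## Diagnostics

For adjacent layer pair `l`, `w_l` is the RMS of the batch-averaged weight
corrections over that pair's edges (each undirected edge counted once),
aggregated per-batch → epoch mean → mean over epochs. The **log-spread**
is the population standard deviation of `{log₁₀ w_l}` over the adjacent
pairs only; skip edges form a separate series and are excluded (a sample
`ddof=1` variant is available). Log-spread 0 means perfectly even
training; large values are the scalar signature of the vanishing gradient.
It is invariant to common rescaling of the corrections, so it does not
depend on whether a global learning rate is folded in. A mean-|ΔW| matrix
accumulator provides the pixel-level view of the same attenuation.

## Synthetic task

`make_synthetic` emulates the structure the benchmark experiments need —
a bounded-feature, multi-class, linearly separable task: class means at
distinct random corners of `[0,1]^dim` (pulled toward the center by a
`separation` factor), isotropic Gaussian noise (`noise_sd`), clipping to
the unit box, balanced classes, stratified split, deterministic in its
arguments. Reference conditions used by the tests: 4 classes, dim 8, 50
examples/class, separation 1.0, noise 0.05, network 8-20-20-20-4, ε = 0.5,
|β| = 1, α = 0.02, 500 free / 8 clamped iterations, batch 20, 10 epochs —
iteration counts and rate mirroring the reference three-hidden-layer
configuration. What it does *not* emulate: correlated features, label
noise, class imbalance, or inputs living on a low-dimensional manifold
(images); passing on it demonstrates the mechanics and the topology
effect, not performance on real data.

## Toy benchmarks and degenerate runs

The 100-epoch benchmark configurations (diabetes 10-10-10-10-10-10-1
regression; wine 13-10-10-10-10-10-3 classification; |β| = 1, ε = 0.5,
α = 0.01, 1000/12 iterations, batch 20; deeper 5000/18 variants available
in `TOY_BENCHMARKS`) use min-max feature scaling to `[0, 1]` from a fixed
75/25 train split, and the diabetes target min-max scaled likewise — the
source experiments do not state their normalization or split, so
reproduction of the printed numbers is approximate by nature.

These narrow (width-10) layers give Glorot bounds of 0.55–0.74, a
strongly-coupled regime in which most units saturate. A known failure
mode follows: for some initializations the output unit's recurrent drive
at the first free equilibrium exceeds `1 + |β|` in magnitude, the clamped
phase cannot move the saturated output, both equilibria coincide, and
every correction is exactly zero forever — the network never trains and
its "log-spread" is floating-point dust. `TrainingLog.is_degenerate`
detects this (any per-pair RMS below 1e-8, four orders of magnitude below
any training run's values). The benchmark protocol
(`run_toy_benchmark`) therefore reports the first `n_runs` non-degenerate
seeds and counts the skipped ones: the log-spread is a statistic about
*how evenly a network trains*, which presupposes that it trains at all.
This bistability (train-or-dead) is a genuine property of equilibrium
propagation at these widths and |β|, and is the main caveat attached to
the toy-benchmark comparisons.

## Problem sizes

Default test and reproduction runs are desk-scale by design: the synthetic
task (200 examples) for the topology-effect claims, the two bundled toy
datasets at their printed architectures for the benchmark claims, and the
shallow (1000/12) benchmark rows for the default reproduction script; the
deep (5000/18) rows are supported by the same harness. Full image-scale
(MNIST/FMNIST via the IDX loader) runs are supported by the harness but
are not part of the default protocol.

## Known limitations

* Fixed-count Euler relaxation measures equilibria only approximately;
  persistent particles trade early-epoch accuracy for speed (training
  error is biased upward in the first epochs).
* The degenerate-run phenomenon above: no recovery mechanism is attempted
  (none is part of the training procedure being studied).
* Per-layer learning rates are deliberately restricted to MLFF networks;
  there is no canonical assignment of a "layer pair" rate to a skip edge.
* `log_spread` is undefined (raises, or NaN in a fit log) when a layer
  pair's corrections are identically zero.
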