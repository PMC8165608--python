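# eqprop

Equilibrium propagation on layered and small-world Hopfield networks, with
diagnostics for the vanishing gradient problem.

## The problem

Equilibrium propagation (EP) trains energy-based networks — prototypically
the continuous Hopfield network — using only locally available quantities:
each connection's update depends on nothing but the activations of its two
endpoint neurons at two equilibria. That locality makes EP attractive as a
biologically plausible learning rule and as a candidate for neuromorphic
hardware, where every neuron should run one circuit, not separate forward
and backward pathways. But on strictly layered networks EP suffers a
vanishing gradient: weight corrections attenuate multiplicatively with
distance from the output, so deep layers barely train unless each layer
pair is given its own hand-tuned learning rate. This package implements
EP training and the topological alternative: replacing a random fraction
`p` of the interlayer connections with random *layer-skipping* connections
(a small-world-style rewiring), which shortens the path from deep neurons
to the output and lets a single global learning rate train all layers more
evenly.

## The model

States `u` of `n` neurons (clamped input block `x`, free units
`s = (h, y)`) relax by forward Euler on the total energy

```
F(u; β) = ½uᵀu − ½ρ(u)ᵀWρ(u) − bᵀρ(u) + β·½‖y − y_d‖²
```

with hard sigmoid `ρ`, symmetric masked `W`, and clamping factor `β`
(0 in the free phase, small and signed in the weakly-clamped phase).
Contrasting the two equilibria `u⁰`, `u^β` gives the local updates

```
ΔW_ij = (1/β)(ρ(u_i^β)ρ(u_j^β) − ρ(u_i⁰)ρ(u_j⁰)),   Δb_i = (1/β)(ρ(u_i^β) − ρ(u_i⁰))
```

whose batch average approaches the true cost gradient as β → 0.

The diagnostics: `w_l`, the RMS correction to the weights between layers
`l` and `l+1` (averaged per epoch, then over the run), and the
**log-spread** `std{log₁₀ w_l}` — zero when every layer trains equally,
large under a vanishing gradient. See `docs/methods.md` for conventions
and numerical details.

## Worked example

`python examples/02_train_synthetic.py` trains an 8-20-20-20-4 network on
a synthetic 4-class task (Gaussian clusters at hypercube corners) for 10
epochs with a single global learning rate, under both topologies:

```
mlff  train=0.355 test=0.354  w_l=[0.00151 0.00463 0.01599 0.05465]  log_spread=0.583
sw    train=0.250 test=0.500  w_l=[0.00491 0.0065  0.01414 0.05519]  log_spread=0.407
```

Reading the numbers: for the strictly layered network (`mlff`) the RMS
corrections `w_l` fall by a factor of ~36 from the output-side pair to the
input-side pair — the vanishing gradient. With 10% of connections rewired
into layer-skips (`sw`), the deepest pair trains ~3× faster, and the
log-spread (the spread of those four values in log10) drops from 0.58 to
0.41. Other examples: `01` (closed-form fixed-point checks), `03` (the
log-spread vs `p` sweep), `04` (diabetes/wine benchmarks).

The same experiments are scriptable from a shell:

```
eqprop train --config cfg.yaml --out runs/demo
eqprop sweep-p --config cfg.yaml --p-values 0 0.1 0.2 --out sweep.csv
```

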