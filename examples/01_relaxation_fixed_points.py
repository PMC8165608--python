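"""Relax a decoupled network to its closed-form fixed points.

With all weights zero the free-phase equilibrium of every free unit is its
bias, and a weakly-clamped output settles at (b + beta*y_d)/(1 + beta) —
two values the forward-Euler relaxation should hit to high precision.
"""
import numpy as np

from eqprop import LayerSpec, NetworkState, Parameters, RelaxationConfig, relax

spec = LayerSpec((2, 3, 1))
b = np.array([0.0, 0.0, 0.2, 0.5, 0.8, 0.4])
params = Parameters(np.zeros((6, 6)), b)

state = NetworkState.cold_start(spec, np.array([0.3, 0.7]))
free = relax(state, params, RelaxationConfig(eps=0.5, n_iterations=100, beta=0.0))
print("free-phase equilibrium s =", free.s, "(expected: the biases", b[2:], ")")

beta, y_d = 1.0, np.array([1.0])
clamped = relax(free, params, RelaxationConfig(0.5, 100, beta), y_d=y_d)
print(
    "weakly-clamped output y =", clamped.y,
    "(expected (b + beta*y_d)/(1+beta) =", (b[-1:] + beta * y_d) / (1 + beta), ")",
)
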