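"""Benchmark both topologies on the bundled scikit-learn toy tasks.

Runs the diabetes (regression, 10-10-10-10-10-10-1) and wine
(classification, 13-10-10-10-10-10-3) configurations for both MLFF and
SW(p=0.1) over three non-degenerate seeds each.  Uses fewer epochs than the
full 100-epoch benchmark so the example finishes quickly; run with
--full for the complete protocol.
"""
import sys

from eqprop.experiments import run_toy_benchmark

epochs = 100 if "--full" in sys.argv else 20
for name in ("diabetes", "wine"):
    for topology in ("mlff", "sw"):
        t = run_toy_benchmark(name, topology, base_seed=1, n_runs=3,
                              epochs=epochs)
        print(
            f"{name:9s} {topology:4s}  log_spread={t.log_spread.mean():.3f}  "
            f"train={t.train_error.mean():.4f}  test={t.test_error.mean():.4f}  "
            f"(skipped {t.attrs['n_degenerate']} degenerate seed(s))"
        )
print("log_spread: std dev of log10 per-layer-pair RMS corrections —")
print("smaller for SW means layer-skipping connections train depth more evenly.")
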