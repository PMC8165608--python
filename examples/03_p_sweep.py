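"""Sweep the rewiring probability p and watch the log-spread shrink.

For each p, a fresh SW topology is generated and trained on the synthetic
task; the table reports final errors and the run-averaged log-spread.  The
Spearman correlation between p and mean log-spread is negative: more
layer-skipping connections mean more even training across depth.
"""
from scipy import stats

from eqprop import ExperimentConfig, sweep_p

cfg = ExperimentConfig(
    sizes=(8, 20, 20, 20, 4),
    alpha=0.02,
    n_free=500,
    n_clamped=8,
    epochs=10,
    dataset={"kind": "synthetic", "classes": 4, "dim": 8, "n_per_class": 50,
             "separation": 1.0, "noise_sd": 0.05, "seed": 0},
)
table = sweep_p(cfg, [0.0, 0.05, 0.1, 0.2, 0.4], n_seeds=3)
summary = table.groupby("p")[["log_spread", "train_error", "test_error"]].mean()
print(summary)
rho = stats.spearmanr(summary.index.to_numpy(),
                      summary["log_spread"].to_numpy()).statistic
print(f"Spearman rho(p, mean log-spread) = {rho:.3f}  (negative = mitigation)")
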