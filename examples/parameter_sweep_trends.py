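"""A reduced parameter sweep and the trend classification it supports.

Sweeps the avoidance-inheritance fidelity Pa across its full range for
the two-step model at intermediate Pn, then classifies the trend of mean
modularity along Pa with a Spearman rank correlation (|rho| >= 0.7 ->
increasing/decreasing, otherwise flat).  This is the reduced-scale
version of the headline result: avoidances inherited from the mother's
social environment make association networks more modular.
"""

import numpy as np

from avoidnet import ExperimentGrid, ModelParams, run_experiment, summarize, trend_report

grid = ExperimentGrid(
    pa_values=tuple(np.round(np.arange(0.0, 0.81, 0.1), 10)),
    pn_values=(0.4,), pr_values=(0.01,),
    variants=("two_step",), replicates=10, base_seed=11,
)
summary = summarize(run_experiment(grid, ModelParams(n=50, timesteps=300)))

print("mean final-step modularity by Pa (two-step, Pn=0.4, Pr=0.01):")
for _, row in summary.iterrows():
    print(f"  Pa={row['pa']:.1f}  modularity {row['modularity_mean']:.3f} "
          f"(sd {row['modularity_sd']:.3f})")

report = trend_report(summary, "modularity", along="pa")
row = report.iloc[0]
print(f"\ntrend along Pa: {row['trend']} (Spearman rho = {row['rho']:.2f})")
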