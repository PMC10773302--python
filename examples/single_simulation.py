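"""Run one replicate of the one-step (maternal inheritance) model.

A population of 50 individuals turns over for 1000 birth-death steps;
each newborn copies its mother's associates and avoidances with
fidelities Pn and Pa and forms rare random ties with probability Pr.
The printed metrics describe the association network (avoidances
removed) at the start and the end of the run.
"""

from avoidnet import ModelParams, run_simulation

params = ModelParams(n=50, timesteps=1000, pn=0.5, pa=0.5, pr=0.01,
                     variant="one_step")
trace = run_simulation(params, seed=1, record="all")

first, last = trace.metrics.iloc[0], trace.metrics.iloc[-1]
for label, row in (("initial", first), ("final", last)):
    print(
        f"{label:7s} step {int(row['step']):4d}: "
        f"{int(row['n_associations']):3d} associations, "
        f"{int(row['n_avoidances']):3d} avoidances, "
        f"density {row['density']:.3f}, "
        f"clustering {row['weak_transitivity']:.3f}, "
        f"modularity {row['modularity']:.3f} "
        f"({int(row['n_communities'])} communities)"
    )

# The initial random network is unstructured (modularity near the random
# baseline); after 1000 steps of social inheritance the association
# network is sparser, much more clustered and strongly modular.
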