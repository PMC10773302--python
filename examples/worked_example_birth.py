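"""A single birth, step by step, on the canonical worked-example network.

The mother (slot 0) has two associates (I1, I2), two avoidances (I3, I4)
and two strangers (I5, I6).  Under one-step inheritance with Pn = 1,
Pa = 0.5 and Pr = 0.25 the offspring surely copies both associates, each
avoidance with a coin flip, and gambles on ties to the strangers.  The
two-step network adds I7 (an associate of both I1 and I2), avoidance
ties I1-I5 and I2-I6, and the fully neutral I8.
"""

import numpy as np

from avoidnet import ModelParams, add_offspring, make_fixture

LABELS1 = ["M", "I1", "I2", "I3", "I4", "I5", "I6", "O"]
LABELS2 = ["M", "I1", "I2", "I3", "I4", "I5", "I6", "I7", "I8", "O"]


def describe(row, labels):
    assoc = [labels[i] for i, s in enumerate(row) if s == 1]
    avoid = [labels[i] for i, s in enumerate(row) if s == -1]
    return f"associates {assoc}, avoidances {avoid}"


net = make_fixture("one_step_worked_example")
params = ModelParams(n=7, timesteps=0, pn=1.0, pa=0.5, pr=0.25)
grown, slot = add_offspring(net, mother=0, params=params,
                            rng=np.random.default_rng(58))
print("one-step offspring:", describe(grown.matrix[slot], LABELS1))

net2 = make_fixture("two_step_worked_example")
params2 = ModelParams(n=9, timesteps=0, pn=1.0, pa=0.5, pr=0.25,
                      variant="two_step")
grown2, slot2 = add_offspring(net2, mother=0, params=params2,
                              rng=np.random.default_rng(103))
print("two-step offspring:", describe(grown2.matrix[slot2], LABELS2))
print()
print("two-step relationship matrix (rows/cols:", " ".join(LABELS2) + "):")
print(grown2.matrix)

# Seeds 58 and 103 realize the illustrative outcomes: the one-step
# offspring inherits I1 and I2, avoids I3 (but not I4) and forms a new
# association with I5 and a new avoidance with I6; the two-step offspring
# additionally adopts its associates' shared associate I7, one of their
# avoidances (I5), and a random association with the neutral I8.
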