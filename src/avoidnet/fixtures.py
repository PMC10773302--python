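"""Small deterministic networks for tests, worked examples and demos.

The two worked-example fixtures reproduce the canonical single-birth
configurations used to illustrate the inheritance mechanisms: a mother with
two associates, two avoidances and two strangers (one-step), extended with
her associates' own associates and avoidances plus a fully neutral
individual (two-step).
"""

from __future__ import annotations

import numpy as np

from .network import SignedNetwork, init_random_network

__all__ = ["FIXTURE_KINDS", "make_fixture", "ONE_STEP_ROLES", "TWO_STEP_ROLES"]

FIXTURE_KINDS = (
    "one_step_worked_example",
    "two_step_worked_example",
    "balanced_factions",
    "random_small",
)

# slot meanings in the worked-example fixtures (slot 0 is the mother)
ONE_STEP_ROLES = {
    "mother": 0,
    "associates": (1, 2),     # I1, I2
    "avoidances": (3, 4),     # I3, I4
    "strangers": (5, 6),      # I5, I6
}
TWO_STEP_ROLES = {
    **ONE_STEP_ROLES,
    "associates_associate": 7,   # I7: associates with both I1 and I2
    "associates_avoidances": (5, 6),  # I5 avoided by I1, I6 avoided by I2
    "neutral": 8,                # I8: no tie to mother, I1 or I2
}


def _symmetric(n: int, ties: dict[tuple[int, int], int]) -> SignedNetwork:
    m = np.zeros((n, n), dtype=np.int8)
    for (i, j), s in ties.items():
        m[i, j] = s
        m[j, i] = s
    return SignedNetwork(m)


def make_fixture(kind: str, seed: int = 0) -> SignedNetwork:
    """Build one of the named deterministic fixtures.

    ``one_step_worked_example``
        7 individuals: mother (slot 0) with associates I1, I2, avoidances
        I3, I4 and strangers I5, I6.
    ``two_step_worked_example``
        9 individuals: the one-step configuration plus I7 (an associate of
        both I1 and I2, hence a potential associate for the offspring),
        avoidance ties I1-I5 and I2-I6 (making I5 and I6 potential
        avoidances), and I8 with no tie to the mother or her associates
        (neutral).
    ``balanced_factions``
        8 individuals in two factions of four: all within-faction pairs
        associate, all between-faction pairs avoid.  Every complete triad
        is structurally balanced (+++ or +--).
    ``random_small``
        8-individual random signed network (p_assoc = p_avoid = 0.2) drawn
        from ``seed``.
    """
    if kind == "one_step_worked_example":
        return _symmetric(7, {(0, 1): 1, (0, 2): 1, (0, 3): -1, (0, 4): -1})
    if kind == "two_step_worked_example":
        return _symmetric(
            9,
            {
                (0, 1): 1, (0, 2): 1,        # mother's associates
                (0, 3): -1, (0, 4): -1,      # mother's avoidances
                (1, 7): 1, (2, 7): 1,        # I7: associates' associate
                (1, 5): -1, (2, 6): -1,      # I5, I6: associates' avoidances
            },
        )
    if kind == "balanced_factions":
        ties = {}
        factions = (range(0, 4), range(4, 8))
        for f in factions:
            for i in f:
                for j in f:
                    if i < j:
                        ties[(i, j)] = 1
        for i in factions[0]:
            for j in factions[1]:
                ties[(i, j)] = -1
        return _symmetric(8, ties)
    if kind == "random_small":
        return init_random_network(8, 0.2, 0.2, np.random.default_rng(seed))
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
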