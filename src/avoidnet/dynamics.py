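"""Birth-death population turnover with social inheritance of signed ties.

At every time step one uniformly sampled individual dies and one uniformly
sampled survivor (the mother) produces a single offspring, keeping the
population size constant.  The newborn always associates with its mother and
acquires its remaining ties through one of three mechanisms:

``one_step``
    Vertical inheritance only.  The offspring copies each of the mother's
    associates with probability Pn and each of her avoidances with
    probability Pa; towards individuals unconnected to the mother it forms
    a random association or avoidance, each with probability Pr (and stays
    unconnected with probability 1 - 2 Pr).

``two_step``
    Vertical then horizontal inheritance.  Step one copies the mother's
    associates and avoidances as above (no random ties yet).  Step two
    classifies every individual still untied to the offspring against the
    offspring's associate set (mother included): a *potential associate*
    has more positive than negative ties to that set and is adopted with
    probability Pn; a *potential avoidance* has at least as many negative
    as positive ties (and at least one nonzero tie) and is adopted with
    probability Pa; a *neutral* individual has no tie to the set and forms
    a random tie exactly as under Pr.  Classifications are computed once
    from a snapshot of the post-step-one state, so step-two adoptions do
    not feed back into each other.

``random_associates``
    Control variant with no maternal inheritance: the offspring's
    associates are drawn independently at random (matched in expectation
    to the mother's associate degree), after which avoidances are adopted
    from that associate set via the potential-avoidance rule with
    probability Pa.  No Pr random ties are formed.

All randomness flows through a single ``numpy`` Generator in a fixed,
documented order (death, mother, then tie draws in ascending slot order),
making every simulation a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .network import (
    ASSOCIATION,
    AVOIDANCE,
    MetricsRecord,
    SignedNetwork,
    init_random_network,
    structural_metrics,
)

__all__ = [
    "VARIANTS",
    "ModelParams",
    "StepEvent",
    "SimulationTrace",
    "tie_probabilities",
    "classify_candidate",
    "inherit_one_step",
    "inherit_two_step",
    "inherit_random_associates",
    "add_offspring",
    "birth_death_step",
    "run_simulation",
]

VARIANTS = ("one_step", "two_step", "random_associates")
CLASSIFICATION_RULES = ("count", "fraction")

Variant = Literal["one_step", "two_step", "random_associates"]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the social-inheritance model.

    Attributes
    ----------
    pn, pa
        Fidelity of inheriting an associate / an avoidance, in [0, 1].
    pr
        Probability of forming each sign of random new tie towards an
        eligible unconnected individual; the stay-null probability is
        1 - 2*pr, so pr must lie in [0, 0.5].
    n
        Population size (constant through time).
    timesteps
        Number of birth-death steps.
    variant
        Inheritance mechanism; one of ``one_step``, ``two_step``,
        ``random_associates``.
    p_assoc_init, p_avoid_init
        Pair-wise probabilities used to draw the initial random network.
    classification_rule
        ``"count"`` (default): compare positive vs negative tie counts, as
        in the worked example; ``"fraction"``: thresholds on the fraction
        of the offspring's associates (>50% positive for a potential
        associate, >=50% negative for a potential avoidance) -- under this
        rule individuals with nonzero ties that clear neither threshold
        form no tie at all.
    walktrap_steps
        Random-walk length for community detection when recording metrics.
    random_assoc_prob
        Per-individual associate probability for the ``random_associates``
        variant; ``None`` matches the mother's associate degree in
        expectation (degree / (n - 2)).
    """

    pn: float = 0.5
    pa: float = 0.5
    pr: float = 0.01
    n: int = 50
    timesteps: int = 1000
    variant: Variant = "one_step"
    p_assoc_init: float = 0.1
    p_avoid_init: float = 0.1
    classification_rule: str = "count"
    walktrap_steps: int = 4
    random_assoc_prob: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pn <= 1.0:
            raise ValueError(f"pn must be in [0, 1], got {self.pn}")
        if not 0.0 <= self.pa <= 1.0:
            raise ValueError(f"pa must be in [0, 1], got {self.pa}")
        if not 0.0 <= self.pr <= 0.5:
            raise ValueError(
                f"pr must be in [0, 0.5] (stay-null probability is 1-2*pr), got {self.pr}"
            )
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.timesteps < 0:
            raise ValueError(f"timesteps must be >= 0, got {self.timesteps}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.classification_rule not in CLASSIFICATION_RULES:
            raise ValueError(
                f"classification_rule must be one of {CLASSIFICATION_RULES}, "
                f"got {self.classification_rule!r}"
            )
        if self.p_assoc_init < 0 or self.p_avoid_init < 0 or (
            self.p_assoc_init + self.p_avoid_init > 1
        ):
            raise ValueError("invalid initialization probabilities")
        if self.random_assoc_prob is not None and not 0 <= self.random_assoc_prob <= 1:
            raise ValueError("random_assoc_prob must be in [0, 1]")

    def with_(self, **kwargs) -> "ModelParams":
        """Copy with some fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StepEvent:
    """What happened in one birth-death step (slots are matrix indices)."""

    dead_id: int
    mother_id: int
    newborn_id: int
    slot: int  # matrix slot freed by the death and taken by the newborn
    mother_slot: int


@dataclass
class SimulationTrace:
    """Result of one replicate.

    ``metrics`` has one row per recorded step (step 0 is the initial
    network); ``final`` is the end-state signed network with its
    individual-id ledger.
    """

    metrics: pd.DataFrame
    final: SignedNetwork
    params: ModelParams
    seed: object

    def __len__(self) -> int:
        return len(self.metrics)


def tie_probabilities(
    relation: int, params: ModelParams
) -> tuple[float, float, float]:
    """Outcome probabilities (P(+1), P(-1), P(0)) for a third party under
    one-step inheritance, given the mother's relation to that individual.

    The three probabilities sum to one in every row of the rule table.
    """
    if relation == ASSOCIATION:
        return (params.pn, 0.0, 1.0 - params.pn)
    if relation == AVOIDANCE:
        return (0.0, params.pa, 1.0 - params.pa)
    return (params.pr, params.pr, 1.0 - 2.0 * params.pr)


def classify_candidate(
    net: SignedNetwork,
    offspring_associates: Iterable[int],
    candidate: int,
    rule: str = "count",
) -> str:
    """Classify a potential new social partner for step-two inheritance.

    Returns one of ``"potential_associate"``, ``"potential_avoidance"``,
    ``"neutral"`` or ``"none"`` (the last only under the ``fraction`` rule,
    for individuals with nonzero ties clearing neither threshold).
    """
    assoc = np.fromiter(offspring_associates, dtype=int)
    row = net.matrix[candidate, assoc]
    p = int((row == ASSOCIATION).sum())
    q = int((row == AVOIDANCE).sum())
    return _classify(p, q, len(assoc), rule)


def _classify(p: int, q: int, n_assoc: int, rule: str) -> str:
    if p == 0 and q == 0:
        return "neutral"
    if rule == "count":
        return "potential_associate" if p > q else "potential_avoidance"
    if p > 0.5 * n_assoc:
        return "potential_associate"
    if q >= 0.5 * n_assoc:
        return "potential_avoidance"
    return "none"


def _draw_signed(
    out: np.ndarray,
    mask_assoc: np.ndarray,
    mask_avoid: np.ndarray,
    mask_neutral: np.ndarray,
    u: np.ndarray,
    params: ModelParams,
) -> None:
    """Fill `out` from one uniform draw per individual, in slot order."""
    out[mask_assoc & (u < params.pn)] = ASSOCIATION
    out[mask_avoid & (u < params.pa)] = AVOIDANCE
    out[mask_neutral & (u < params.pr)] = ASSOCIATION
    out[mask_neutral & (u >= params.pr) & (u < 2 * params.pr)] = AVOIDANCE


def inherit_one_step(
    matrix: np.ndarray,
    mother: int,
    slot: int,
    params: ModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Tie vector for a newborn under vertical (maternal) inheritance.

    ``slot`` is the newborn's matrix slot (the deceased individual's ties
    must already be cleared).  The returned vector covers every slot;
    entry ``mother`` is +1, entry ``slot`` is 0.
    """
    n = matrix.shape[0]
    row = matrix[mother]
    v = np.zeros(n, dtype=np.int8)
    third = np.ones(n, dtype=bool)
    third[[mother, slot]] = False
    u = rng.random(n)
    _draw_signed(
        v,
        third & (row == ASSOCIATION),
        third & (row == AVOIDANCE),
        third & (row == 0),
        u,
        params,
    )
    v[mother] = ASSOCIATION
    v[slot] = 0
    return v


def inherit_two_step(
    matrix: np.ndarray,
    mother: int,
    slot: int,
    params: ModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Tie vector under vertical-then-horizontal inheritance."""
    n = matrix.shape[0]
    row = matrix[mother]
    v = np.zeros(n, dtype=np.int8)
    third = np.ones(n, dtype=bool)
    third[[mother, slot]] = False

    # step one: maternal ties only, no random ties yet
    u1 = rng.random(n)
    v[third & (row == ASSOCIATION) & (u1 < params.pn)] = ASSOCIATION
    v[third & (row == AVOIDANCE) & (u1 < params.pa)] = AVOIDANCE
    v[mother] = ASSOCIATION

    # step two: snapshot classification against the current associate set
    assoc_set = np.flatnonzero(v == ASSOCIATION)  # mother included
    cand = np.flatnonzero(third & (v == 0))
    if cand.size:
        sub = matrix[np.ix_(cand, assoc_set)]
        p = (sub == ASSOCIATION).sum(axis=1)
        q = (sub == AVOIDANCE).sum(axis=1)
        u2 = rng.random(cand.size)
        if params.classification_rule == "count":
            pot_assoc = p > q
            pot_avoid = (q >= p) & (p + q > 0)
        else:
            na = assoc_set.size
            pot_assoc = p > 0.5 * na
            pot_avoid = (q >= 0.5 * na) & (q > 0) & ~pot_assoc
        neutral = (p == 0) & (q == 0)
        w = np.zeros(cand.size, dtype=np.int8)
        w[pot_assoc & (u2 < params.pn)] = ASSOCIATION
        w[pot_avoid & (u2 < params.pa)] = AVOIDANCE
        w[neutral & (u2 < params.pr)] = ASSOCIATION
        w[neutral & (u2 >= params.pr) & (u2 < 2 * params.pr)] = AVOIDANCE
        v[cand] = w
    v[slot] = 0
    return v


def inherit_random_associates(
    matrix: np.ndarray,
    mother: int,
    slot: int,
    params: ModelParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Tie vector under the no-maternal-inheritance control.

    Associates are drawn independently at random with a per-individual
    probability matching the mother's expected associate degree (or
    ``params.random_assoc_prob`` if set); avoidances are then adopted from
    this associate set with probability Pa via the potential-avoidance
    rule.  No Pr random ties are formed.
    """
    n = matrix.shape[0]
    third = np.ones(n, dtype=bool)
    third[[mother, slot]] = False
    if params.random_assoc_prob is not None:
        prob = params.random_assoc_prob
    else:
        deg = int((matrix[mother] == ASSOCIATION).sum())
        prob = deg / (n - 2) if n > 2 else 0.0
    v = np.zeros(n, dtype=np.int8)
    u1 = rng.random(n)
    v[third & (u1 < prob)] = ASSOCIATION
    # the mother is NOT part of the classification set: this variant has no
    # maternal inheritance, avoidances come only from the drawn associates
    assoc_set = np.flatnonzero(v == ASSOCIATION)
    v[mother] = ASSOCIATION
    cand = np.flatnonzero(third & (v == 0))
    if cand.size:
        sub = matrix[np.ix_(cand, assoc_set)]
        p = (sub == ASSOCIATION).sum(axis=1)
        q = (sub == AVOIDANCE).sum(axis=1)
        u2 = rng.random(cand.size)
        if params.classification_rule == "count":
            pot_avoid = (q >= p) & (p + q > 0)
        else:
            pot_avoid = (q >= 0.5 * assoc_set.size) & (q > 0) & ~(p > 0.5 * assoc_set.size)
        v[cand[pot_avoid & (u2 < params.pa)]] = AVOIDANCE
    v[slot] = 0
    return v


_INHERIT = {
    "one_step": inherit_one_step,
    "two_step": inherit_two_step,
    "random_associates": inherit_random_associates,
}


def add_offspring(
    net: SignedNetwork,
    mother: int,
    params: ModelParams,
    rng: np.random.Generator,
) -> tuple[SignedNetwork, int]:
    """Append a newborn of ``mother`` to the network (population grows by 1).

    Convenience for worked examples and single-birth studies; the
    birth-death process itself keeps the population constant by reusing
    the deceased individual's slot.  Returns the grown network and the
    newborn's slot index.
    """
    n = net.n
    grown = np.zeros((n + 1, n + 1), dtype=np.int8)
    grown[:n, :n] = net.matrix
    v = _INHERIT[params.variant](grown, mother, n, params, rng)
    grown[n, :] = v
    grown[:, n] = v
    ids = np.append(net.ids, net.ids.max() + 1)
    return SignedNetwork(grown, ids), n


def birth_death_step(
    net: SignedNetwork,
    params: ModelParams,
    rng: np.random.Generator,
    next_id: Optional[int] = None,
) -> StepEvent:
    """One time step: a uniformly sampled death, then a birth.

    Mutates ``net`` in place.  The deceased individual's ties are cleared
    before the mother (sampled uniformly from the survivors) is read, so a
    newborn can never hold a tie to a dead individual.  The newborn takes
    the freed matrix slot but receives a fresh id in the ledger, and
    always associates with its mother.
    """
    n = net.n
    if n < 2:
        raise ValueError("cannot step a population of fewer than 2 individuals")
    m = net.matrix
    dead = int(rng.integers(n))
    survivors = np.delete(np.arange(n), dead)
    mother = int(survivors[rng.integers(n - 1)])
    dead_id = int(net.ids[dead])
    m[dead, :] = 0
    m[:, dead] = 0
    v = _INHERIT[params.variant](m, mother, dead, params, rng)
    m[dead, :] = v
    m[:, dead] = v
    newborn_id = int(net.ids.max() + 1) if next_id is None else next_id
    net.ids[dead] = newborn_id
    return StepEvent(
        dead_id=dead_id,
        mother_id=int(net.ids[mother]),
        newborn_id=newborn_id,
        slot=dead,
        mother_slot=mother,
    )


def run_simulation(
    params: ModelParams,
    seed,
    record: str = "all",
    initial: Optional[SignedNetwork] = None,
) -> SimulationTrace:
    """Run one replicate of the birth-death inheritance process.

    Parameters
    ----------
    params
        Model parameters.
    seed
        Anything accepted by ``np.random.default_rng``; the whole replicate
        is a pure function of (params, seed).
    record
        ``"all"`` records a metrics row for the initial state (step 0) and
        after every step (trace length = timesteps + 1); ``"final"``
        records only the initial and last states, which is what the
        parameter sweep needs and is much faster.
    initial
        Optional starting network (must have ``params.n`` individuals);
        by default a random signed network is drawn from the
        initialization probabilities.
    """
    if record not in ("all", "final"):
        raise ValueError("record must be 'all' or 'final'")
    rng = np.random.default_rng(seed)
    if initial is None:
        net = init_random_network(
            params.n, params.p_assoc_init, params.p_avoid_init, rng
        )
    else:
        if initial.n != params.n:
            raise ValueError(
                f"initial network has {initial.n} individuals, params.n={params.n}"
            )
        net = initial.copy()

    rows: list[tuple] = []

    def _record(step: int) -> None:
        rows.append((step, *structural_metrics(net, params.walktrap_steps)))

    _record(0)
    for step in range(1, params.timesteps + 1):
        birth_death_step(net, params, rng)
        if record == "all" or step == params.timesteps:
            _record(step)

    metrics = pd.DataFrame(
        rows, columns=("step", *MetricsRecord._fields)
    )
    return SimulationTrace(metrics=metrics, final=net, params=params, seed=seed)
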