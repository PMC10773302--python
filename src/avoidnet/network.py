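"""Signed social networks and their structural metrics.

The central object is :class:`SignedNetwork`: a symmetric matrix over a fixed
set of individuals in which every unordered pair is in exactly one of three
states -- association (+1), avoidance (-1), or no relationship (0).  All
structure metrics (density, weak transitivity, walktrap modularity) are
computed on the *association subnetwork*: the binary graph obtained by
keeping +1 ties and discarding avoidances, which is how avoidances stay
"invisible" to standard network statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import igraph as ig
import numpy as np

__all__ = [
    "SignedNetwork",
    "MetricsRecord",
    "TriadCensus",
    "init_random_network",
    "association_subnetwork",
    "count_ties",
    "density",
    "weak_transitivity",
    "newman_modularity",
    "walktrap_communities",
    "signed_triad_census",
    "structural_metrics",
]

ASSOCIATION = 1
AVOIDANCE = -1
NULL = 0


@dataclass
class SignedNetwork:
    """Symmetric relationship matrix with entries in {-1, 0, +1}.

    Parameters
    ----------
    matrix
        ``(n, n)`` integer array; ``matrix[i, j]`` is the relationship
        between individuals in slots ``i`` and ``j``.  Must be symmetric
        with a zero diagonal.
    ids
        Persistent individual identity per matrix slot.  The simulator
        reuses matrix slots across generations but never reuses an id,
        so lineages can be tracked.  Defaults to ``0..n-1``.
    """

    matrix: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.ids is None:
            self.ids = np.arange(self.matrix.shape[0], dtype=np.int64)
        else:
            self.ids = np.asarray(self.ids, dtype=np.int64)
        self.validate()

    @property
    def n(self) -> int:
        """Number of individuals."""
        return self.matrix.shape[0]

    def relation(self, i: int, j: int) -> int:
        """Relationship between slots ``i`` and ``j`` (+1, -1 or 0)."""
        if i == j:
            raise ValueError("self-relations are undefined")
        return int(self.matrix[i, j])

    def copy(self) -> "SignedNetwork":
        return SignedNetwork(self.matrix.copy(), self.ids.copy())

    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"matrix must be square, got shape {m.shape}")
        if self.ids.shape != (m.shape[0],):
            raise ValueError("ids length must equal matrix dimension")
        if not np.array_equal(m, m.T):
            raise ValueError("relationship matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero (no self-ties)")
        if not np.isin(m, (-1, 0, 1)).all():
            raise ValueError("entries must be in {-1, 0, +1}")


class MetricsRecord(NamedTuple):
    """Per-network structure summary.

    ``weak_transitivity`` is NaN when the association subnetwork has no
    connected two-paths (the statistic is undefined there); aggregation
    drops NaNs with a reported count rather than coercing them to zero.
    """

    n_associations: int
    n_avoidances: int
    density: float
    weak_transitivity: float
    modularity: float
    n_communities: int


class TriadCensus(NamedTuple):
    """Counts of complete signed triads by sign pattern.

    Only triples whose three pairwise ties are all nonzero are counted.
    Under structural balance theory ``ppp`` (+++) and ``pmm`` (+--) are
    the stable classes; ``ppm`` (++-) and ``mmm`` (---) are unstable.
    """

    ppp: int
    ppm: int
    pmm: int
    mmm: int


def init_random_network(
    n: int,
    p_assoc: float,
    p_avoid: float,
    rng: np.random.Generator,
) -> SignedNetwork:
    """Draw a random signed network.

    Each unordered pair is independently assigned an association with
    probability ``p_assoc``, an avoidance with probability ``p_avoid``,
    and no relationship otherwise.

    Raises
    ------
    ValueError
        If ``n < 2`` or the probabilities are negative or sum above 1.
    """
    if n < 2:
        raise ValueError(f"need at least 2 individuals, got n={n}")
    if p_assoc < 0 or p_avoid < 0 or p_assoc + p_avoid > 1:
        raise ValueError(
            f"require p_assoc >= 0, p_avoid >= 0, p_assoc + p_avoid <= 1; "
            f"got ({p_assoc}, {p_avoid})"
        )
    u = rng.random((n, n))
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    m = np.zeros((n, n), dtype=np.int8)
    m[upper & (u < p_assoc)] = ASSOCIATION
    m[upper & (u >= p_assoc) & (u < p_assoc + p_avoid)] = AVOIDANCE
    m = m + m.T
    return SignedNetwork(m)


def association_subnetwork(net: SignedNetwork) -> SignedNetwork:
    """Binary network of associations: +1 kept as 1, everything else 0."""
    return SignedNetwork((net.matrix == ASSOCIATION).astype(np.int8), net.ids.copy())


def count_ties(net: SignedNetwork) -> tuple[int, int]:
    """Counts of (associations, avoidances) over unordered pairs."""
    upper = np.triu(net.matrix, k=1)
    return int((upper == ASSOCIATION).sum()), int((upper == AVOIDANCE).sum())


def density(net: SignedNetwork) -> float:
    """Fraction of pairs holding an association tie."""
    n_assoc, _ = count_ties(net)
    n = net.n
    return n_assoc / (n * (n - 1) / 2)


def _as_adjacency(net: "SignedNetwork | np.ndarray") -> np.ndarray:
    adj = net.matrix if isinstance(net, SignedNetwork) else np.asarray(net)
    if (adj < 0).any():
        adj = (adj == ASSOCIATION).astype(np.int8)
    return adj


def _to_igraph(adj: np.ndarray) -> ig.Graph:
    edges = np.argwhere(np.triu(adj, k=1) != 0)
    return ig.Graph(n=adj.shape[0], edges=edges.tolist())


def weak_transitivity(net: "SignedNetwork | np.ndarray") -> float:
    """Global clustering coefficient in its weak form.

    The probability that A and C are tied given that both are tied to B:
    3 x triangles / connected triples.  Returns NaN when the graph has no
    connected two-paths, where the ratio is undefined.
    """
    adj = _as_adjacency(net)
    return float(_to_igraph(adj).transitivity_undirected(mode="nan"))


def newman_modularity(
    adj: "SignedNetwork | np.ndarray", membership: Sequence[int]
) -> float:
    """Newman-Girvan modularity Q of a partition, computed from scratch.

    Q = sum_c [ e_c / m  -  (d_c / 2m)^2 ]  over communities c, where m is
    the total edge count, e_c the number of within-community edges and d_c
    the summed degree of community c.  An edgeless graph has Q = 0 by
    convention.  Kept independent of the graph library so the two can be
    cross-checked.
    """
    a = _as_adjacency(adj)
    membership = np.asarray(membership)
    deg = a.sum(axis=1).astype(float)
    two_m = deg.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for c in np.unique(membership):
        mask = membership == c
        e_c = a[np.ix_(mask, mask)].sum() / 2.0
        d_c = deg[mask].sum()
        q += e_c / (two_m / 2.0) - (d_c / two_m) ** 2
    return float(q)


def walktrap_communities(
    net: "SignedNetwork | np.ndarray", steps: int = 4
) -> tuple[list[int], float, int]:
    """Walktrap community detection on the association subnetwork.

    Random-walk agglomerative clustering cut at the maximum-modularity
    partition.  Returns ``(membership, modularity, n_communities)``.  For
    an edgeless network every node is its own community with Q = 0.

    Parameters
    ----------
    steps
        Random-walk length; 4 is the conventional default.
    """
    adj = _as_adjacency(net)
    n = adj.shape[0]
    g = _to_igraph(adj)
    if g.ecount() == 0:
        return list(range(n)), 0.0, n
    clustering = g.community_walktrap(steps=steps).as_clustering()
    membership = list(clustering.membership)
    q = newman_modularity(adj, membership)
    return membership, q, len(set(membership))


def signed_triad_census(net: SignedNetwork) -> TriadCensus:
    """Census of complete signed triads.

    Counts node triples whose three pairwise relationships are all
    nonzero, by sign pattern.  Computed with adjacency-matrix products:
    e.g. the number of +++ triads is tr(P^3)/6 for the +1 adjacency P,
    and a ++- triad is a -1 edge whose endpoints are joined by a +1
    two-path.
    """
    p = (net.matrix == ASSOCIATION).astype(np.int64)
    m = (net.matrix == AVOIDANCE).astype(np.int64)
    upper = np.triu(np.ones_like(p, dtype=bool), k=1)
    p2 = p @ p
    m2 = m @ m
    ppp = int(np.trace(p @ p2)) // 6
    mmm = int(np.trace(m @ m2)) // 6
    ppm = int(p2[upper & (m == 1)].sum())
    pmm = int(m2[upper & (p == 1)].sum())
    return TriadCensus(ppp=ppp, ppm=ppm, pmm=pmm, mmm=mmm)


def structural_metrics(net: SignedNetwork, walktrap_steps: int = 4) -> MetricsRecord:
    """All per-network summary statistics in one record.

    Tie counts are taken on the signed network; density, weak transitivity
    and walktrap modularity are computed on the association subnetwork.
    """
    n_assoc, n_avoid = count_ties(net)
    adj = (net.matrix == ASSOCIATION).astype(np.int8)
    n = net.n
    _, q, n_comm = walktrap_communities(adj, steps=walktrap_steps)
    return MetricsRecord(
        n_associations=n_assoc,
        n_avoidances=n_avoid,
        density=n_assoc / (n * (n - 1) / 2),
        weak_transitivity=weak_transitivity(adj),
        modularity=q,
        n_communities=n_comm,
    )
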