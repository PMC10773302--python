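"""Independent brute-force oracles used to cross-check the fast implementations.

Everything here enumerates node triples directly and is deliberately kept
free of the package's own metric code paths.
"""

from itertools import combinations
from math import nan

import numpy as np


def brute_force_weak_transitivity(adj: np.ndarray) -> float:
    """3 x triangles / connected triples by explicit triple enumeration."""
    n = adj.shape[0]
    closed = 0
    triples = 0
    for b in range(n):
        neighbours = [x for x in range(n) if x != b and adj[b, x]]
        for a, c in combinations(neighbours, 2):
            triples += 1
            closed += int(adj[a, c] != 0)
    if triples == 0:
        return nan
    return closed / triples


def brute_force_triad_census(matrix: np.ndarray) -> tuple[int, int, int, int]:
    """(+++, ++-, +--, ---) counts over all-nonzero triples."""
    n = matrix.shape[0]
    ppp = ppm = pmm = mmm = 0
    for a, b, c in combinations(range(n), 3):
        signs = (matrix[a, b], matrix[a, c], matrix[b, c])
        if 0 in signs:
            continue
        neg = sum(1 for s in signs if s == -1)
        if neg == 0:
            ppp += 1
        elif neg == 1:
            ppm += 1
        elif neg == 2:
            pmm += 1
        else:
            mmm += 1
    return ppp, ppm, pmm, mmm


def brute_force_modularity(adj: np.ndarray, membership) -> float:
    """Newman-Girvan Q summed edge by edge: (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta."""
    membership = np.asarray(membership)
    deg = adj.sum(axis=1).astype(float)
    two_m = deg.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += adj[i, j] - deg[i] * deg[j] / two_m
    return q / two_m
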