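"""Plain-text readers and writers for signed networks and traces.

Formats:

* signed edge list — three whitespace-separated columns ``id_i id_j sign``
  with one header line; only nonzero ties are listed (absent pairs are 0),
  each unordered pair once.
* dense matrix CSV — the full symmetric relationship matrix with ids as
  row/column labels, mirroring how a relationship matrix is tabulated.
* GraphML — association subnetwork only, for external visualization.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .network import SignedNetwork, association_subnetwork, _to_igraph

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_graphml",
]

_EDGE_HEADER = "id_i\tid_j\tsign"


def write_edge_list(net: SignedNetwork, path) -> None:
    """Write the nonzero ties of a signed network, one unordered pair per line."""
    lines = [_EDGE_HEADER]
    m = net.matrix
    for i, j in np.argwhere(np.triu(m, k=1) != 0):
        lines.append(f"{net.ids[i]}\t{net.ids[j]}\t{m[i, j]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path, ids: Optional[Sequence[int]] = None) -> SignedNetwork:
    """Read a signed edge list back into a network.

    ``ids`` fixes the full individual roster (needed to restore
    individuals with no ties); if omitted, the roster is the set of ids
    appearing in the file, in sorted order.
    """
    rows = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            if not line.strip():
                continue
            a, b, s = line.split()
            rows.append((int(a), int(b), int(s)))
    if ids is None:
        ids = sorted({i for a, b, _ in rows for i in (a, b)})
    ids = np.asarray(list(ids), dtype=np.int64)
    index = {int(v): k for k, v in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)), dtype=np.int8)
    for a, b, s in rows:
        m[index[a], index[b]] = s
        m[index[b], index[a]] = s
    return SignedNetwork(m, ids)


def write_matrix_csv(net: SignedNetwork, path) -> None:
    """Write the dense signed relationship matrix with id labels."""
    df = pd.DataFrame(net.matrix, index=net.ids, columns=net.ids)
    df.to_csv(path, index_label="id")


def read_matrix_csv(path) -> SignedNetwork:
    df = pd.read_csv(path, index_col=0)
    return SignedNetwork(df.to_numpy(dtype=np.int8), df.index.to_numpy(dtype=np.int64))


def write_graphml(net: SignedNetwork, path) -> None:
    """Export the association subnetwork as GraphML (ids as vertex names)."""
    binary = association_subnetwork(net)
    g = _to_igraph(binary.matrix)
    g.vs["name"] = [str(i) for i in net.ids]
    g.write_graphml(str(path))
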