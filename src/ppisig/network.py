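"""Protein–protein interaction networks and generalized topological overlap.

A PPI network is read from a tab-delimited edge list (two interactor
columns), canonicalized to a simple undirected graph (duplicate edges
collapsed, self-loops dropped), and summarized by the m-step generalized
topological overlap matrix (GTOM).  GTOM-m scores a pair of proteins by how
much their m-step neighborhoods overlap; 1 - GTOM is the dissimilarity used
downstream for module detection.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "PPINetwork",
    "GtomMatrix",
    "EDGELIST_PRESETS",
    "parse_ppi_edgelist",
    "write_edgelist",
    "compute_gtom",
    "gtom_dissimilarity",
    "write_gtom",
    "read_gtom",
]

#: Named column presets (0-based column indices of the two interactor columns).
#: "hprd" matches the HPRD binary protein-protein interaction flat file, whose
#: gene-symbol columns are the 1st and 4th.
EDGELIST_PRESETS: dict[str, tuple[int, int]] = {
    "simple": (0, 1),
    "hprd": (0, 3),
}


class EdgeListFormatError(ValueError):
    """Raised when an edge-list row cannot be parsed."""


class EmptyNetworkError(ValueError):
    """Raised when parsing yields a network without any nodes."""


@dataclass(frozen=True)
class PPINetwork:
    """Simple undirected network of protein/gene identifiers.

    Nodes are kept in deterministic (lexicographic) order; edges are
    unordered identifier pairs with no duplicates and no self-loops.
    """

    graph: nx.Graph = field(repr=False)

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("PPI network must not contain self-loops")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def adjacency(self) -> np.ndarray:
        """Symmetric 0/1 adjacency with zero diagonal, rows in node order."""
        return nx.to_numpy_array(self.graph, nodelist=self.nodes, dtype=np.int8)

    @classmethod
    def from_edges(cls, pairs: Sequence[tuple[str, str]]) -> "PPINetwork":
        g = nx.Graph()
        for a, b in pairs:
            if a != b:
                g.add_edge(a, b)
            else:
                g.add_node(a)
        return cls(g)


@dataclass(frozen=True)
class GtomMatrix:
    """m-step generalized topological overlap similarities.

    ``values[i, j]`` is the overlap of the m-step neighborhoods of nodes
    ``node_order[i]`` and ``node_order[j]``; the diagonal is 1 by definition
    and all entries lie in [0, 1].
    """

    values: np.ndarray
    step_m: int
    node_order: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.node_order):
            raise ValueError("GTOM matrix shape does not match node order")
        if not np.allclose(v, v.T):
            raise ValueError("GTOM matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("GTOM entries must lie in [0, 1]")


def parse_ppi_edgelist(
    path: str | Path | io.TextIOBase,
    columns: tuple[int, int] | str = "simple",
    skip_header: bool = False,
) -> PPINetwork:
    """Parse a tab-delimited interaction file into a canonical network.

    Parameters
    ----------
    path:
        File path or open text handle.
    columns:
        Pair of 0-based column indices of the two interactor identifier
        columns, or the name of a preset in :data:`EDGELIST_PRESETS`.
    skip_header:
        Skip the first line (for files with a header row).

    Replicated interactions are reduced to one undirected edge and
    self-loops are removed.  Identifiers are whitespace-trimmed and compared
    case-sensitively.  Node order of the result is lexicographic, so parsing
    the same file twice yields identical networks.
    """
    if isinstance(columns, str):
        try:
            columns = EDGELIST_PRESETS[columns]
        except KeyError:
            raise ValueError(f"unknown edge-list preset {columns!r}") from None
    ca, cb = columns
    need = max(ca, cb) + 1

    if isinstance(path, (str, Path)):
        handle: io.TextIOBase = open(path, "rt", encoding="utf-8")
        close = True
    else:
        handle, close = path, False

    pairs: list[tuple[str, str]] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            if skip_header and lineno == 1:
                continue
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < need:
                raise EdgeListFormatError(
                    f"row {lineno}: expected at least {need} tab-separated "
                    f"columns, found {len(fields)}"
                )
            a, b = fields[ca].strip(), fields[cb].strip()
            if not a or not b:
                raise EdgeListFormatError(
                    f"row {lineno}: empty interactor identifier"
                )
            pairs.append((a, b))
    finally:
        if close:
            handle.close()

    if not pairs:
        raise EmptyNetworkError("edge list contains no interactions")
    return PPINetwork.from_edges(pairs)


def write_edgelist(network: PPINetwork, path: str | Path) -> None:
    """Write the canonical (sorted, deduplicated) edge list as two-column TSV."""
    lines = sorted(tuple(sorted(e)) for e in network.edges)
    with open(path, "wt", encoding="utf-8") as fh:
        for a, b in lines:
            fh.write(f"{a}\t{b}\n")


def _reachability(adjacency: np.ndarray, m: int) -> np.ndarray:
    """0/1 indicator of 0 < shortest-path distance <= m, zero diagonal."""
    a = adjacency.astype(bool)
    reach = a.copy()
    power = a.copy()
    for _ in range(m - 1):
        power = power @ a
        reach |= power
    np.fill_diagonal(reach, False)
    return reach


def compute_gtom(
    network: PPINetwork, m: int = 2, variant: str = "reachability"
) -> GtomMatrix:
    """Compute the m-step generalized topological overlap matrix.

    Let ``r_ij`` indicate that j is within m steps of i, ``k_i`` the size of
    the m-step neighborhood of i, and ``l_ij`` the number of shared m-step
    neighbors.  Then::

        t_ij = (l_ij + r_ij) / (min(k_i, k_j) + 1 - r_ij)      (i != j)
        t_ii = 1

    i.e. the standard topological overlap measure applied to the m-step
    neighborhood graph; ``m=1`` recovers plain TOM.  ``variant="adjacency"``
    uses the 1-step adjacency ``a_ij`` in place of ``r_ij`` in the two
    correction terms, as some published GTOM definitions do.
    """
    if m < 1:
        raise ValueError(f"GTOM step m must be >= 1, got {m}")
    if variant not in ("reachability", "adjacency"):
        raise ValueError(f"unknown GTOM variant {variant!r}")
    if network.n_nodes < 2:
        raise ValueError("GTOM requires a network with at least 2 nodes")

    adj = network.adjacency()
    reach = _reachability(adj, m)
    r = reach.astype(np.float64)
    link = r if variant == "reachability" else adj.astype(np.float64)

    shared = r @ r  # l_ij: r_ii = 0 so u = i, j terms vanish
    k = r.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - link
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (shared + link) / denom
    t[denom <= 0] = 0.0  # isolated pair: no neighborhoods, overlap 0
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return GtomMatrix(values=t, step_m=m, node_order=network.nodes)


def gtom_dissimilarity(gtom: GtomMatrix) -> np.ndarray:
    """Dissimilarity d = 1 - GTOM with an exactly zero diagonal."""
    d = 1.0 - gtom.values
    np.fill_diagonal(d, 0.0)
    return d


def write_gtom(gtom: GtomMatrix, path: str | Path) -> None:
    """Write a GTOM matrix as TSV with a node-id header row and column."""
    import pandas as pd

    pd.DataFrame(
        gtom.values, index=gtom.node_order, columns=gtom.node_order
    ).to_csv(path, sep="\t")


def read_gtom(path: str | Path, step_m: int) -> GtomMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return GtomMatrix(
        values=df.to_numpy(dtype=float),
        step_m=step_m,
        node_order=[str(c) for c in df.columns],
    )
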