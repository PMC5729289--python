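"""Sub-module detection on a GTOM dissimilarity: dendrogram + dynamic tree cut.

The network's 1 - GTOM dissimilarity is clustered with complete linkage and
the dendrogram is cut adaptively: a static cut at ``max_height`` defines
candidate branches, an optional "deep split" recursively separates nested
sub-branches whose merge structure shows a clear height gap, and branches
smaller than ``min_size`` are left unassigned.  The result is a set of named
gene sets (sub-modules) serializable to/from GMT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

__all__ = [
    "Dendrogram",
    "ModuleAssignment",
    "ModuleSet",
    "hierarchical_cluster",
    "dynamic_tree_cut",
    "modules_to_gene_sets",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative tree over ``n`` leaves in scipy linkage encoding.

    ``linkage_matrix`` has ``n - 1`` rows ``(left, right, height, size)``;
    for complete linkage the heights are non-decreasing.
    """

    linkage_matrix: np.ndarray
    leaf_ids: list[str]
    method: str = "complete"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def __post_init__(self) -> None:
        n = self.n_leaves
        if self.linkage_matrix.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n - 1 rows of 4")


@dataclass(frozen=True)
class ModuleAssignment:
    """Per-leaf module labels: 0 = unassigned, 1..K = module id.

    Module ids are contiguous and ordered by decreasing module size.
    """

    labels: np.ndarray
    max_height: float
    min_size: int
    deep_split: bool

    @property
    def n_modules(self) -> int:
        return int(self.labels.max(initial=0))

    def module_members(self, node_order: Sequence[str]) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for mod in range(1, self.n_modules + 1):
            out[mod] = [node_order[i] for i in np.flatnonzero(self.labels == mod)]
        return out


@dataclass
class ModuleSet:
    """Named, disjoint gene sets with tree-cut provenance."""

    sets: dict[str, list[str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"module {name!r} is empty")
            dup = seen.intersection(members)
            if dup:
                raise ValueError(
                    f"identifiers assigned to more than one module: {sorted(dup)}"
                )
            seen.update(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sets.items()}

    def subset(self, names: Sequence[str]) -> "ModuleSet":
        return ModuleSet(
            sets={n: list(self.sets[n]) for n in names},
            provenance=dict(self.provenance),
        )


def hierarchical_cluster(
    dissimilarity: np.ndarray,
    leaf_ids: Sequence[str] | None = None,
    linkage: str = "complete",
) -> Dendrogram:
    """Agglomerative clustering of a square dissimilarity matrix.

    Only complete linkage is supported (the maximum pairwise dissimilarity
    between clusters), which keeps every merge height within [0, 1] for a
    1 - GTOM input.
    """
    if linkage != "complete":
        raise ValueError("only complete linkage is supported")
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if d.min() < 0:
        raise ValueError("dissimilarity entries must be non-negative")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("dissimilarity must have a zero diagonal")
    n = d.shape[0]
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    if len(leaf_ids) != n:
        raise ValueError("leaf_ids length must match matrix size")
    condensed = ssd.squareform((d + d.T) / 2.0, checks=False)
    z = sch.linkage(condensed, method="complete")
    return Dendrogram(linkage_matrix=z, leaf_ids=list(leaf_ids), method="complete")


# ---------------------------------------------------------------------------
# dynamic tree cut


class _Tree:
    """Light array-backed view of a scipy linkage for subtree traversal."""

    def __init__(self, z: np.ndarray, n: int) -> None:
        self.z = z
        self.n = n

    def height(self, node: int) -> float:
        return 0.0 if node < self.n else float(self.z[node - self.n, 2])

    def children(self, node: int) -> tuple[int, int]:
        row = self.z[node - self.n]
        return int(row[0]), int(row[1])

    def leaves(self, node: int) -> list[int]:
        out: list[int] = []
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur < self.n:
                out.append(cur)
            else:
                stack.extend(self.children(cur))
        return sorted(out)

    def size(self, node: int) -> int:
        return 1 if node < self.n else int(self.z[node - self.n, 3])

    def roots(self) -> list[int]:
        """Maximal nodes (forest roots); a full linkage has one root."""
        return [self.n + self.z.shape[0] - 1] if self.z.shape[0] else [0]

    def cut_below(self, node: int, height: float) -> list[int]:
        """Maximal subnodes of ``node`` whose merge height is <= height."""
        out: list[int] = []
        stack = [node]
        while stack:
            cur = stack.pop()
            if self.height(cur) <= height:
                out.append(cur)
            else:
                stack.extend(self.children(cur))
        return sorted(out)


def _split_branch(
    tree: _Tree, node: int, min_size: int, gap: float
) -> list[int]:
    """Recursively separate nested sub-branches of a candidate branch.

    A branch is split at its top merge when the jump from the children's
    merge heights to the branch height exceeds ``gap`` and at least one
    child is large enough to form a module on its own; otherwise the branch
    is kept whole.  Homogeneous branches (merges at similar heights) are
    never split.
    """
    if node < tree.n:
        return [node]
    left, right = tree.children(node)
    top = tree.height(node)
    child_top = max(tree.height(left), tree.height(right))
    big_child = max(tree.size(left), tree.size(right))
    if top - child_top > gap and big_child >= min_size:
        return _split_branch(tree, left, min_size, gap) + _split_branch(
            tree, right, min_size, gap
        )
    return [node]


def dynamic_tree_cut(
    dendrogram: Dendrogram,
    max_height: float = 0.6,
    min_size: int = 5,
    deep_split: bool = True,
    deep_split_gap: float = 0.25,
) -> ModuleAssignment:
    """Adaptive branch cutting of a dendrogram into sub-modules.

    Parameters
    ----------
    max_height:
        Static cut height in (0, 1]; leaves joined only above this height
        are never co-assigned.
    min_size:
        Minimum number of leaves a branch needs to become a module; smaller
        branches stay unassigned (label 0).
    deep_split:
        Recursively split candidate branches whose internal merge structure
        shows a height gap larger than ``deep_split_gap * max_height``
        between a branch top and its children, isolating nested tight
        sub-branches that a single static cut would lump together.
    """
    if not (0.0 < max_height <= 1.0):
        raise ValueError("max_height must lie in (0, 1]")
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    n = dendrogram.n_leaves
    tree = _Tree(dendrogram.linkage_matrix, n)
    if min_size > n:
        warnings.warn(
            f"min_size={min_size} exceeds leaf count {n}; no modules assigned",
            stacklevel=2,
        )
        return ModuleAssignment(
            labels=np.zeros(n, dtype=int),
            max_height=max_height,
            min_size=min_size,
            deep_split=deep_split,
        )

    candidates: list[int] = []
    for root in tree.roots():
        candidates.extend(tree.cut_below(root, max_height))

    gap = deep_split_gap * max_height
    branches: list[int] = []
    for node in candidates:
        if deep_split:
            branches.extend(_split_branch(tree, node, min_size, gap))
        else:
            branches.append(node)

    modules = [tree.leaves(b) for b in branches if tree.size(b) >= min_size]
    # rank by decreasing size; ties by smallest leaf index for determinism
    modules.sort(key=lambda leaves: (-len(leaves), leaves[0]))

    labels = np.zeros(n, dtype=int)
    for rank, leaves in enumerate(modules, start=1):
        labels[leaves] = rank
    return ModuleAssignment(
        labels=labels,
        max_height=max_height,
        min_size=min_size,
        deep_split=deep_split,
    )


def modules_to_gene_sets(
    assignment: ModuleAssignment,
    node_order: Sequence[str],
    name_prefix: str = "Mod",
    provenance: Mapping | None = None,
) -> ModuleSet:
    """Turn a tree-cut label vector into a named ModuleSet.

    Modules are named ``<prefix><rank>`` with rank 1 the largest module;
    unassigned leaves are omitted.
    """
    if len(node_order) != len(assignment.labels):
        raise ValueError("node_order length must match label vector")
    members = assignment.module_members(node_order)
    prov = dict(provenance or {})
    prov.update(
        max_height=assignment.max_height,
        min_size=assignment.min_size,
        deep_split=assignment.deep_split,
    )
    return ModuleSet(
        sets={f"{name_prefix}{mod}": genes for mod, genes in members.items()},
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# GMT round trip


def write_gmt(modules: ModuleSet, path: str | Path) -> None:
    """Write gene sets in GMT format (name, description, members)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for name, members in modules.items():
            desc = str(modules.provenance.get("description", "ppisig"))
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path: str | Path) -> ModuleSet:
    sets: dict[str, list[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return ModuleSet(sets=sets)
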