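"""Tree-sequence and sample-metadata I/O plus topology/time queries.

Every downstream component consumes marginal coalescent trees through the
:class:`MarginalTree` view defined here, so the rest of the package is
agnostic to whether a tree came from a simulation, from an external
genealogy-inference tool (converted to the standard ``.trees`` container),
or from a newick test fixture.

Conventions: node indices are 0-based (the tree-sequence container's own
numbering), genomic intervals are 0-based half-open in bp, and all times
are real-valued generations before present.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import tskit

__all__ = [
    "Population",
    "SampleMeta",
    "MarginalTree",
    "TreeSequenceHandle",
    "load_metadata",
    "load_tree_sequence",
    "tmrca",
    "ancestor_chain",
    "marginal_tree_from_newick",
]

#: Leaf-time agreement tolerance between file and metadata, in generations.
TIME_ATOL = 1e-6


class Population(str, enum.Enum):
    """Population labels of the four-way European admixture model.

    ANA/WHG/EHG/CHG are the ancestral classes (Anatolian early farmers and
    the Western, Eastern and Caucasus hunter-gatherers).  NEO (Neolithic
    farmers, ANA+WHG) and YAM (Yamnaya steppe, CHG+EHG) are admixed but
    usable as references for their component ancestries.  POSTNEO and
    PRESENT carry all four ancestries and are never references.
    """

    ANA = "ANA"
    WHG = "WHG"
    EHG = "EHG"
    CHG = "CHG"
    NEO = "NEO"
    YAM = "YAM"
    POSTNEO = "POSTNEO"
    PRESENT = "PRESENT"


#: Populations allowed to serve as references in the panel.
REFERENCE_POPULATIONS = frozenset(
    {Population.ANA, Population.WHG, Population.EHG, Population.CHG,
     Population.NEO, Population.YAM}
)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sampled haplotype (one leaf node)."""

    haplotype_id: int
    individual_id: str
    population: Population
    sample_time: float  # generations before present
    is_reference: bool

    def __post_init__(self) -> None:
        if self.sample_time < 0:
            raise ValueError(
                f"sample_time must be >= 0, got {self.sample_time} "
                f"for haplotype {self.haplotype_id}"
            )
        if self.is_reference and self.population not in REFERENCE_POPULATIONS:
            raise ValueError(
                f"{self.population.value} haplotypes cannot be references "
                f"(haplotype {self.haplotype_id})"
            )


class MarginalTree:
    """One marginal coalescent tree over a half-open genomic interval.

    Stores a parent map and node times as flat arrays indexed by node id.
    Roots have parent -1.  Node times never decrease from child to parent.
    """

    def __init__(
        self,
        interval: tuple[float, float],
        parent: np.ndarray,
        node_time: np.ndarray,
        leaves: Sequence[int],
    ) -> None:
        left, right = interval
        if not left < right:
            raise ValueError(f"empty interval [{left}, {right})")
        self.interval = (float(left), float(right))
        self.parent = np.asarray(parent, dtype=np.int64)
        self.node_time = np.asarray(node_time, dtype=np.float64)
        self.leaves = frozenset(int(v) for v in leaves)
        for child, par in enumerate(self.parent):
            if par >= 0 and self.node_time[par] < self.node_time[child]:
                raise ValueError(
                    f"parent {par} (t={self.node_time[par]}) younger than "
                    f"child {child} (t={self.node_time[child]})"
                )

    @property
    def span(self) -> float:
        return self.interval[1] - self.interval[0]

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.interval[0] + self.interval[1])

    def __contains__(self, node: int) -> bool:
        return 0 <= node < len(self.parent) and (
            self.parent[node] >= 0 or node in self.leaves or self._is_root(node)
        )

    def _is_root(self, node: int) -> bool:
        # a root of this tree is an ancestor of some leaf with parent -1
        return self.parent[node] == -1 and self.node_time[node] >= 0

    def is_leaf(self, node: int) -> bool:
        return int(node) in self.leaves

    def time(self, node: int) -> float:
        return float(self.node_time[node])

    def root_path(self, node: int) -> list[int]:
        """Nodes from ``node`` (inclusive) up to its root (inclusive)."""
        path = [int(node)]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for child, par in enumerate(self.parent):
            if par >= 0:
                out.setdefault(int(par), []).append(child)
        return out

    def subtree_leaves(self, node: int) -> list[int]:
        """All leaves below (or equal to) ``node`` in this tree."""
        if self.is_leaf(node):
            return [int(node)]
        children = self.children_map()
        stack, out = [int(node)], []
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(v)
            else:
                stack.extend(children.get(v, []))
        return sorted(out)

    @classmethod
    def from_tskit(cls, tree: tskit.Tree) -> "MarginalTree":
        ts = tree.tree_sequence
        return cls(
            interval=(tree.interval.left, tree.interval.right),
            parent=tree.parent_array[: ts.num_nodes].copy(),
            node_time=ts.tables.nodes.time,
            leaves=list(ts.samples()),
        )


def tmrca(tree: MarginalTree, i: int, j: int) -> float:
    """Time (generations) of the most recent common ancestor of ``i``, ``j``.

    Symmetric; ``tmrca(i, i)`` is the node's own time.  Uses the classic
    two-pointer climb: repeatedly advance whichever lineage is currently
    younger until the pointers meet.
    """
    i, j = int(i), int(j)
    n = len(tree.parent)
    for v in (i, j):
        if not (0 <= v < n):
            raise ValueError(f"node {v} not in tree (has {n} nodes)")
    t = tree.node_time
    par = tree.parent
    while i != j:
        if t[i] < t[j] or (t[i] == t[j] and i < j):
            if par[i] < 0:
                raise ValueError(f"nodes {i}, {j} share no ancestor in this tree")
            i = int(par[i])
        else:
            if par[j] < 0:
                raise ValueError(f"nodes {i}, {j} share no ancestor in this tree")
            j = int(par[j])
    return float(t[i])


@dataclass
class AncestorChain:
    """Ordered ancestors of a leaf, oldest last, with a truncation flag."""

    nodes: list[int]
    truncated: bool


def ancestor_chain(tree: MarginalTree, leaf: int, m: int) -> AncestorChain:
    """The ``m`` nearest ancestral nodes of ``leaf`` (parent first).

    If the root is reached before ``m`` ancestors are collected the chain
    is returned short with ``truncated=True``.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not tree.is_leaf(leaf):
        raise ValueError(f"node {leaf} is not a leaf")
    nodes: list[int] = []
    v = int(leaf)
    while len(nodes) < m and tree.parent[v] >= 0:
        v = int(tree.parent[v])
        nodes.append(v)
    return AncestorChain(nodes=nodes, truncated=len(nodes) < m)


METADATA_COLUMNS = ["haplotype_id", "individual_id", "population",
                    "sample_time", "is_reference"]


def load_metadata(path: str | Path) -> dict[int, SampleMeta]:
    """Read the sample-metadata TSV into a haplotype_id → SampleMeta map."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata file {path} lacks columns {sorted(missing)}")
    out: dict[int, SampleMeta] = {}
    for row in df.itertuples(index=False):
        hid = int(row.haplotype_id)
        is_ref = row.is_reference in (True, 1, "1", "true", "True")
        out[hid] = SampleMeta(
            haplotype_id=hid,
            individual_id=str(row.individual_id),
            population=Population(row.population),
            sample_time=float(row.sample_time),
            is_reference=is_ref,
        )
    return out


def write_metadata(metadata: Mapping[int, SampleMeta], path: str | Path) -> None:
    rows = [
        (m.haplotype_id, m.individual_id, m.population.value, m.sample_time,
         int(m.is_reference))
        for m in sorted(metadata.values(), key=lambda m: m.haplotype_id)
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


class TreeSequenceHandle:
    """A tree sequence plus its sample metadata.

    Validates that every leaf has a metadata row and that leaf node times
    agree with metadata sample times; iterates marginal trees in genomic
    order.  Marginal-tree intervals tile ``[0, sequence_length)``.
    """

    def __init__(self, ts: tskit.TreeSequence,
                 metadata: Mapping[int, SampleMeta]) -> None:
        self.ts = ts
        self.metadata = dict(metadata)
        node_time = ts.tables.nodes.time
        for leaf in ts.samples():
            leaf = int(leaf)
            if leaf not in self.metadata:
                raise ValueError(f"no metadata row for leaf {leaf}")
            expected = self.metadata[leaf].sample_time
            if abs(node_time[leaf] - expected) > TIME_ATOL:
                raise ValueError(
                    f"leaf {leaf}: file time {node_time[leaf]} disagrees with "
                    f"metadata sample_time {expected}"
                )
        self._check_tiling()

    def _check_tiling(self) -> None:
        expected_left = 0.0
        for tree in self.ts.trees():
            if tree.interval.left != expected_left:
                raise ValueError(
                    f"marginal tree intervals do not tile: gap/overlap at "
                    f"{tree.interval.left} (expected {expected_left})"
                )
            expected_left = tree.interval.right
        if expected_left != self.ts.sequence_length:
            raise ValueError("marginal trees do not reach sequence end")

    @property
    def sequence_length(self) -> float:
        return self.ts.sequence_length

    @property
    def num_trees(self) -> int:
        return self.ts.num_trees

    def samples(self) -> list[int]:
        return [int(s) for s in self.ts.samples()]

    def references(self) -> list[int]:
        return [h for h, m in sorted(self.metadata.items()) if m.is_reference]

    def trees(self) -> Iterator[MarginalTree]:
        for tree in self.ts.trees():
            yield MarginalTree.from_tskit(tree)


def load_tree_sequence(path: str | Path,
                       metadata: str | Path | Mapping[int, SampleMeta]
                       ) -> TreeSequenceHandle:
    """Load a ``.trees`` file and its metadata table into a handle."""
    ts = tskit.load(str(path))
    if not isinstance(metadata, Mapping):
        metadata = load_metadata(metadata)
    return TreeSequenceHandle(ts, metadata)


def marginal_tree_from_newick(newick: str, span: float = 1.0) -> tuple[
        MarginalTree, dict[str, int]]:
    """Build a single MarginalTree from a newick string (test fixtures).

    Branch lengths are in generations; leaf times are inferred from root
    depth (deepest leaf is at time 0).  Returns the tree and a
    name → node-id map.
    """
    import io

    from Bio import Phylo

    clade_tree = Phylo.read(io.StringIO(newick), "newick")
    ids: dict[int, int] = {}
    names: dict[str, int] = {}
    parent: list[int] = []
    depth: list[float] = []
    leaves: list[int] = []

    def visit(clade, parent_id: int, d: float) -> None:
        node_id = len(parent)
        ids[id(clade)] = node_id
        parent.append(parent_id)
        depth.append(d)
        if clade.name:
            names[clade.name] = node_id
        if not clade.clades:
            leaves.append(node_id)
        for child in clade.clades:
            visit(child, node_id, d + (child.branch_length or 0.0))

    visit(clade_tree.root, -1, 0.0)
    max_depth = max(depth[v] for v in leaves)
    times = np.array([max_depth - d for d in depth])
    tree = MarginalTree((0.0, span), np.array(parent), times, leaves)
    return tree, names
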