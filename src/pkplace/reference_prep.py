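"""Reference preprocessing: gap-column filtering and the extended tree.

Every branch ``y`` of the rooted reference tree receives a pair of *ghost
nodes*: ``u_y`` at the branch midpoint and a new leaf ``v_y`` hanging from it.
Ghost nodes stand in for unsampled sequences that diverged from ``y`` in the
past; posterior state probabilities are later computed at both.  The ghost
branch ``(u_y, v_y)`` has length equal to the mean path length from ``u_y``
to the original leaves that descend from it — the expected divergence of a
query that belongs on ``y``.  Correct rooting is therefore a prerequisite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .seqio import Alignment, GAP_CHARS


@dataclass
class ColumnMap:
    """Original 0-based indices of alignment columns kept by the gap filter."""

    kept: list[int]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.kept, self.kept[1:])):
            raise ValueError("kept column indices must be strictly increasing")


def filter_gap_columns(
    aln: Alignment, max_gap_ratio: float = 0.99
) -> tuple[Alignment, ColumnMap]:
    """Drop columns whose gap fraction is >= ``max_gap_ratio``.

    The comparison is non-strict, so a threshold of 0.5 removes a column
    that is exactly half gaps, and a threshold of 1.0 removes only all-gap
    columns.
    """
    if not 0.0 <= max_gap_ratio <= 1.0:
        raise ValueError("max_gap_ratio must be in [0, 1]")
    n = aln.n_sequences
    kept: list[int] = []
    for j in range(aln.length):
        gaps = sum(1 for row in aln.rows if row[j] in GAP_CHARS)
        if gaps / n < max_gap_ratio:
            kept.append(j)
    if not kept:
        raise ValueError("empty alignment after gap filtering")
    rows = ["".join(row[j] for j in kept) for row in aln.rows]
    return (
        Alignment(names=list(aln.names), rows=rows, alphabet=aln.alphabet),
        ColumnMap(kept=kept),
    )


@dataclass
class EdgeRecord:
    """One original branch of the reference tree.

    ``edge_id`` is the jplace edge number (deterministic post-order);
    ``child`` is the node below the branch; ``ghost_length`` is the length of
    the ghost branch (u_y, v_y).
    """

    edge_id: int
    length: float
    child: dendropy.Node
    ghost_length: float
    leaf_labels: frozenset[str]


@dataclass
class ExtendedTree:
    """Rooted reference tree plus per-branch ghost node bookkeeping.

    The dendropy tree itself is left untouched; ghost nodes exist only as
    the (midpoint, ghost-leaf) geometry recorded per edge.  The extended
    tree conceptually has 3B edges for B original branches: the two halves
    of each split branch plus the ghost branch.
    """

    tree: dendropy.Tree
    edges: list[EdgeRecord]
    edge_of_child: dict[int, int] = field(repr=False, default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_edges_extended(self) -> int:
        return 3 * len(self.edges)

    def edge_for_node(self, node: dendropy.Node) -> EdgeRecord:
        return self.edges[self.edge_of_child[id(node)]]

    def edge_by_leafset(self, labels: frozenset[str]) -> EdgeRecord:
        """The branch subtending exactly the given set of leaf labels."""
        for e in self.edges:
            if e.leaf_labels == labels:
                return e
        raise KeyError(f"no branch subtends leaf set {sorted(labels)}")

    def edge_numbered_newick(self) -> str:
        """Newick string with jplace ``{n}`` edge annotations."""

        def render(node: dendropy.Node) -> str:
            if node.is_leaf():
                base = node.taxon.label if node.taxon else ""
            else:
                base = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
                if node.taxon is not None:
                    base += node.taxon.label
            if node is self.tree.seed_node:
                return base
            eid = self.edge_of_child[id(node)]
            length = self.edges[eid].length
            return f"{base}:{length:.12g}{{{eid}}}"

        return render(self.tree.seed_node) + ";"


def extend_tree(tree: dendropy.Tree) -> ExtendedTree:
    """Number the branches and compute ghost node geometry.

    Edge numbers follow a post-order traversal of the original tree, so the
    numbering (and all downstream output) is reproducible across runs for
    the same Newick input.  The ghost branch length for edge ``y`` with
    length ``t`` below node ``c`` is ``t/2`` plus the mean distance from
    ``c`` to the original leaves under it; ghost leaves never enter the mean.
    """
    # mean root-ward distance from each node down to its descendant leaves
    n_leaves: dict[int, int] = {}
    sum_dist: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            n_leaves[id(node)] = 1
            sum_dist[id(node)] = 0.0
        else:
            cnt = 0
            tot = 0.0
            for ch in node.child_nodes():
                t = ch.edge.length
                if t is None or t < 0:
                    raise ValueError("all branch lengths must be present and >= 0")
                cnt += n_leaves[id(ch)]
                tot += sum_dist[id(ch)] + n_leaves[id(ch)] * t
            n_leaves[id(node)] = cnt
            sum_dist[id(node)] = tot

    leafsets: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = frozenset([node.taxon.label])
        else:
            s: frozenset[str] = frozenset()
            for ch in node.child_nodes():
                s |= leafsets[id(ch)]
            leafsets[id(node)] = s

    edges: list[EdgeRecord] = []
    edge_of_child: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length
        if t is None or t < 0:
            raise ValueError("all branch lengths must be present and >= 0")
        mean_below = sum_dist[id(node)] / n_leaves[id(node)]
        ghost = t / 2.0 + mean_below
        eid = len(edges)
        edges.append(
            EdgeRecord(
                edge_id=eid,
                length=t,
                child=node,
                ghost_length=ghost,
                leaf_labels=leafsets[id(node)],
            )
        )
        edge_of_child[id(node)] = eid
    return ExtendedTree(tree=tree, edges=edges, edge_of_child=edge_of_child)
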