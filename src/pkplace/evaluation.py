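"""Pruning-based accuracy (PAC) evaluation and the filtering experiment.

A pruning removes a random subtree from the reference tree; reads extracted
from the removed leaves are placed back on the pruned tree, and accuracy is
the *node distance* between the reported branch and the branch created by
the pruning (the two edges incident to the suppressed attachment node merge
into one, which is the expected placement).  Node distance counts the tree
nodes on the path between the observed and expected edges, with the
degree-2 root suppressed as in the unrooted view, so two pendant edges of
sister cherries in ((A,B),(C,D)) are 2 apart.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from . import db_build, placement, posteriors as _posteriors
from .reference_prep import ExtendedTree, extend_tree, filter_gap_columns
from .seqio import Alignment, GAP_CHARS
from .substitution import SubstitutionModel, get_model


@dataclass
class PruningInstance:
    """One PAC pruning: the reduced reference set plus ground truth."""

    pruned_tree: dendropy.Tree
    pruned_alignment: Alignment
    removed_leaves: list[str]
    expected_leafset: frozenset[str]  # identifies the merged branch
    seed: int

    def expected_edge_id(self, ext: ExtendedTree) -> int:
        return ext.edge_by_leafset(self.expected_leafset).edge_id


def prune(
    tree: dendropy.Tree, aln: Alignment, seed: int, max_retries: int = 100
) -> PruningInstance:
    """Remove a uniformly random subtree and record the merged branch.

    The parent of the removed subtree is suppressed and its two remaining
    incident edges merge (lengths add).  Draws that would leave fewer than
    3 leaves, or whose attachment point is the root (no merged branch
    exists), are resampled up to ``max_retries`` times.
    """
    rng = np.random.default_rng(seed)
    n_total = sum(1 for _ in tree.leaf_node_iter())
    if n_total < 4:
        raise ValueError("tree must have at least 4 leaves to prune")
    for _ in range(max_retries):
        work = tree.clone(depth=1)
        candidates = [
            nd for nd in work.postorder_node_iter() if nd is not work.seed_node
        ]
        node = candidates[int(rng.integers(len(candidates)))]
        parent = node.parent_node
        if parent is work.seed_node:
            continue
        removed = sorted(lf.taxon.label for lf in node.leaf_iter())
        if n_total - len(removed) < 3:
            continue
        grand = parent.parent_node
        siblings = [c for c in parent.child_nodes() if c is not node]
        if len(siblings) != 1:
            continue
        sib = siblings[0]
        merged_length = sib.edge.length + parent.edge.length
        parent.remove_child(node)
        grand.remove_child(parent)
        grand.add_child(sib)
        sib.edge.length = merged_length
        kept = [n for n in aln.names if n not in set(removed)]
        sub = Alignment(
            names=kept,
            rows=[aln.row(n) for n in kept],
            alphabet=aln.alphabet,
        )
        expected = frozenset(lf.taxon.label for lf in sib.leaf_iter())
        return PruningInstance(
            pruned_tree=work,
            pruned_alignment=sub,
            removed_leaves=removed,
            expected_leafset=expected,
            seed=seed,
        )
    raise RuntimeError("could not find a valid pruning after bounded retries")


def make_reads(
    sequences: dict[str, str],
    read_length: int = 150,
    n_reads: int | None = None,
    seed: int = 0,
    cap: int = 10_000,
) -> list[tuple[str, str]]:
    """Random substrings of the (ungapped) removed-leaf sequences.

    By default the read count is ceil(total residues / read_length), capped;
    reads cycle through the source leaves.  A sequence shorter than
    ``read_length`` contributes itself whole.
    """
    rng = np.random.default_rng(seed)
    names = sorted(sequences)
    degapped = {n: "".join(c for c in sequences[n] if c not in GAP_CHARS) for n in names}
    total = sum(len(s) for s in degapped.values())
    if n_reads is None:
        n_reads = min(cap, max(1, math.ceil(total / read_length)))
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        src = names[i % len(names)]
        seq = degapped[src]
        if len(seq) <= read_length:
            frag = seq
        else:
            start = int(rng.integers(len(seq) - read_length + 1))
            frag = seq[start : start + read_length]
        reads.append((f"{src}_read{i}", frag))
    return reads


def node_distance(ext: ExtendedTree, observed: int, expected: int) -> int:
    """Nodes on the path between two edges; 0 iff the same edge.

    Computed on the unrooted view: the degree-2 root is suppressed, which
    also identifies its two child edges with each other.
    """
    edges = ext.edges
    if not (0 <= observed < len(edges)) or not (0 <= expected < len(edges)):
        raise KeyError("unknown branch id")
    if observed == expected:
        return 0
    root = ext.tree.seed_node
    root_children = root.child_nodes()

    def endpoints(eid: int) -> tuple:
        child = edges[eid].child
        parent = child.parent_node
        if parent is root and len(root_children) == 2:
            other = root_children[0] if root_children[1] is child else root_children[1]
            return (id(child), id(other))
        return (id(child), id(parent))

    e1, e2 = endpoints(observed), endpoints(expected)
    if set(e1) == set(e2):
        return 0  # the two root edges are one edge unrooted
    # adjacency with the root suppressed
    adj: dict[int, list[int]] = {}

    def link(a, b):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    for nd in ext.tree.preorder_node_iter():
        for ch in nd.child_nodes():
            if nd is root and len(root_children) == 2:
                continue
            link(id(nd), id(ch))
    if len(root_children) == 2:
        link(id(root_children[0]), id(root_children[1]))
    # BFS from e1's endpoints to the nearest endpoint of e2
    dist = {a: 0 for a in e1}
    q = deque(e1)
    targets = set(e2)
    while q:
        cur = q.popleft()
        if cur in targets:
            return dist[cur] + 1
        for nb in adj.get(cur, ()):
            if nb not in dist:
                dist[nb] = dist[cur] + 1
                q.append(nb)
    raise RuntimeError("edges are not connected in the tree")


def _build_db_for(
    aln: Alignment,
    tree: dendropy.Tree,
    k: int,
    model: SubstitutionModel,
    omega: float,
    gap_ratio: float,
) -> tuple[db_build.PhyloKmerDB, ExtendedTree]:
    filtered, _ = filter_gap_columns(aln, gap_ratio)
    ext = extend_tree(tree)
    post = _posteriors.marginal_posteriors(ext, filtered, model)
    db = db_build.build_database(
        ext, post, k=k, omega=omega, alphabet=aln.alphabet
    )
    db_build.compute_mi(db)
    return db, ext


def pac_experiment(
    aln: Alignment,
    tree: dendropy.Tree,
    n_prunings: int = 30,
    mu_grid: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125, 0.0625),
    filters: tuple[str, ...] = ("mi", "random"),
    seed: int = 0,
    k: int = 10,
    model: SubstitutionModel | str = "JC69",
    omega: float = 1.5,
    gap_ratio: float = 0.99,
    read_length: int = 150,
    max_reads_per_pruning: int = 100,
) -> pd.DataFrame:
    """Mean node distance per (pruning, μ, filter).

    For each pruning the database is rebuilt on the pruned references and
    filtered in memory at each μ for each filter (the in-memory filter and
    partial deserialization apply identical bookkeeping and seeded
    selection); prunings and reads are identical across μ values and
    filters.  Returns a table with columns pruning, mu, filter, n_reads,
    mean_nd, se.
    """
    if isinstance(model, str):
        model = get_model(model)
    rows = []
    for p in range(n_prunings):
        inst = prune(tree, aln, seed=seed * 100_003 + p)
        reads = make_reads(
            {n: aln.row(n) for n in inst.removed_leaves},
            read_length=read_length,
            seed=seed * 100_003 + p,
            cap=max_reads_per_pruning,
        )
        db, ext = _build_db_for(
            inst.pruned_alignment, inst.pruned_tree, k, model, omega, gap_ratio
        )
        expected = inst.expected_edge_id(ext)
        for filt in filters:
            for mu in mu_grid:
                loaded = db_build.filter_database(
                    db, mu=mu, mode=filt, seed=seed * 100_003 + p
                )
                cfg = placement.ScoringConfig.for_db(loaded)
                results = placement.place_batch(reads, loaded, cfg)
                nds = [
                    node_distance(ext, r.best_branch, expected)
                    for r in results
                    if not r.unplaced
                ]
                nds = np.array(nds, dtype=float)
                rows.append(
                    {
                        "pruning": p,
                        "mu": mu,
                        "filter": filt,
                        "n_reads": len(nds),
                        "mean_nd": nds.mean() if len(nds) else np.nan,
                        "se": (
                            nds.std(ddof=1) / math.sqrt(len(nds))
                            if len(nds) > 1
                            else 0.0
                        ),
                    }
                )
    return pd.DataFrame(rows)
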