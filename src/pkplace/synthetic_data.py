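"""Synthetic reference data with known ground truth.

Trees follow a Yule (pure-birth) topology — at each step a uniformly chosen
extant leaf splits — with i.i.d. exponential branch lengths.  Sequences
evolve down the tree site-independently under a reversible substitution
model from a stationary root draw, so the reference alignment is ungapped
and every leaf's true pendant branch is known.  Query reads are random
substrings with optional i.i.d. substitution errors.

Two standard fixtures are used throughout the test-suite and the
reproduction script: "small" (16 leaves × 600 bp) and "medium"
(64 leaves × 1500 bp), both DNA under JC69 with exponential branch lengths
of mean 0.1 substitutions/site — divergences typical of a single-gene
reference phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import dendropy

from .seqio import ALPHABETS, Alignment, DNA, tree_from_string
from .substitution import SubstitutionModel, get_model


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset; the seed fixes all randomness."""

    n_leaves: int = 16
    seq_length: int = 600
    branch_length_mean: float = 0.1
    model: SubstitutionModel = field(default_factory=lambda: get_model("JC69"))
    read_length: int = 150
    read_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 3:
            raise ValueError("need at least 3 leaves")
        if self.seq_length <= 0 or self.branch_length_mean <= 0:
            raise ValueError("lengths must be positive")
        if not 0.0 <= self.read_error_rate <= 1.0:
            raise ValueError("error rate must be in [0, 1]")


def simulate_tree(spec: SimulationSpec) -> dendropy.Tree:
    """Yule topology with exponential branch lengths, leaves L0..L{n-1}."""
    rng = np.random.default_rng(spec.seed)
    # nested-list shape: a leaf is a token, an internal node a pair
    next_token = [0]

    def new_leaf():
        t = next_token[0]
        next_token[0] += 1
        return t

    shape: list = [new_leaf(), new_leaf()]
    leaves = 2
    # locations of leaf tokens: (parent list, index)
    while leaves < spec.n_leaves:
        # pick a uniform leaf by walking for its token
        target = int(rng.integers(leaves))

        def split(node: list, count: int) -> int:
            for i, ch in enumerate(node):
                if isinstance(ch, list):
                    count = split(ch, count)
                    if count < 0:
                        return count
                else:
                    if count == target:
                        node[i] = [new_leaf(), new_leaf()]
                        return -1
                    count += 1
            return count

        split(shape, 0)
        leaves += 1

    # relabel tokens to L0.. in left-to-right order and attach branch lengths
    label_counter = [0]

    def render(node) -> str:
        if isinstance(node, list):
            inner = ",".join(render(ch) for ch in node)
            return f"({inner}):{rng.exponential(spec.branch_length_mean):.10f}"
        lbl = f"L{label_counter[0]}"
        label_counter[0] += 1
        return f"{lbl}:{rng.exponential(spec.branch_length_mean):.10f}"

    inner = ",".join(render(ch) for ch in shape)
    newick = f"({inner});"
    return tree_from_string(newick)


def simulate_alignment(tree: dendropy.Tree, spec: SimulationSpec) -> Alignment:
    """Evolve an ungapped alignment down the tree under ``spec.model``."""
    model = spec.model
    rng = np.random.default_rng(spec.seed + 1)
    S = spec.seq_length
    chars = np.array(list(ALPHABETS[model.alphabet]))
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(len(model.pi), size=S, p=model.pi)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        P = model.transition_matrix(node.edge.length)
        cum = np.cumsum(P, axis=1)
        parent_states = states[id(node.parent_node)]
        u = rng.random(S)
        states[id(node)] = (u[:, None] > cum[parent_states]).sum(axis=1)
    names, rows = [], []
    for leaf in tree.leaf_node_iter():
        names.append(leaf.taxon.label)
        rows.append("".join(chars[states[id(leaf)]]))
    return Alignment(names=names, rows=rows, alphabet=model.alphabet)


def make_queries(
    aln: Alignment,
    read_length: int = 150,
    error_rate: float = 0.0,
    n_reads: int = 100,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Reads with recorded truth: (read name, sequence, source leaf).

    Start positions are uniform; each position is independently corrupted
    with probability ``error_rate`` to a uniformly chosen *different* state.
    """
    rng = np.random.default_rng(seed)
    chars = ALPHABETS[aln.alphabet]
    s = len(chars)
    rank = {c: i for i, c in enumerate(chars)}
    out = []
    for i in range(n_reads):
        src = aln.names[int(rng.integers(aln.n_sequences))]
        seq = aln.degapped(src)
        if len(seq) <= read_length:
            frag = seq
        else:
            start = int(rng.integers(len(seq) - read_length + 1))
            frag = seq[start : start + read_length]
        if error_rate > 0:
            arr = np.array([rank[c] for c in frag])
            hits = rng.random(len(arr)) < error_rate
            # shift by 1..σ-1 guarantees a different state
            arr[hits] = (arr[hits] + rng.integers(1, s, size=hits.sum())) % s
            frag = "".join(chars[j] for j in arr)
        out.append((f"{src}_q{i}", frag, src))
    return out


def small_fixture(seed: int = 0) -> tuple[Alignment, dendropy.Tree, SimulationSpec]:
    """16 leaves × 600 bp DNA under JC69."""
    spec = SimulationSpec(n_leaves=16, seq_length=600, seed=seed)
    tree = simulate_tree(spec)
    return simulate_alignment(tree, spec), tree, spec


def medium_fixture(seed: int = 0) -> tuple[Alignment, dendropy.Tree, SimulationSpec]:
    """64 leaves × 1500 bp DNA under JC69."""
    spec = SimulationSpec(n_leaves=64, seq_length=1500, seed=seed)
    tree = simulate_tree(spec)
    return simulate_alignment(tree, spec), tree, spec
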