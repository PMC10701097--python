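"""Marginal posterior state probabilities at ghost nodes.

An upward (pruning) pass computes, per node and site, the conditional
likelihood of the data below given each state; a downward pass completes the
standard up–down marginal ancestral reconstruction.  The midpoint ghost node
u_y of branch y combines the outside message arriving at the branch with the
upward message of the child across two half-length transitions; the ghost
leaf v_y is u_y's marginal pushed through the ghost branch.

Per-site scaling factors are tracked in log space so long alignments do not
underflow; scale factors cancel in the posteriors but are kept so that the
total site log-likelihood can be evaluated at any node (the two evaluations
must agree for a reversible model — a useful consistency check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .reference_prep import ExtendedTree
from .seqio import ALPHABETS, Alignment
from .substitution import SubstitutionModel


@dataclass
class PosteriorMatrix:
    """Sites × σ posterior state probabilities at one ghost node."""

    node_id: str
    P: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.P < -1e-12) or not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must be distributions")


@dataclass
class GhostPosteriors:
    """Posterior matrices at (u_y, v_y) for every original branch y."""

    u: dict[int, np.ndarray]  # edge_id -> (S, sigma)
    v: dict[int, np.ndarray]
    site_loglik: np.ndarray = field(repr=False, default=None)

    def pair(self, edge_id: int) -> tuple[np.ndarray, np.ndarray]:
        return self.u[edge_id], self.v[edge_id]


def _leaf_likelihoods(row: str, alphabet: str) -> np.ndarray:
    """One-hot vectors for observed states; all-ones for gaps/ambiguities."""
    chars = ALPHABETS[alphabet]
    s = len(chars)
    lut = np.full(128, -1, dtype=np.int64)
    for i, c in enumerate(chars):
        lut[ord(c)] = i
    idx = lut[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
    L = np.zeros((len(row), s))
    known = idx >= 0
    L[np.arange(len(row))[known], idx[known]] = 1.0
    L[~known, :] = 1.0
    return L


class _TransitionCache:
    def __init__(self, model: SubstitutionModel):
        self.model = model
        self._cache: dict[float, np.ndarray] = {}

    def __call__(self, t: float) -> np.ndarray:
        P = self._cache.get(t)
        if P is None:
            P = self.model.transition_matrix(t)
            self._cache[t] = P
        return P


def conditional_likelihoods_up(
    ext_tree: ExtendedTree, aln: Alignment, model: SubstitutionModel
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Upward partial likelihoods per node.

    Returns ``(up, logscale)`` keyed by ``id(node)``: ``up`` holds the
    scaled (S, σ) conditional likelihood of the data below the node given
    each state; ``logscale`` the per-site log of the accumulated scaling.
    """
    tree = ext_tree.tree
    trans = _TransitionCache(model)
    S = aln.length
    up: dict[int, np.ndarray] = {}
    logscale: dict[int, np.ndarray] = {}
    row_of = {name: i for i, name in enumerate(aln.names)}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            up[id(node)] = _leaf_likelihoods(aln.rows[row_of[node.taxon.label]], aln.alphabet)
            logscale[id(node)] = np.zeros(S)
        else:
            acc = np.ones((S, model.n_states))
            ls = np.zeros(S)
            for ch in node.child_nodes():
                P = trans(ch.edge.length)
                acc *= up[id(ch)] @ P.T
                ls += logscale[id(ch)]
            m = acc.max(axis=1)
            m[m == 0] = 1.0
            up[id(node)] = acc / m[:, None]
            logscale[id(node)] = ls + np.log(m)
    return up, logscale


def marginal_posteriors(
    ext_tree: ExtendedTree, aln: Alignment, model: SubstitutionModel
) -> GhostPosteriors:
    """Posterior state distributions at every ghost node pair (u_y, v_y).

    The root prior is the model's stationary distribution.  For branch y
    between parent p and child c with length t, the joint weight of state x
    at the midpoint u_y is::

        (outside message into the branch at p) · P(t/2)  [row x]
          × P(t/2) · (upward message of c)               [entry x]

    normalized over x.  v_y's posterior is u_y's marginal propagated through
    the ghost branch, so a zero-length ghost branch copies u_y exactly.
    """
    tree = ext_tree.tree
    trans = _TransitionCache(model)
    up, upscale = conditional_likelihoods_up(ext_tree, aln, model)
    S = aln.length

    # messages from each child into its parent: m_c = up_c @ P(t_c).T
    msg: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        msg[id(node)] = up[id(node)] @ trans(node.edge.length).T

    # outside ("mid") message entering each branch from the parent side,
    # before the branch transition; includes the root prior π
    mid: dict[int, np.ndarray] = {}
    midscale: dict[int, np.ndarray] = {}
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        down_here: np.ndarray
        if node is root:
            down_here = np.broadcast_to(model.pi, (S, model.n_states)).copy()
            scale_here = np.zeros(S)
        else:
            down_here = mid[id(node)] @ trans(node.edge.length)
            scale_here = midscale[id(node)]
        for ch in node.child_nodes():
            acc = down_here.copy()
            ls = scale_here.copy()
            for sib in node.child_nodes():
                if sib is ch:
                    continue
                acc *= msg[id(sib)]
                ls += upscale[id(sib)]
            m = acc.max(axis=1)
            m[m == 0] = 1.0
            mid[id(ch)] = acc / m[:, None]
            midscale[id(ch)] = ls + np.log(m)

    u_post: dict[int, np.ndarray] = {}
    v_post: dict[int, np.ndarray] = {}
    site_ll: np.ndarray | None = None
    for rec in ext_tree.edges:
        c = rec.child
        Ph = trans(rec.length / 2.0)
        joint = (mid[id(c)] @ Ph) * (up[id(c)] @ Ph.T)
        tot = joint.sum(axis=1)
        ll = np.log(tot) + midscale[id(c)] + upscale[id(c)]
        if site_ll is None:
            site_ll = ll
        pu = joint / tot[:, None]
        u_post[rec.edge_id] = pu
        v_post[rec.edge_id] = pu @ trans(rec.ghost_length)
    return GhostPosteriors(u=u_post, v=v_post, site_loglik=site_ll)


def site_loglik_at_root(
    ext_tree: ExtendedTree, aln: Alignment, model: SubstitutionModel
) -> np.ndarray:
    """Per-site log-likelihood evaluated at the root (pulley cross-check)."""
    up, upscale = conditional_likelihoods_up(ext_tree, aln, model)
    root = ext_tree.tree.seed_node
    return np.log(up[id(root)] @ model.pi) + upscale[id(root)]


def read_posterior_table(path, n_states: int) -> dict[str, np.ndarray]:
    """Ingest an externally produced posterior table.

    TSV columns: node_id, site (0-based), then σ state probabilities in
    alphabet rank order.  Rows that do not sum to 1 within 1e-6 are
    renormalized with a warning.  Returns node_id -> (S, σ) matrices.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] != 2 + n_states:
        raise ValueError(f"expected {2 + n_states} columns, found {df.shape[1]}")
    out: dict[str, np.ndarray] = {}
    for node_id, grp in df.groupby(0, sort=False):
        grp = grp.sort_values(1)
        sites = grp[1].to_numpy()
        if not np.array_equal(sites, np.arange(len(sites))):
            raise ValueError(f"non-contiguous site indices for node {node_id!r}")
        P = grp.iloc[:, 2:].to_numpy(dtype=float)
        sums = P.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            warnings.warn(
                f"posterior rows for node {node_id!r} do not sum to 1; renormalizing"
            )
        out[str(node_id)] = P / sums[:, None]
    return out
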