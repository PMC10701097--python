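"""Posterior correctness against an exhaustive sum-over-assignments oracle.

The oracle rebuilds, for one target branch, the explicit extended graph
(midpoint node u, ghost leaf v) and sums the joint probability over every
state assignment of all unobserved nodes — no pruning recursion, no shared
code with the implementation.
"""

import itertools

import numpy as np
import pytest

from pkplace.posteriors import (
    conditional_likelihoods_up,
    marginal_posteriors,
    read_posterior_table,
    site_loglik_at_root,
)
from pkplace.reference_prep import extend_tree
from pkplace.seqio import ALPHABETS, Alignment, tree_from_string
from pkplace.substitution import get_model, gtr


def exhaustive_ghost_posterior(ext, aln, model, edge_id, which):
    """Posterior at u_y ('u') or v_y ('v') by brute-force marginalization."""
    sigma = model.n_states
    rank = {c: i for i, c in enumerate(ALPHABETS[aln.alphabet])}
    rec = ext.edges[edge_id]
    target_child = rec.child

    # collect original edges as (parent, child, length), splitting the target
    nodes = list(ext.tree.preorder_node_iter())
    edges = []
    for nd in nodes:
        if nd is ext.tree.seed_node:
            continue
        if nd is target_child:
            edges.append(("u", id(nd.parent_node), rec.length / 2.0, "down"))
            edges.append((id(nd), "u", rec.length / 2.0, "down"))
        else:
            edges.append((id(nd), id(nd.parent_node), nd.edge.length, "down"))
    edges.append(("v", "u", rec.ghost_length, "down"))

    leaf_state = {}
    row_of = {n: i for i, n in enumerate(aln.names)}
    for leaf in ext.tree.leaf_node_iter():
        leaf_state[id(leaf)] = aln.rows[row_of[leaf.taxon.label]]

    all_ids = {id(ext.tree.seed_node)} | {id(n) for n in nodes} | {"u", "v"}
    S = aln.length
    out = np.zeros((S, sigma))
    for s in range(S):
        fixed = {}
        free = []
        for nid in all_ids:
            if nid in leaf_state:
                c = leaf_state[nid][s]
                if c in rank:
                    fixed[nid] = rank[c]
                else:
                    free.append(nid)  # gap/ambiguity: marginalized out
            else:
                free.append(nid)
        root_id = id(ext.tree.seed_node)
        P = {t: model.transition_matrix(t) for _, _, t, _ in edges}
        for assign in itertools.product(range(sigma), repeat=len(free)):
            states = dict(fixed)
            states.update(zip(free, assign))
            w = model.pi[states[root_id]]
            for child, parent, t, _ in edges:
                w *= P[t][states[parent], states[child]]
            node = "u" if which == "u" else "v"
            out[s, states[node]] += w
    return out / out.sum(axis=1, keepdims=True)


TREES = [
    "(A:0.3,B:0.7);",
    "((A:0.2,B:0.5):0.3,C:0.4);",
    "(((A:0.2,B:0.4):0.25,C:0.6):0.15,D:0.5);",
    "((A:0.3,B:0.2):0.4,(C:0.5,D:0.1):0.35);",
]


def random_alignment(names, n_sites, rng, with_gap=False):
    chars = "ACGT" + ("-" if with_gap else "")
    rows = ["".join(rng.choice(list(chars), size=n_sites)) for _ in names]
    return Alignment(names=list(names), rows=rows)


@pytest.fixture(scope="module")
def models():
    rng = np.random.default_rng(5)
    return [
        get_model("JC69"),
        gtr(rng.dirichlet(np.ones(4) * 8), rng.uniform(0.3, 2.5, size=6)),
    ]


class TestUpwardPass:
    def test_leaf_vectors(self, jc):
        tree = tree_from_string("(A:0.1,B:0.1);")
        aln = Alignment(names=["A", "B"], rows=["AC-", "AN-"])
        ext = extend_tree(tree)
        up, _ = conditional_likelihoods_up(ext, aln, jc)
        leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        a = up[id(leaves["A"])]
        assert np.array_equal(a[0], [1, 0, 0, 0])  # observed A
        assert np.array_equal(a[1], [0, 1, 0, 0])  # observed C
        assert np.array_equal(a[2], [1, 1, 1, 1])  # gap: missing data
        b = up[id(leaves["B"])]
        assert np.array_equal(b[1], [1, 1, 1, 1])  # ambiguity code N

    def test_cherry_root_vector_jc_closed_form(self, jc):
        # both leaves 'A', t=0.1 each: unscaled root vector at A is P_AA(0.1)^2
        tree = tree_from_string("(A:0.1,B:0.1);")
        aln = Alignment(names=["A", "B"], rows=["A", "A"])
        ext = extend_tree(tree)
        up, logscale = conditional_likelihoods_up(ext, aln, jc)
        root = tree.seed_node
        unscaled = up[id(root)][0] * np.exp(logscale[id(root)][0])
        p_aa = 0.25 + 0.75 * np.exp(-4.0 * 0.1 / 3.0)
        assert unscaled[0] == pytest.approx(p_aa**2, abs=1e-12)
        assert unscaled[0] == pytest.approx(0.821525, abs=1e-6)


class TestMarginalPosteriors:
    def test_rows_are_distributions(self, jc):
        rng = np.random.default_rng(0)
        tree = tree_from_string(TREES[3])
        aln = random_alignment("ABCD", 5, rng, with_gap=True)
        ext = extend_tree(tree)
        post = marginal_posteriors(ext, aln, jc)
        for eid in range(ext.n_edges):
            for P in post.pair(eid):
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
                assert np.all(P >= -1e-15) and np.all(P <= 1 + 1e-12)

    @pytest.mark.parametrize("newick", TREES)
    def test_matches_exhaustive_oracle(self, newick, models):
        """Ghost-node posteriors equal brute-force marginalization on all
        small trees, for JC and a random GTR, at both u_y and v_y."""
        rng = np.random.default_rng(42)
        tree = tree_from_string(newick)
        names = [lf.taxon.label for lf in tree.leaf_node_iter()]
        aln = random_alignment(names, 3, rng, with_gap=True)
        ext = extend_tree(tree)
        for model in models:
            post = marginal_posteriors(ext, aln, model)
            for eid in range(ext.n_edges):
                for which, got in (("u", post.u[eid]), ("v", post.v[eid])):
                    want = exhaustive_ghost_posterior(ext, aln, model, eid, which)
                    np.testing.assert_allclose(got, want, atol=1e-9)

    def test_site_likelihood_node_invariant(self, models):
        """The total site likelihood is the same evaluated at the root or
        through any ghost node (pulley principle for reversible models)."""
        rng = np.random.default_rng(1)
        tree = tree_from_string(TREES[2])
        aln = random_alignment("ABCD", 3, rng)
        ext = extend_tree(tree)
        for model in models:
            post = marginal_posteriors(ext, aln, model)
            at_root = site_loglik_at_root(ext, aln, model)
            np.testing.assert_allclose(post.site_loglik, at_root, atol=1e-9)

    def test_zero_ghost_branch_copies_u(self, jc):
        tree = tree_from_string("((A:0.0,B:0.3):0.2,C:0.4);")
        aln = Alignment(names=["A", "B", "C"], rows=["ACG", "ACG", "ATG"])
        ext = extend_tree(tree)
        eid = ext.edge_by_leafset(frozenset(["A"])).edge_id
        assert ext.edges[eid].ghost_length == 0.0
        post = marginal_posteriors(ext, aln, jc)
        np.testing.assert_allclose(post.u[eid], post.v[eid], atol=1e-15)

    def test_all_gap_site_gives_prior(self, jc):
        tree = tree_from_string("(A:0.2,B:0.4);")
        aln = Alignment(names=["A", "B"], rows=["-A", "-A"])
        ext = extend_tree(tree)
        post = marginal_posteriors(ext, aln, jc)
        np.testing.assert_allclose(post.u[0][0], jc.pi, atol=1e-12)


class TestExternalTable:
    def test_round_trip_and_renormalization(self, tmp_path):
        p = tmp_path / "post.tsv"
        p.write_text(
            "n1\t0\t0.7\t0.1\t0.1\t0.1\n"
            "n1\t1\t0.2\t0.2\t0.2\t0.4\n"
            "n2\t0\t0.5\t0.5\t0.1\t0.1\n"  # sums to 1.2: renormalized
            "n2\t1\t0.25\t0.25\t0.25\t0.25\n"
        )
        with pytest.warns(UserWarning, match="renormaliz"):
            tables = read_posterior_table(p, 4)
        assert set(tables) == {"n1", "n2"}
        np.testing.assert_allclose(tables["n1"][0], [0.7, 0.1, 0.1, 0.1])
        np.testing.assert_allclose(tables["n2"][0].sum(), 1.0)
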