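"""Database construction against brute-force oracles.

The enumeration oracle multiplies out all σ^k per-site probabilities
directly; the database oracle recomputes every S_y(w) by explicit iteration
over windows and ghost nodes.  Neither shares code with the meet-in-the-
middle implementation.
"""

import itertools

import numpy as np
import pytest

from pkplace import db_build
from pkplace.db_build import (
    PhyloKmerDB,
    build_database,
    compute_mi,
    default_epsilon,
    deserialize,
    entry_size,
    enumerate_window_kmers,
    filter_database,
    serialize,
)
from pkplace.posteriors import marginal_posteriors
from pkplace.reference_prep import extend_tree
from pkplace.seqio import Alignment, tree_from_string


def brute_force_window(window, epsilon):
    """All (code, product) pairs with product > ε, by direct expansion."""
    k, sigma = window.shape
    out = {}
    for digits in itertools.product(range(sigma), repeat=k):
        p = 1.0
        for i, d in enumerate(digits):
            p = p * window[i, d]
        if p > epsilon:
            code = 0
            for d in digits:
                code = code * sigma + d
            out[code] = p
    return out


class TestEnumerateWindowKmers:
    def test_worked_example(self):
        window = np.array([[0.7, 0.1, 0.1, 0.1], [0.6, 0.2, 0.1, 0.1]])
        got = dict(enumerate_window_kmers(window, 0.1))
        assert got == {0: pytest.approx(0.42), 1: pytest.approx(0.14)}

    def test_epsilon_at_least_one_gives_empty(self):
        window = np.full((3, 4), 0.25)
        assert enumerate_window_kmers(window, 1.0) == []

    def test_deterministic_window_single_kmer(self):
        window = np.zeros((4, 4))
        for i, d in enumerate([0, 2, 3, 1]):  # A G T C
            window[i, d] = 1.0
        got = enumerate_window_kmers(window, 0.5)
        assert got == [(0 * 64 + 2 * 16 + 3 * 4 + 1, 1.0)]

    @pytest.mark.parametrize(
        "sigma,ks", [(4, (2, 3, 4)), (20, (1, 2))], ids=["dna", "aa"]
    )
    def test_equals_brute_force_random_windows(self, sigma, ks):
        """200 seeded random windows: exact same set and scores as direct
        expansion of all σ^k products."""
        rng = np.random.default_rng(2024)
        for trial in range(200):
            k = ks[trial % len(ks)]
            window = rng.dirichlet(np.ones(sigma) * 0.4, size=k)
            epsilon = float(rng.uniform(0.001, 0.3))
            got = dict(enumerate_window_kmers(window, epsilon))
            want = brute_force_window(window, epsilon)
            assert set(got) == set(want)
            for code, p in want.items():
                assert got[code] == pytest.approx(p, abs=1e-12)


def naive_database(ext, post, k, epsilon):
    """S_y(w) for every branch by explicit window/node iteration."""
    scores = {}
    for rec in ext.edges:
        for P in post.pair(rec.edge_id):
            S = P.shape[0]
            for s in range(S - k + 1):
                for code, p in brute_force_window(P[s : s + k], epsilon).items():
                    key = (code, rec.edge_id)
                    if p > scores.get(key, 0.0):
                        scores[key] = p
    return scores


@pytest.fixture(scope="module")
def tiny_instance(jc):
    tree = tree_from_string("((A:0.2,B:0.4):0.3,C:0.5);")
    aln = Alignment(names=["A", "B", "C"], rows=["ACGTAC", "ACGTGC", "ATGTAC"])
    ext = extend_tree(tree)
    post = marginal_posteriors(ext, aln, jc)
    return ext, post


class TestBuildDatabase:
    def test_matches_naive_recomputation(self, tiny_instance):
        ext, post = tiny_instance
        k = 3
        eps = default_epsilon(k, "DNA")
        db = build_database(ext, post, k=k)
        want = naive_database(ext, post, k, eps)
        got = {
            (code, int(b)): float(s)
            for code, bids, scs in db.items()
            for b, s in zip(bids, scs)
        }
        assert set(got) == set(want)
        for key, p in want.items():
            assert got[key] == pytest.approx(p, abs=1e-12)

    def test_scores_above_epsilon_and_branches_sorted(self, tiny_instance):
        ext, post = tiny_instance
        db = build_database(ext, post, k=3)
        assert db.n_kmers > 0
        for _, bids, scs in db.items():
            assert np.all(scs > db.epsilon)
            assert np.all(np.diff(bids) > 0)

    def test_max_aggregation_across_windows_and_nodes(self, jc):
        # a k-mer seen in several windows / both ghost nodes keeps the max
        tree = tree_from_string("(A:0.05,B:0.05);")
        aln = Alignment(names=["A", "B"], rows=["AAAA", "AAAA"])
        ext = extend_tree(tree)
        post = marginal_posteriors(ext, aln, jc)
        built = build_database(ext, post, k=2)
        got = built.get(0)  # code of "AA"
        for eid in range(ext.n_edges):
            best = max(
                P[s, 0] * P[s + 1, 0]
                for P in post.pair(eid)
                for s in range(3)
            )
            idx = np.where(got[0] == eid)[0]
            assert got[1][idx[0]] == pytest.approx(best, abs=1e-15)

    def test_width_smaller_than_k_errors(self, tiny_instance):
        ext, post = tiny_instance
        with pytest.raises(ValueError, match="smaller than k"):
            build_database(ext, post, k=7)

    def test_default_epsilon_form(self):
        assert default_epsilon(10, "DNA") == pytest.approx((1.5 / 4) ** 10)
        assert default_epsilon(6, "AA") == pytest.approx((1.5 / 20) ** 6)


def make_db(mapping, n_edges=10, epsilon=1e-6, k=3):
    return PhyloKmerDB.from_entries(
        mapping, k=k, n_edges=n_edges, epsilon=epsilon, newick="();"
    )


class TestMutualInformation:
    def test_single_branch_kmer(self):
        """A k-mer on one branch has zero branch entropy: MI = S·ln|E(T)|."""
        db = make_db({5: [(2, 0.5)]})
        compute_mi(db)
        assert db.mi_of(5) == pytest.approx(0.5 * np.log(10), abs=1e-9)
        assert db.mi_of(5) == pytest.approx(1.15129, abs=1e-5)

    def test_uniform_kmer_is_uninformative(self):
        db = make_db({7: [(b, 0.05) for b in range(10)]})
        compute_mi(db)
        assert db.mi_of(7) == pytest.approx(0.0, abs=1e-9)

    def test_mi_linear_in_total_score(self):
        a = make_db({1: [(2, 0.5)], 2: [(b, 0.05) for b in range(10)]})
        b = make_db({1: [(2, 1.0)], 2: [(b, 0.10) for b in range(10)]})
        compute_mi(a)
        compute_mi(b)
        assert b.mi_of(1) == pytest.approx(2 * a.mi_of(1), abs=1e-12)
        assert b.mi_of(2) == pytest.approx(2 * a.mi_of(2), abs=1e-12)


class TestSerialization:
    @pytest.fixture
    def mi_db(self):
        db = make_db(
            {
                3: [(0, 0.9)],                      # high MI
                1: [(b, 0.09) for b in range(10)],  # MI 0
                9: [(1, 0.4), (2, 0.2)],
                12: [(0, 0.9)],                     # ties with code 3
            }
        )
        compute_mi(db)
        return db

    def test_round_trip_full(self, mi_db, tmp_path):
        p = tmp_path / "db.ipk"
        serialize(mi_db, p)
        back = deserialize(p, mu=1.0)
        assert np.array_equal(back.codes, mi_db.codes)
        assert np.array_equal(back.offsets, mi_db.offsets)
        assert np.array_equal(back.branches, mi_db.branches)
        assert np.array_equal(back.scores, mi_db.scores)
        np.testing.assert_allclose(back.mi_values, mi_db.mi_values, atol=1e-12)
        assert back.total_size == mi_db.total_size

    def test_on_disk_order_mi_descending_with_code_ties(self, mi_db, tmp_path):
        order = mi_db.ordered_indices()
        mis = mi_db.mi_values[order]
        assert np.all(np.diff(mis) <= 1e-15)
        # codes 3 and 12 have identical MI; ascending code breaks the tie
        tied = [int(mi_db.codes[i]) for i in order[:2]]
        assert tied == [3, 12]

    def test_mu_just_below_one_drops_lowest_mi_entry(self, mi_db, tmp_path):
        p = tmp_path / "db.ipk"
        serialize(mi_db, p)
        total = mi_db.total_size
        last_size = entry_size(10)  # the uniform k-mer is least informative
        mu = (total - 1) / total
        back = deserialize(p, mu=mu)
        assert back.n_kmers == mi_db.n_kmers - 1
        assert 1 not in back.codes
        assert back.total_size == total - last_size

    def test_partial_loads_are_nested_prefixes(self, mi_db, tmp_path):
        p = tmp_path / "db.ipk"
        serialize(mi_db, p)
        small = deserialize(p, mu=0.3)
        large = deserialize(p, mu=0.8)
        assert set(small.codes) <= set(large.codes)
        # and both are prefixes of the MI ordering
        order_codes = [int(mi_db.codes[i]) for i in mi_db.ordered_indices()]
        assert sorted(small.codes) == sorted(order_codes[: small.n_kmers])
        assert sorted(large.codes) == sorted(order_codes[: large.n_kmers])

    def test_random_filter_matches_in_memory_filter(self, mi_db, tmp_path):
        p = tmp_path / "db.ipk"
        serialize(mi_db, p)
        a = deserialize(p, mu=0.5, mode="random", seed=11)
        b = filter_database(mi_db, 0.5, mode="random", seed=11)
        assert np.array_equal(a.codes, b.codes)
        assert np.array_equal(a.scores, b.scores)

    def test_filter_budget_respected(self, mi_db):
        for mu in (0.25, 0.5, 0.75):
            for mode in ("mi", "random"):
                sub = filter_database(mi_db, mu, mode=mode, seed=0)
                assert sub.total_size <= mu * mi_db.total_size

    def test_total_size_equals_sum_of_entry_sizes(self, mi_db):
        sizes = [entry_size(int(n)) for n in mi_db.tuple_counts()]
        assert mi_db.total_size == sum(sizes)

    def test_corrupt_header_rejected(self, tmp_path):
        p = tmp_path / "bad.ipk"
        p.write_bytes(b"NOPE" + b"\x00" * 64)
        with pytest.raises(ValueError, match="magic"):
            deserialize(p)

    def test_k_mismatch_rejected(self, mi_db, tmp_path):
        p = tmp_path / "db.ipk"
        serialize(mi_db, p)
        with pytest.raises(ValueError, match="k="):
            deserialize(p, expect_k=5)
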