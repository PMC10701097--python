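"""Phylo-k-mer database construction, MI scoring and serialization.

For every branch y and k-mer w, the score S_y(w) is the maximum, over all
windows of k consecutive alignment columns and over the two ghost nodes of
y, of the product of per-site posterior probabilities of w's characters
(sites are treated as independent).  Only scores above the threshold ε are
stored, as a map from k-mer code to (branch, score) tuples.

Enumeration of the ε-probable k-mers of a window uses a meet-in-the-middle
split: all σ^(k/2) half-products are tabulated, the right halves sorted,
and qualifying pairs emitted by a thresholded cross join.  The output is
exactly the brute-force set { w : Π_i P[i][w_i] > ε }.

Informativeness of a k-mer is the mutual information between the branch
variable and the indicator of observing w, up to a factor that does not
depend on w:

    MI(w) = S_w · ( ln|E(T)| + Σ_y (S_y(w)/S_w) · ln(S_y(w)/S_w) ),

with S_w = Σ_y S_y(w).  The database is serialized in MI-descending order
(ties broken by ascending k-mer code), so a prefix of the file is always
the most informative fraction; partial loading reads entries until the next
one would push the cumulative entry size past μ·|D|.

In memory the database is columnar (CSR over code-sorted entries): real
databases hold millions of k-mers and tens of millions of tuples, so all
construction, MI and filtering steps are array operations.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .posteriors import GhostPosteriors
from .reference_prep import ExtendedTree
from .seqio import ALPHABETS, sigma as _sigma

MAGIC = b"PKDB"
FORMAT_VERSION = 1

# header: magic, version, k, sigma, omega, epsilon, n_edges, entry count, |D|
_HEADER_FIXED = struct.Struct("<4sIBBddIQQ")
# entry record: code u64, tuple count u32, (branch u32, score f64)*, MI f64
_ENTRY_HEAD = struct.Struct("<QI")
_TUPLE_DTYPE = np.dtype([("branch", "<u4"), ("score", "<f8")])
_ENTRY_OVERHEAD = _ENTRY_HEAD.size + 8  # code+count before, MI after the tuples


def entry_size(n_tuples: int) -> int:
    """On-disk byte size of one database entry with ``n_tuples`` tuples."""
    return _ENTRY_OVERHEAD + n_tuples * _TUPLE_DTYPE.itemsize


def default_epsilon(k: int, alphabet: str, omega: float = 1.5) -> float:
    """ε = (ω/σ)^k — commensurate across word lengths and alphabets."""
    return (omega / _sigma(alphabet)) ** k


@dataclass
class PhyloKmerDB:
    """Map from k-mer code to per-branch scores, with MI annotations.

    Stored columnar: ``codes`` ascending, ``offsets`` delimiting each
    code's slice of ``branches``/``scores`` (branch ids ascending within an
    entry, every score strictly above ``epsilon``).  ``mi_values`` aligns
    with ``codes`` and is filled by :func:`compute_mi`.  ``total_size``
    (|D|) is the sum of serialized entry sizes, header excluded.
    """

    k: int
    alphabet: str
    omega: float
    epsilon: float
    n_edges: int
    newick: str
    edge_lengths: np.ndarray
    ghost_lengths: np.ndarray
    codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    offsets: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=np.int64))
    branches: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    mi_values: np.ndarray | None = None

    @classmethod
    def from_entries(
        cls,
        mapping: dict[int, list[tuple[int, float]]],
        k: int,
        n_edges: int,
        epsilon: float,
        alphabet: str = "DNA",
        omega: float = 1.5,
        newick: str = "",
        edge_lengths: np.ndarray | None = None,
        ghost_lengths: np.ndarray | None = None,
    ) -> "PhyloKmerDB":
        """Build a database from an explicit {code: [(branch, score)]} map."""
        codes = np.array(sorted(mapping), dtype=np.int64)
        offsets = np.zeros(len(codes) + 1, dtype=np.int64)
        branches: list[int] = []
        scores: list[float] = []
        for i, c in enumerate(codes):
            tups = sorted(mapping[int(c)])
            branches.extend(b for b, _ in tups)
            scores.extend(sc for _, sc in tups)
            offsets[i + 1] = len(branches)
        return cls(
            k=k,
            alphabet=alphabet,
            omega=omega,
            epsilon=epsilon,
            n_edges=n_edges,
            newick=newick,
            edge_lengths=(
                edge_lengths if edge_lengths is not None else np.ones(n_edges)
            ),
            ghost_lengths=(
                ghost_lengths if ghost_lengths is not None else np.ones(n_edges)
            ),
            codes=codes,
            offsets=offsets,
            branches=np.array(branches, dtype=np.int32),
            scores=np.array(scores),
        )

    @property
    def n_kmers(self) -> int:
        return len(self.codes)

    @property
    def n_tuples(self) -> int:
        return len(self.branches)

    @property
    def total_size(self) -> int:
        return _ENTRY_OVERHEAD * self.n_kmers + _TUPLE_DTYPE.itemsize * self.n_tuples

    def tuple_counts(self) -> np.ndarray:
        return np.diff(self.offsets)

    def get(self, code: int) -> tuple[np.ndarray, np.ndarray] | None:
        """(branch_ids, scores) for one k-mer code, or None if absent."""
        i = np.searchsorted(self.codes, code)
        if i == len(self.codes) or self.codes[i] != code:
            return None
        a, b = self.offsets[i], self.offsets[i + 1]
        return self.branches[a:b], self.scores[a:b]

    def items(self):
        """Iterate (code, branch_ids, scores) over all entries."""
        for i, code in enumerate(self.codes):
            a, b = self.offsets[i], self.offsets[i + 1]
            yield int(code), self.branches[a:b], self.scores[a:b]

    def mi_of(self, code: int) -> float:
        if self.mi_values is None:
            raise ValueError("MI values missing; run compute_mi first")
        i = np.searchsorted(self.codes, code)
        if i == len(self.codes) or self.codes[i] != code:
            raise KeyError(code)
        return float(self.mi_values[i])

    def ordered_indices(self) -> np.ndarray:
        """Entry indices in MI-descending order, ties by ascending code."""
        if self.mi_values is None:
            raise ValueError("MI values missing; run compute_mi first")
        return np.lexsort((self.codes, -self.mi_values))

    def subset(self, keep: np.ndarray) -> "PhyloKmerDB":
        """New database with only the entries at indices ``keep``."""
        keep = np.sort(np.asarray(keep, dtype=np.int64))
        counts = self.tuple_counts()[keep]
        new_off = np.zeros(len(keep) + 1, dtype=np.int64)
        np.cumsum(counts, out=new_off[1:])
        idx = np.repeat(self.offsets[keep], counts) + (
            np.arange(new_off[-1]) - np.repeat(new_off[:-1], counts)
        )
        return PhyloKmerDB(
            k=self.k,
            alphabet=self.alphabet,
            omega=self.omega,
            epsilon=self.epsilon,
            n_edges=self.n_edges,
            newick=self.newick,
            edge_lengths=self.edge_lengths,
            ghost_lengths=self.ghost_lengths,
            codes=self.codes[keep],
            offsets=new_off,
            branches=self.branches[idx],
            scores=self.scores[idx],
            mi_values=None if self.mi_values is None else self.mi_values[keep],
        )


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def _half_tables(P: np.ndarray, h: int) -> np.ndarray:
    """Products of every length-``h`` word over every run of ``h`` rows.

    Returns shape (S-h+1, σ^h); entry [s, c] is the product of
    P[s+i, digit_i(c)] with the leftmost character most significant.
    """
    S, s = P.shape
    T = P[: S - h + 1]
    for i in range(1, h):
        T = (T[:, :, None] * P[i : S - h + 1 + i, None, :]).reshape(S - h + 1, -1)
    return T


def _cross_join(
    lvals: np.ndarray,
    r_sorted: np.ndarray,
    r_order: np.ndarray,
    epsilon: float,
    shift: int,
) -> tuple[np.ndarray, np.ndarray]:
    """All (code, product) with left·right > ε.

    ``r_sorted`` is ascending with ``r_order`` the matching right codes;
    ``shift`` = σ^(right half length).  A small slack is applied before an
    exact final filter so borderline products are decided by the product
    itself, not by the division.
    """
    n = len(r_sorted)
    rmax = r_sorted[-1]
    cand = np.nonzero(lvals * rmax > epsilon * (1.0 - 1e-12))[0]
    if len(cand) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    cut = epsilon / lvals[cand] * (1.0 - 1e-12)
    start = np.searchsorted(r_sorted, cut, side="right")
    counts = n - start
    keep = counts > 0
    cand, start, counts = cand[keep], start[keep], counts[keep]
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    rpos = np.repeat(start, counts) + within
    probs = np.repeat(lvals[cand], counts) * r_sorted[rpos]
    codes = np.repeat(cand.astype(np.int64) * shift, counts) + r_order[rpos]
    exact = probs > epsilon
    return codes[exact], probs[exact]


def enumerate_window_kmers(
    window: np.ndarray, epsilon: float
) -> list[tuple[int, float]]:
    """All k-mers of one k×σ window with product probability > ε.

    Rows of ``window`` are per-site state distributions.  The returned
    (code, probability) set equals brute force over all σ^k products.
    """
    window = np.asarray(window, dtype=float)
    k, s = window.shape
    if epsilon >= 1.0:
        return []
    h1 = k // 2
    h2 = k - h1
    if h1 == 0:
        codes = np.nonzero(window[0] > epsilon)[0]
        return [(int(c), float(window[0][c])) for c in codes]
    left = _half_tables(window[:h1], h1)[0]
    right = _half_tables(window[h1:], h2)[0]
    order = np.argsort(right, kind="stable")
    codes, probs = _cross_join(left, right[order], order, epsilon, s**h2)
    return [(int(c), float(p)) for c, p in zip(codes, probs)]


def _node_kmers(P: np.ndarray, k: int, epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    """ε-probable (code, prob) pairs over all sliding windows of one node."""
    S, s = P.shape
    W = S - k + 1
    h1, h2 = k // 2, k - k // 2
    if h1 == 0:
        codes_all, probs_all = [], []
        for w in range(W):
            c = np.nonzero(P[w] > epsilon)[0]
            codes_all.append(c.astype(np.int64))
            probs_all.append(P[w][c])
        return np.concatenate(codes_all), np.concatenate(probs_all)
    # windows whose best possible product is already <= ε produce nothing
    logmax = np.log(P.max(axis=1))
    cs = np.concatenate([[0.0], np.cumsum(logmax)])
    window_best = cs[k:] - cs[:-k]
    active = np.nonzero(window_best > np.log(epsilon) - 1e-9)[0]
    if len(active) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    T1 = _half_tables(P, h1)
    T2 = _half_tables(P, h2)
    order = np.argsort(T2, axis=1, kind="stable")
    T2_sorted = np.take_along_axis(T2, order, axis=1)
    shift = s**h2
    codes_all, probs_all = [], []
    for w in active:
        codes, probs = _cross_join(
            T1[w], T2_sorted[w + h1], order[w + h1], epsilon, shift
        )
        if len(codes):
            codes_all.append(codes)
            probs_all.append(probs)
    if not codes_all:
        return np.empty(0, dtype=np.int64), np.empty(0)
    return np.concatenate(codes_all), np.concatenate(probs_all)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

_DENSE_LIMIT = 1 << 26  # fall back to sorting above this many possible codes


@njit(cache=True)
def _build_table(P, h, T):
    """Fill T[w, c] with the product of P[w+i, digit_i(c)] in place."""
    W = P.shape[0] - h + 1
    s = P.shape[1]
    for w in range(W):
        for j in range(s):
            T[w, j] = P[w, j]
        cur = s
        for i in range(1, h):
            # expand backwards so reads stay ahead of writes
            for c in range(cur - 1, -1, -1):
                v = T[w, c]
                off = c * s
                for j in range(s - 1, -1, -1):
                    T[w, off + j] = v * P[w + i, j]
            cur *= s
    return W


@njit(cache=True)
def _emit_node_dense(T1, T2_sorted, order2, active, h1, epsilon, shift, dense, touched, n_touched):
    """Enumerate ε-probable window k-mers of one node, max-accumulating
    into the dense per-code score table; returns the touched-code count."""
    W = active.shape[0]
    m1 = T1.shape[1]
    m2 = T2_sorted.shape[1]
    slack = epsilon * (1.0 - 1e-12)
    for w in range(W):
        if not active[w]:
            continue
        lrow = T1[w]
        rrow = T2_sorted[w + h1]
        orow = order2[w + h1]
        rmax = rrow[m2 - 1]
        for i in range(m1):
            l = lrow[i]
            if l * rmax <= slack:
                continue
            cutoff = epsilon / l * (1.0 - 1e-12)
            lo = 0
            hi = m2
            while lo < hi:
                mid = (lo + hi) // 2
                if rrow[mid] <= cutoff:
                    lo = mid + 1
                else:
                    hi = mid
            base = i * shift
            for j in range(lo, m2):
                p = l * rrow[j]
                if p > epsilon:
                    code = base + orow[j]
                    if p > dense[code]:
                        if dense[code] == 0.0:
                            touched[n_touched] = code
                            n_touched += 1
                        dense[code] = p
    return n_touched


@njit(cache=True)
def _extract_dense(dense, touched, n, out_codes, out_scores):
    for idx in range(n):
        c = touched[idx]
        out_codes[idx] = c
        out_scores[idx] = dense[c]
        dense[c] = 0.0


def build_database(
    ext_tree: ExtendedTree,
    posteriors: GhostPosteriors,
    k: int,
    epsilon: float | None = None,
    omega: float = 1.5,
    alphabet: str = "DNA",
) -> PhyloKmerDB:
    """Assemble the phylo-k-mer database (MI not yet computed).

    Per branch, scores from the two ghost nodes and all windows are reduced
    by maximum; entries keep only scores strictly above ε.
    """
    some = next(iter(posteriors.u.values()))
    S = some.shape[0]
    if S < k:
        raise ValueError(f"alignment width {S} is smaller than k={k}")
    if epsilon is None:
        epsilon = default_epsilon(k, alphabet, omega)
    s = _sigma(alphabet)
    n_codes = s**k
    h1, h2 = k // 2, k - k // 2

    per_edge: list[tuple[int, np.ndarray, np.ndarray]] = []
    if n_codes <= _DENSE_LIMIT and h1 >= 1:
        dense = np.zeros(n_codes)
        touched = np.empty(n_codes, dtype=np.int64)
        shift = s**h2
        log_eps = np.log(epsilon)
        # scratch buffers reused across all ghost nodes
        T1 = np.empty((S - h1 + 1, s**h1))
        T2 = T1 if h1 == h2 else np.empty((S - h2 + 1, s**h2))
        for rec in ext_tree.edges:
            n_t = 0
            for P in posteriors.pair(rec.edge_id):
                logmax = np.log(P.max(axis=1))
                cs = np.concatenate([[0.0], np.cumsum(logmax)])
                active = (cs[k:] - cs[:-k] > log_eps - 1e-9).astype(np.uint8)
                if not active.any():
                    continue
                _build_table(P, h1, T1)
                if h2 != h1:
                    _build_table(P, h2, T2)
                order2 = np.argsort(T2, axis=1)
                T2_sorted = np.take_along_axis(T2, order2, axis=1)
                n_t = _emit_node_dense(
                    T1, T2_sorted, order2, active, h1, epsilon, shift,
                    dense, touched, n_t,
                )
            if n_t == 0:
                continue
            codes_e = np.empty(n_t, dtype=np.int64)
            scores_e = np.empty(n_t)
            _extract_dense(dense, touched, n_t, codes_e, scores_e)
            per_edge.append((rec.edge_id, codes_e, scores_e))
    else:
        for rec in ext_tree.edges:
            parts = [_node_kmers(P, k, epsilon) for P in posteriors.pair(rec.edge_id)]
            codes = np.concatenate([c for c, _ in parts])
            probs = np.concatenate([p for _, p in parts])
            if len(codes) == 0:
                continue
            order = np.argsort(codes, kind="stable")
            codes_s = codes[order]
            probs_s = probs[order]
            first = np.concatenate([[True], codes_s[1:] != codes_s[:-1]])
            uniq = codes_s[first]
            maxima = np.maximum.reduceat(probs_s, np.nonzero(first)[0])
            per_edge.append((rec.edge_id, uniq, maxima))

    db = PhyloKmerDB(
        k=k,
        alphabet=alphabet,
        omega=omega,
        epsilon=epsilon,
        n_edges=ext_tree.n_edges,
        newick=ext_tree.edge_numbered_newick(),
        edge_lengths=np.array([e.length for e in ext_tree.edges]),
        ghost_lengths=np.array([e.ghost_length for e in ext_tree.edges]),
    )
    if not per_edge:
        return db

    if n_codes <= _DENSE_LIMIT:
        # dense per-code slot table; edges processed in ascending id, so
        # branch ids come out sorted within each entry without a global sort
        counts = np.zeros(n_codes, dtype=np.int64)
        for _, uniq, _ in per_edge:
            counts[uniq] += 1
        starts = np.cumsum(counts) - counts
        total = int(counts.sum())
        branches = np.empty(total, dtype=np.int32)
        scores = np.empty(total)
        slot = starts.copy()
        for eid, uniq, maxima in per_edge:
            pos = slot[uniq]
            branches[pos] = eid
            scores[pos] = maxima
            slot[uniq] = pos + 1
        present = np.nonzero(counts)[0]
        offsets = np.zeros(len(present) + 1, dtype=np.int64)
        np.cumsum(counts[present], out=offsets[1:])
        db.codes = present.astype(np.int64)
        db.offsets = offsets
        db.branches = branches
        db.scores = scores
    else:
        codes_all = np.concatenate([u for _, u, _ in per_edge])
        branch_all = np.concatenate(
            [np.full(len(u), eid, dtype=np.int32) for eid, u, _ in per_edge]
        )
        score_all = np.concatenate([m for _, _, m in per_edge])
        order = np.lexsort((branch_all, codes_all))
        codes_all = codes_all[order]
        first = np.concatenate([[True], codes_all[1:] != codes_all[:-1]])
        db.codes = codes_all[first]
        starts = np.nonzero(first)[0]
        db.offsets = np.concatenate([starts, [len(codes_all)]]).astype(np.int64)
        db.branches = branch_all[order]
        db.scores = score_all[order]
    return db


def compute_mi(db: PhyloKmerDB) -> np.ndarray:
    """Per-k-mer mutual information; stored on the database and returned.

    The branch sum runs over the stored tuples only; branches whose score
    fell below ε contribute nothing to S_w.  A k-mer concentrated on one
    branch scores S_w·ln|E(T)|; one spread uniformly over all branches
    scores 0.
    """
    if db.n_kmers == 0:
        db.mi_values = np.empty(0)
        return db.mi_values
    starts = db.offsets[:-1]
    sw = np.add.reduceat(db.scores, starts)
    slogs = np.add.reduceat(db.scores * np.log(db.scores), starts)
    mi = sw * np.log(db.n_edges) + slogs - sw * np.log(sw)
    db.mi_values = mi
    return mi


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def serialize(db: PhyloKmerDB, path: str | Path) -> None:
    """Write the database with entries in MI-descending order."""
    order = db.ordered_indices()
    counts = db.tuple_counts()
    newick_bytes = db.newick.encode("utf-8")
    tuples = np.empty(db.n_tuples, dtype=_TUPLE_DTYPE)
    tuples["branch"] = db.branches
    tuples["score"] = db.scores
    tuple_bytes = tuples.tobytes()
    ts = _TUPLE_DTYPE.itemsize
    with open(path, "wb") as fh:
        fh.write(
            _HEADER_FIXED.pack(
                MAGIC,
                FORMAT_VERSION,
                db.k,
                _sigma(db.alphabet),
                db.omega,
                db.epsilon,
                db.n_edges,
                db.n_kmers,
                db.total_size,
            )
        )
        fh.write(struct.pack("<I", len(newick_bytes)))
        fh.write(newick_bytes)
        fh.write(db.edge_lengths.astype("<f8").tobytes())
        fh.write(db.ghost_lengths.astype("<f8").tobytes())
        buf = bytearray(db.total_size)
        pos = 0
        pack_head = _ENTRY_HEAD.pack_into
        pack_mi = struct.Struct("<d").pack_into
        for i in order:
            n = int(counts[i])
            pack_head(buf, pos, int(db.codes[i]), n)
            pos += _ENTRY_HEAD.size
            a = int(db.offsets[i]) * ts
            buf[pos : pos + n * ts] = tuple_bytes[a : a + n * ts]
            pos += n * ts
            pack_mi(buf, pos, float(db.mi_values[i]))
            pos += 8
        fh.write(buf)


def _read_header(fh):
    head = fh.read(_HEADER_FIXED.size)
    if len(head) < _HEADER_FIXED.size:
        raise ValueError("truncated database header")
    magic, version, k, sig, omega, epsilon, n_edges, n_entries, total_size = (
        _HEADER_FIXED.unpack(head)
    )
    if magic != MAGIC:
        raise ValueError("not a phylo-k-mer database (bad magic bytes)")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported database format version {version}")
    alphabet = {len(chars): a for a, chars in ALPHABETS.items()}[sig]
    (nwlen,) = struct.unpack("<I", fh.read(4))
    newick = fh.read(nwlen).decode("utf-8")
    edge_lengths = np.frombuffer(fh.read(8 * n_edges), dtype="<f8").copy()
    ghost_lengths = np.frombuffer(fh.read(8 * n_edges), dtype="<f8").copy()
    return (
        k,
        alphabet,
        omega,
        epsilon,
        n_edges,
        n_entries,
        total_size,
        newick,
        edge_lengths,
        ghost_lengths,
    )


def deserialize(
    path: str | Path,
    mu: float = 1.0,
    mode: str = "mi",
    seed: int | None = None,
    byte_budget: int | None = None,
    expect_k: int | None = None,
) -> PhyloKmerDB:
    """Load the database, optionally only its most informative fraction.

    With ``mode='mi'`` entries are read in file order (MI-descending) and
    reading stops before the entry that would push the cumulative entry
    size past μ·|D| — so the load for μ' < μ is a prefix of the load for μ.
    ``mode='random'`` keeps k-mers in a seeded random order instead, up to
    the same budget (the baseline filter).  An explicit ``byte_budget``
    overrides μ·|D|.
    """
    if not 0.0 < mu <= 1.0:
        raise ValueError("mu must be in (0, 1]")
    if mode not in ("mi", "random"):
        raise ValueError("mode must be 'mi' or 'random'")
    with open(path, "rb") as fh:
        (
            k,
            alphabet,
            omega,
            epsilon,
            n_edges,
            n_entries,
            total_size,
            newick,
            edge_lengths,
            ghost_lengths,
        ) = _read_header(fh)
        if expect_k is not None and k != expect_k:
            raise ValueError(f"database was built with k={k}, requested k={expect_k}")
        payload = fh.read(total_size)
    if len(payload) < total_size:
        raise ValueError("truncated database payload")
    budget = byte_budget if byte_budget is not None else mu * total_size

    # walk the variable-length records once, collecting offsets
    ts = _TUPLE_DTYPE.itemsize
    head = _ENTRY_HEAD.size
    offs = np.empty(n_entries, dtype=np.int64)
    ntups = np.empty(n_entries, dtype=np.int64)
    mv = memoryview(payload)
    pos = 0
    n_read = 0
    limit = budget if mode == "mi" else float("inf")
    used = 0
    for i in range(n_entries):
        n = int.from_bytes(mv[pos + 8 : pos + 12], "little")
        sz = _ENTRY_OVERHEAD + n * ts
        if mode == "mi":
            if used + sz > limit:
                break
            used += sz
        offs[i] = pos
        ntups[i] = n
        pos += sz
        n_read += 1
    offs = offs[:n_read]
    ntups = ntups[:n_read]

    if mode == "random" and n_read:
        rng = np.random.default_rng(seed)
        order = rng.permutation(n_read)
        sizes = _ENTRY_OVERHEAD + ntups[order] * ts
        cum = np.cumsum(sizes)
        stop = int(np.searchsorted(cum, budget, side="right"))
        sel = np.sort(order[:stop])
        offs, ntups = offs[sel], ntups[sel]
        n_read = len(sel)

    raw = np.frombuffer(payload, dtype=np.uint8)
    codes = _gather_scalar(raw, offs, 8, "<u8").astype(np.int64)
    mi_vals = _gather_scalar(raw, offs + head + ntups * ts, 8, "<f8")
    total_tuples = int(ntups.sum())
    tup_buf = np.empty(total_tuples * ts, dtype=np.uint8)
    dst = 0
    for o, n in zip(offs.tolist(), ntups.tolist()):
        nb = n * ts
        tup_buf[dst : dst + nb] = raw[o + head : o + head + nb]
        dst += nb
    tuples = tup_buf.view(_TUPLE_DTYPE)
    branches = tuples["branch"].astype(np.int32)
    scores = tuples["score"].astype(np.float64)

    # re-sort entries by code for in-memory lookup
    offsets = np.zeros(n_read + 1, dtype=np.int64)
    np.cumsum(ntups, out=offsets[1:])
    db = PhyloKmerDB(
        k=k,
        alphabet=alphabet,
        omega=omega,
        epsilon=epsilon,
        n_edges=n_edges,
        newick=newick,
        edge_lengths=edge_lengths,
        ghost_lengths=ghost_lengths,
        codes=codes,
        offsets=offsets,
        branches=branches,
        scores=scores,
        mi_values=mi_vals,
    )
    return _resort_by_code(db)


def _gather_scalar(raw: np.ndarray, offs: np.ndarray, width: int, dtype) -> np.ndarray:
    if len(offs) == 0:
        return np.empty(0, dtype=dtype)
    idx = offs[:, None] + np.arange(width)
    return raw[idx].reshape(-1).view(dtype).copy()


def _resort_by_code(db: PhyloKmerDB) -> PhyloKmerDB:
    if db.n_kmers <= 1 or np.all(db.codes[1:] > db.codes[:-1]):
        return db
    order = np.argsort(db.codes, kind="stable")
    counts = db.tuple_counts()[order]
    new_off = np.zeros(len(order) + 1, dtype=np.int64)
    np.cumsum(counts, out=new_off[1:])
    idx = np.repeat(db.offsets[:-1][order], counts) + (
        np.arange(new_off[-1]) - np.repeat(new_off[:-1], counts)
    )
    db.codes = db.codes[order]
    db.offsets = new_off
    db.branches = db.branches[idx]
    db.scores = db.scores[idx]
    if db.mi_values is not None:
        db.mi_values = db.mi_values[order]
    return db


def filter_database(
    db: PhyloKmerDB, mu: float, mode: str = "mi", seed: int | None = None
) -> PhyloKmerDB:
    """In-memory counterpart of partial loading (same bookkeeping and, for
    the random filter, the same seeded selection as :func:`deserialize`)."""
    if not 0.0 < mu <= 1.0:
        raise ValueError("mu must be in (0, 1]")
    if mode == "mi":
        order = db.ordered_indices()
    elif mode == "random":
        file_order = db.ordered_indices()
        rng = np.random.default_rng(seed)
        order = file_order[rng.permutation(len(file_order))]
    else:
        raise ValueError("mode must be 'mi' or 'random'")
    ts = _TUPLE_DTYPE.itemsize
    sizes = _ENTRY_OVERHEAD + db.tuple_counts()[order] * ts
    budget = mu * db.total_size
    cum = np.cumsum(sizes)
    stop = int(np.searchsorted(cum, budget, side="right"))
    return db.subset(order[:stop])
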