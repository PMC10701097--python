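"""Alignment-free placement of query reads against a phylo-k-mer database.

The log-score of placing query q on branch y is

    ℓ_y(q) = (1/k) · Σ_i max{ log_b ε, log_b S_y(w_i) }

over all k-mers w_i of q; a branch absent from a k-mer's tuple list
contributes log_b ε for it.  The 1/k factor compensates for each query
character appearing in (up to) k overlapping k-mers, so ℓ approximates the
per-character log-probability of q diverging from y.  Reported branches
carry likelihood weight ratios LWR(q,y) = b^ℓ_y / Σ_x b^ℓ_x, normalized
over *all* branches of the tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .db_build import PhyloKmerDB
from .seqio import DNA, UnencodableKmer, encode_kmer, reverse_complement


@dataclass
class ScoringConfig:
    """Placement scoring parameters.

    ``b`` is the logarithm base used both in ℓ and in the LWR (the LWR is
    base-invariant only if the same base is used consistently; 10 is fixed
    as the package default).  ``n_top`` bounds the number of reported
    branches per query; ``use_revcomp`` scores DNA queries in both
    orientations and keeps the better one.
    """

    k: int
    epsilon: float
    b: float = 10.0
    n_top: int = 7
    use_revcomp: bool | None = None

    def __post_init__(self) -> None:
        if self.b <= 1:
            raise ValueError("log base must be > 1")
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")

    @classmethod
    def for_db(cls, db: PhyloKmerDB, **kwargs) -> "ScoringConfig":
        cfg = cls(k=db.k, epsilon=db.epsilon, **kwargs)
        if cfg.use_revcomp is None:
            cfg.use_revcomp = db.alphabet == DNA
        return cfg


@dataclass
class PlacementResult:
    """Ranked placement of one query.

    ``branch_ids``/``scores``/``lwr`` are the top branches by ℓ descending
    (ties by ascending branch id); LWRs are normalized over all branches, so
    a truncated report sums to ≤ 1.  ``unplaced`` marks queries with no
    encodable k-mer.
    """

    name: str
    branch_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    lwr: np.ndarray = field(default_factory=lambda: np.empty(0))
    distal: np.ndarray = field(default_factory=lambda: np.empty(0))
    pendant: np.ndarray = field(default_factory=lambda: np.empty(0))
    unplaced: bool = False

    @property
    def best_branch(self) -> int | None:
        return None if self.unplaced else int(self.branch_ids[0])

    def jplace_rows(self) -> list[list]:
        if self.unplaced:
            return []
        return [
            [int(b), float(s), float(w), float(d), float(p)]
            for b, s, w, d, p in zip(
                self.branch_ids, self.scores, self.lwr, self.distal, self.pendant
            )
        ]


def extract_query_kmers(seq: str, k: int, alphabet: str = DNA) -> list[int]:
    """Codes of all |q|−k+1 windows, skipping windows with unencodable
    characters (ambiguity codes, gaps); order preserved."""
    seq = seq.upper()
    out: list[int] = []
    for i in range(len(seq) - k + 1):
        try:
            out.append(encode_kmer(seq[i : i + k], alphabet))
        except UnencodableKmer:
            continue
    return out


def score_query(
    kmers: list[int], db: PhyloKmerDB, cfg: ScoringConfig
) -> np.ndarray:
    """ℓ_y(q) for every branch y of the tree (including unmatched ones)."""
    if not kmers:
        raise ValueError("query has no valid k-mers")
    log_b = math.log(cfg.b)
    log_eps = math.log(cfg.epsilon) / log_b
    ell = np.full(db.n_edges, len(kmers) * log_eps)
    codes = np.asarray(kmers, dtype=np.int64)
    if len(db.codes):
        pos = np.minimum(np.searchsorted(db.codes, codes), len(db.codes) - 1)
        hits = np.nonzero(db.codes[pos] == codes)[0]
        for i in hits:
            a, b = db.offsets[pos[i]], db.offsets[pos[i] + 1]
            ell[db.branches[a:b]] += np.log(db.scores[a:b]) / log_b - log_eps
    ell /= cfg.k
    return ell


def lwr(scores: np.ndarray, b: float = 10.0) -> np.ndarray:
    """Likelihood weight ratios: b^ℓ normalized over all branches.

    Computed by subtracting the maximum before exponentiation, so the
    weights are shift-invariant and sum to 1 even for very negative ℓ.
    """
    scores = np.asarray(scores, dtype=float)
    w = np.power(b, scores - scores.max())
    return w / w.sum()


def place_query(
    name: str, seq: str, db: PhyloKmerDB, cfg: ScoringConfig
) -> PlacementResult:
    """Place one query; with ``use_revcomp`` the better orientation wins."""
    kmers = extract_query_kmers(seq, cfg.k, db.alphabet)
    ell = None
    if kmers:
        ell = score_query(kmers, db, cfg)
    if cfg.use_revcomp:
        rc_kmers = extract_query_kmers(reverse_complement(seq), cfg.k, db.alphabet)
        if rc_kmers:
            rc_ell = score_query(rc_kmers, db, cfg)
            if ell is None or rc_ell.max() > ell.max():
                ell = rc_ell
    if ell is None:
        return PlacementResult(name=name, unplaced=True)
    weights = lwr(ell, cfg.b)
    # rank by score descending, ties by ascending branch id
    order = np.lexsort((np.arange(db.n_edges), -ell))[: cfg.n_top]
    return PlacementResult(
        name=name,
        branch_ids=order.astype(np.int64),
        scores=ell[order],
        lwr=weights[order],
        distal=db.edge_lengths[order] / 2.0,
        pendant=db.ghost_lengths[order],
    )


def place_batch(
    queries: list[tuple[str, str]],
    db: PhyloKmerDB,
    cfg: ScoringConfig | None = None,
    jplace_path=None,
) -> list[PlacementResult]:
    """Place queries independently; optionally write a jplace file.

    Results do not depend on query order or batch partitioning.  Unplaced
    queries appear in the jplace output with an empty placement row set.
    """
    if cfg is None:
        cfg = ScoringConfig.for_db(db)
    results = [place_query(name, seq, db, cfg) for name, seq in queries]
    if jplace_path is not None:
        from .seqio import write_jplace

        write_jplace(results, db.newick, jplace_path)
    return results
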