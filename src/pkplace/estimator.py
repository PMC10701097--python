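"""Scikit-learn-style estimator facade over the build/place pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import db_build, placement
from .posteriors import marginal_posteriors
from .reference_prep import extend_tree, filter_gap_columns
from .seqio import Alignment, DNA
from .substitution import SubstitutionModel, get_model


class PhyloKmerPlacer(BaseEstimator):
    """Alignment-free phylogenetic placement via a phylo-k-mer database.

    ``fit`` builds the database from a reference alignment and rooted
    reference tree (gap filtering, ghost-node posteriors, ε-thresholded
    k-mer enumeration, MI computation); ``predict`` returns the top-scoring
    branch id for each query read, and ``place`` the full ranked results.

    Parameters
    ----------
    k : word length in residues; defaults to 10 for DNA and 6 for AA.
    omega : sets the score threshold ε = (ω/σ)^k unless ``epsilon`` is given.
    epsilon : explicit probability threshold, overrides ``omega``.
    model : substitution model name ("JC69", "Poisson") or a
        :class:`~pkplace.substitution.SubstitutionModel`.
    gap_ratio : columns with a gap fraction >= this are dropped.
    mu : fraction of the database (by serialized size) retained after MI
        filtering; 1.0 keeps everything.
    filter : "mi" (most informative first) or "random" (baseline).
    b : logarithm base for placement scores and LWR.
    n_top : number of branches reported per query.
    use_revcomp : score DNA queries in both orientations (default: DNA only).
    random_state : seed for the random filter.

    Attributes
    ----------
    db_ : the (possibly μ-filtered) :class:`~pkplace.db_build.PhyloKmerDB`.
    ext_tree_ : the edge-numbered reference tree with ghost geometry.
    n_edges_ : number of original branches (placement classes).
    """

    def __init__(
        self,
        k: int | None = None,
        omega: float = 1.5,
        epsilon: float | None = None,
        model: str | SubstitutionModel = "JC69",
        gap_ratio: float = 0.99,
        mu: float = 1.0,
        filter: str = "mi",
        b: float = 10.0,
        n_top: int = 7,
        use_revcomp: bool | None = None,
        random_state: int | None = None,
    ):
        self.k = k
        self.omega = omega
        self.epsilon = epsilon
        self.model = model
        self.gap_ratio = gap_ratio
        self.mu = mu
        self.filter = filter
        self.b = b
        self.n_top = n_top
        self.use_revcomp = use_revcomp
        self.random_state = random_state

    def fit(self, alignment: Alignment, tree) -> "PhyloKmerPlacer":
        """Build the phylo-k-mer database from the reference data."""
        model = self.model if isinstance(self.model, SubstitutionModel) else get_model(self.model)
        if model.alphabet != alignment.alphabet:
            raise ValueError("model alphabet does not match alignment alphabet")
        k = self.k if self.k is not None else (10 if alignment.alphabet == DNA else 6)
        filtered, colmap = filter_gap_columns(alignment, self.gap_ratio)
        ext = extend_tree(tree)
        post = marginal_posteriors(ext, filtered, model)
        db = db_build.build_database(
            ext,
            post,
            k=k,
            epsilon=self.epsilon,
            omega=self.omega,
            alphabet=alignment.alphabet,
        )
        db_build.compute_mi(db)
        if self.mu < 1.0:
            db = db_build.filter_database(db, self.mu, self.filter, self.random_state)
        self.k_ = k
        self.column_map_ = colmap
        self.ext_tree_ = ext
        self.db_ = db
        self.n_edges_ = db.n_edges
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "db_"):
            raise RuntimeError("PhyloKmerPlacer is not fitted; call fit first")

    def _config(self) -> placement.ScoringConfig:
        return placement.ScoringConfig.for_db(
            self.db_, b=self.b, n_top=self.n_top, use_revcomp=self.use_revcomp
        )

    def place(self, queries, jplace_path=None) -> list[placement.PlacementResult]:
        """Full ranked placements for (name, sequence) pairs."""
        self._check_fitted()
        return placement.place_batch(
            list(queries), self.db_, self._config(), jplace_path=jplace_path
        )

    def predict(self, queries) -> np.ndarray:
        """Top-scoring branch id per query (-1 for unplaced reads)."""
        results = self.place(queries)
        return np.array(
            [r.best_branch if not r.unplaced else -1 for r in results], dtype=np.int64
        )

    def predict_lwr(self, queries) -> np.ndarray:
        """Likelihood weight ratio of the reported top branch per query."""
        results = self.place(queries)
        return np.array(
            [r.lwr[0] if not r.unplaced else np.nan for r in results]
        )
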