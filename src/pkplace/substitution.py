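"""Time-reversible substitution models and transition probabilities.

A model is given by stationary frequencies π and symmetric exchangeabilities
R; the rate matrix Q_ij = R_ij·π_j (i≠j) is normalized so that the expected
number of substitutions per unit branch length is 1, i.e. −Σ_i π_i Q_ii = 1.
P(t) = exp(Qt) is evaluated through the eigendecomposition of the
π-symmetrized matrix, which is real-symmetric for any reversible model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import AA, DNA, ALPHABETS, sigma


@dataclass
class SubstitutionModel:
    name: str
    alphabet: str
    pi: np.ndarray
    exchangeabilities: np.ndarray  # symmetric, zero diagonal
    Q: np.ndarray = field(init=False, repr=False)
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        s = sigma(self.alphabet)
        self.pi = np.asarray(self.pi, dtype=float)
        R = np.asarray(self.exchangeabilities, dtype=float)
        if self.pi.shape != (s,) or R.shape != (s, s):
            raise ValueError("pi/exchangeability shapes do not match alphabet size")
        if np.any(self.pi <= 0) or not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("stationary frequencies must be positive and sum to 1")
        if not np.allclose(R, R.T):
            raise ValueError("exchangeability matrix must be symmetric")
        self.pi = self.pi / self.pi.sum()
        Q = R * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -np.dot(self.pi, np.diag(Q))
        if mean_rate <= 0:
            raise ValueError("degenerate rate matrix")
        self.Q = Q / mean_rate
        # symmetrize: B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
        sq = np.sqrt(self.pi)
        B = (sq[:, None] * self.Q) / sq[None, :]
        B = (B + B.T) / 2.0
        w, V = np.linalg.eigh(B)
        self._eig = (w, sq[:, None] ** -1 * V, V.T * sq[None, :])

    @property
    def n_states(self) -> int:
        return len(self.pi)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are probability distributions."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        w, L, Rm = self._eig
        P = (L * np.exp(w * t)[None, :]) @ Rm
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    return model.transition_matrix(t)


def jc69() -> SubstitutionModel:
    """Jukes–Cantor: uniform frequencies and exchangeabilities (DNA)."""
    R = np.ones((4, 4)) - np.eye(4)
    return SubstitutionModel("JC69", DNA, np.full(4, 0.25), R)


def gtr(pi, rates) -> SubstitutionModel:
    """General time-reversible DNA model.

    ``rates`` are the six exchangeabilities in the order
    (AC, AG, AT, CG, CT, GT).
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (6,) or np.any(rates <= 0):
        raise ValueError("gtr expects six positive exchangeabilities")
    R = np.zeros((4, 4))
    R[0, 1], R[0, 2], R[0, 3] = rates[0], rates[1], rates[2]
    R[1, 2], R[1, 3] = rates[3], rates[4]
    R[2, 3] = rates[5]
    R = R + R.T
    return SubstitutionModel("GTR", DNA, pi, R)


def poisson_aa() -> SubstitutionModel:
    """Uniform-rate amino acid model (all exchanges equally likely)."""
    s = sigma(AA)
    R = np.ones((s, s)) - np.eye(s)
    return SubstitutionModel("Poisson", AA, np.full(s, 1.0 / s), R)


def general_aa(pi, exchangeabilities, name: str = "customAA") -> SubstitutionModel:
    """Empirical-style amino acid model from user-supplied π and symmetric R."""
    return SubstitutionModel(name, AA, pi, exchangeabilities)


_FACTORIES = {"JC69": jc69, "POISSON": poisson_aa}


def get_model(name: str) -> SubstitutionModel:
    """Look up a parameter-free model by name (``JC69`` or ``Poisson``)."""
    try:
        return _FACTORIES[name.upper()]()
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; parameterized models (GTR, custom AA) "
            "must be constructed explicitly"
        ) from None
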