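"""The JTT amino-acid substitution model.

Builds the reversible rate matrix Q from the packaged exchangeabilities and
equilibrium frequencies, scaled so that one unit of branch length equals one
expected substitution per site, and exposes transition-probability matrices
P(t) = exp(Qt) through a cached spectral decomposition.
"""

from __future__ import annotations

import numpy as np

from ._jtt_data import JTT_EXCHANGE, JTT_FREQS, JTT_ORDER

ORDER = JTT_ORDER
_INDEX = {aa: i for i, aa in enumerate(ORDER)}


def equilibrium_frequencies() -> np.ndarray:
    """Equilibrium residue frequencies pi (PAML residue order)."""
    return np.asarray(JTT_FREQS, dtype=float)


def rate_matrix() -> np.ndarray:
    """The JTT rate matrix Q, scaled to 1 expected substitution per unit t.

    Q_ij = s_ij * pi_j for i != j; rows sum to zero; -sum_i pi_i Q_ii = 1.
    """
    S = np.asarray(JTT_EXCHANGE, dtype=float)
    pi = equilibrium_frequencies()
    Q = S * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(20)] = -Q.sum(axis=1)
    scale = -float(pi @ np.diag(Q))
    return Q / scale


class _Spectral:
    """Cached symmetric eigendecomposition of Q for fast exp(Qt)."""

    def __init__(self) -> None:
        Q = rate_matrix()
        pi = equilibrium_frequencies()
        d = np.sqrt(pi)
        B = (Q * d[:, np.newaxis]) / d[np.newaxis, :]  # similar symmetric matrix
        B = (B + B.T) / 2.0
        self.eigval, self.eigvec = np.linalg.eigh(B)
        self.d = d

    def probability_matrix(self, t: float) -> np.ndarray:
        E = self.eigvec * np.exp(self.eigval * t)[np.newaxis, :]
        P = E @ self.eigvec.T
        P *= self.d[np.newaxis, :] / self.d[:, np.newaxis]
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


_SPECTRAL: _Spectral | None = None


def probability_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows are probability distributions."""
    if t < 0:
        raise ValueError("divergence t must be non-negative")
    global _SPECTRAL
    if _SPECTRAL is None:
        _SPECTRAL = _Spectral()
    return _SPECTRAL.probability_matrix(float(t))


def encode(seq: str) -> np.ndarray:
    """Map a residue string (standard 20 letters) to JTT indices; X -> -1."""
    return np.array([_INDEX.get(ch, -1) for ch in seq], dtype=np.int64)
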