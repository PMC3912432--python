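"""Dayhoff (1978) empirical amino-acid substitution model.

The classic PAM accepted-point-mutation data, expressed as a reversible
rate matrix: symmetric exchangeabilities ``s_ij`` (lower triangle,
column-major, amino acids in the order ARNDCQEGHILKMFPSTWYV) combined
with the Dayhoff equilibrium frequencies ``pi`` as

    Q_ij = s_ij * pi_j   (i != j),   Q_ii = -sum_j Q_ij,

scaled so that the expected substitution rate at equilibrium is one per
site per unit time; distances from this model are therefore in expected
substitutions per site.  These are the standard published constants used
identically across phylogenetics software.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

# Lower triangle (column-major) of the symmetric exchangeability matrix.
_EXCHANGE = [
    27, 98, 120, 36, 89, 198, 240, 23, 65, 41, 26, 72, 18, 250, 409, 371, 0, 24,
    208, 32, 0, 23, 246, 1, 9, 240, 64, 15, 464, 90, 14, 103, 154, 26, 201, 8, 24,
    905, 0, 103, 148, 139, 535, 77, 34, 318, 1, 14, 42, 495, 229, 23, 95, 15, 0,
    134, 1153, 125, 86, 24, 0, 71, 0, 0, 13, 95, 66, 0, 0, 18, 0, 0, 11, 28, 44,
    0, 0, 0, 0, 19, 161, 16, 0, 96, 49, 716, 28, 606, 18, 73, 153, 114, 0, 153,
    56, 53, 0, 0, 35, 81, 43, 61, 11, 83, 30, 0, 51, 79, 34, 0, 22, 37, 10, 0, 7,
    27, 17, 15, 34, 234, 30, 0, 0, 54, 7, 44, 26, 0, 48, 94, 35, 22, 27, 127, 44,
    257, 46, 336, 196, 12, 24, 192, 0, 37, 889, 18, 527, 157, 32, 17, 33, 46, 28,
    175, 243, 0, 33, 96, 136, 0, 13, 10, 92, 17, 62, 104, 0, 0, 258, 11, 46, 13,
    76, 698, 12, 245, 78, 0, 0, 48, 550, 75, 34, 30, 0, 42, 157, 61, 0, 28,
]

# Dayhoff equilibrium amino-acid frequencies (sum to 1).
_FREQS = [
    0.0871269129, 0.0409039591, 0.0404319596, 0.0468719531, 0.0334739665,
    0.0382549617, 0.0495299505, 0.0886119114, 0.0336179664, 0.0368859631,
    0.0853569146, 0.0804819195, 0.0147529852, 0.0397719602, 0.0506799493,
    0.0695769304, 0.0585419415, 0.0104939895, 0.0299159701, 0.0647179353,
]


def equilibrium_frequencies() -> np.ndarray:
    pi = np.array(_FREQS)
    return pi / pi.sum()


def rate_matrix() -> np.ndarray:
    """Normalized reversible rate matrix Q (rows sum to zero)."""
    n = 20
    s = np.zeros((n, n))
    k = 0
    for j in range(n):  # column-major lower triangle
        for i in range(j + 1, n):
            s[i, j] = s[j, i] = _EXCHANGE[k]
            k += 1
    assert k == len(_EXCHANGE)
    pi = equilibrium_frequencies()
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    # one expected substitution per site per unit time at equilibrium
    scale = -(pi * np.diag(q)).sum()
    return q / scale


class DayhoffModel:
    """Expected-difference curve of the Dayhoff model and its inverse.

    The probability that two sequences separated by evolutionary
    distance ``d`` (expected substitutions per site) differ at a site is

        p(d) = 1 - sum_i pi_i [exp(Q d)]_ii,

    a monotone curve rising from 0 to ``p_max = 1 - sum_i pi_i**2``.
    The matrix exponential is evaluated through the symmetrized
    eigendecomposition of Q (exact for a reversible model), and the
    inverse ``d(p)`` by bisection to 1e-6.
    """

    def __init__(self) -> None:
        self.pi = equilibrium_frequencies()
        self.q = rate_matrix()
        sqrt_pi = np.sqrt(self.pi)
        # B = D^{1/2} Q D^{-1/2} with D = diag(pi) is symmetric for a
        # reversible Q; its eigenvectors give exp(Qd) diagonals directly.
        sym = (self.q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        evals, evecs = np.linalg.eigh((sym + sym.T) / 2.0)
        self._evals = evals
        # P(d)_ii = sum_k (U_ik)^2 e^{lambda_k d} in the symmetric basis
        self._u_sq = evecs**2
        self.p_max = float(1.0 - (self.pi**2).sum())

    def expected_difference(self, d: float) -> float:
        """p(d): expected proportion of differing sites at distance d."""
        if d < 0:
            raise ValueError("distance must be >= 0")
        diag = self._u_sq @ np.exp(self._evals * d)  # diagonal of exp(Qd)
        return float(1.0 - (self.pi * diag).sum())

    def invert(self, p: float, tol: float = 1e-6) -> float:
        """Distance d such that expected_difference(d) == p (bisection)."""
        if p == 0.0:
            return 0.0
        lo, hi = 0.0, 1.0
        while self.expected_difference(hi) < p:
            hi *= 2.0
            if hi > 1e6:  # unreachable for p < p_max
                raise FloatingPointError("Dayhoff inversion failed to bracket")
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if self.expected_difference(mid) < p:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


_MODEL: DayhoffModel | None = None


def default_model() -> DayhoffModel:
    """Memoized module-level model instance."""
    global _MODEL
    if _MODEL is None:
        _MODEL = DayhoffModel()
    return _MODEL
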