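"""The JTT empirical amino-acid substitution model.

Provides the reversible rate matrix, transition probabilities P(t) via
eigendecomposition of the symmetrized generator, a derived log-odds scoring
matrix (half-bit units) for pairwise alignment, and sequence simulation
under the model. Time is measured in expected substitutions per site.

The exchangeability coefficients and equilibrium frequencies are the
published JTT values (the lower triangle of the symmetric exchangeability
matrix in the standard ARNDCQEGHILKMFPSTWYV residue order).
"""

from __future__ import annotations

import functools

import numpy as np

JTT_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Lower-triangle exchangeabilities: row R has 1 entry (vs A), row N has 2, ...
_JTT_LOWER = [
    58,
    54, 45,
    81, 16, 528,
    56, 113, 34, 10,
    57, 310, 86, 49, 9,
    105, 29, 58, 767, 5, 323,
    179, 137, 81, 130, 59, 26, 119,
    27, 328, 391, 112, 69, 597, 26, 23,
    36, 22, 47, 11, 17, 9, 12, 6, 16,
    30, 38, 12, 7, 23, 72, 9, 6, 56, 229,
    35, 646, 263, 26, 7, 292, 181, 27, 45, 21, 14,
    54, 44, 30, 15, 31, 43, 18, 14, 33, 479, 388, 65,
    15, 5, 10, 4, 78, 4, 5, 5, 40, 89, 248, 4, 43,
    194, 74, 15, 15, 14, 164, 18, 24, 115, 10, 102, 21, 16, 17,
    378, 101, 503, 59, 223, 53, 30, 201, 73, 40, 59, 47, 29, 92, 285,
    475, 64, 232, 38, 42, 51, 32, 33, 46, 245, 25, 103, 226, 12, 118, 477,
    9, 126, 8, 4, 115, 18, 10, 55, 8, 9, 52, 10, 24, 53, 6, 35, 12,
    11, 20, 70, 46, 209, 24, 7, 8, 573, 32, 24, 8, 18, 536, 10, 63, 21, 71,
    298, 17, 16, 31, 62, 20, 45, 47, 11, 961, 180, 14, 323, 62, 23, 38, 112, 25, 16,
]

JTT_FREQS = np.array([
    0.076747923252076758, 0.051690948309051694, 0.042644957355042652,
    0.051543948456051550, 0.019802980197019805, 0.040751959248040752,
    0.061829938170061841, 0.073151926848073159, 0.022943977056022944,
    0.053760946239053767, 0.091903908096091905, 0.058675941324058678,
    0.023825976174023829, 0.040125959874040135, 0.050900949099050907,
    0.068764931235068771, 0.058564941435058568, 0.014260985739014262,
    0.032101967898032102, 0.066004933995066004,
])


def exchangeability_matrix() -> np.ndarray:
    """Symmetric 20x20 JTT exchangeability matrix (zero diagonal)."""
    s = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = _JTT_LOWER[k]
            k += 1
    return s


@functools.lru_cache(maxsize=1)
def _eigensystem():
    """Eigendecomposition of the normalized reversible generator.

    Returns (eigenvalues, U, U_inv) with Q = U diag(lam) U_inv and Q
    scaled so the expected rate -sum_i pi_i Q_ii equals 1.
    """
    pi = JTT_FREQS
    q = exchangeability_matrix() * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    q /= -(pi * np.diag(q)).sum()
    # symmetrize: B = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
    d = np.sqrt(pi)
    b = q * d[:, np.newaxis] / d[np.newaxis, :]
    lam, v = np.linalg.eigh((b + b.T) / 2.0)
    u = v / d[:, np.newaxis]
    u_inv = v.T * d[np.newaxis, :]
    return lam, u, u_inv


def rate_matrix() -> np.ndarray:
    lam, u, u_inv = _eigensystem()
    return (u * lam) @ u_inv


def transition_matrix(t: float) -> np.ndarray:
    """P(t) with rows indexed by ancestral, columns by derived residue."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    lam, u, u_inv = _eigensystem()
    p = (u * np.exp(lam * t)) @ u_inv
    np.clip(p, 0.0, None, out=p)
    return p / p.sum(axis=1, keepdims=True)


def log_odds_matrix(t: float = 1.0) -> np.ndarray:
    """Symmetric substitution scores s(a,b) = 2*log2(P(t)[a,b]/pi_b), half-bits.

    Symmetry follows from detailed balance: pi_a P_ab = pi_b P_ba.
    """
    p = transition_matrix(t)
    s = 2.0 * np.log2(p / JTT_FREQS[np.newaxis, :])
    return (s + s.T) / 2.0


def aa_index(seq: str) -> np.ndarray:
    """Map an AA string to JTT-order integer indices."""
    try:
        return np.array([JTT_ORDER.index(a) for a in seq], dtype=np.intp)
    except ValueError as exc:
        raise ValueError(f"non-standard amino acid in {seq!r}") from exc


def indices_to_seq(idx: np.ndarray) -> str:
    return "".join(JTT_ORDER[i] for i in idx)


def sample_equilibrium(n_sites: int, rng: np.random.Generator) -> str:
    """Draw an AA sequence from the JTT equilibrium frequencies."""
    return indices_to_seq(rng.choice(20, size=n_sites, p=JTT_FREQS))


def evolve(seq: str, t: float, rng: np.random.Generator) -> str:
    """Evolve an AA sequence for time t under JTT, sites independent."""
    p = transition_matrix(t)
    idx = aa_index(seq)
    out = np.array([rng.choice(20, p=p[i]) for i in idx], dtype=np.intp)
    return indices_to_seq(out)
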