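"""Nucleotide substitution models (JC69, HKY85, GTR) with Gamma+I rate variation.

All models are time-reversible and normalized so that one unit of branch
length equals one expected substitution per site at stationarity (before
rate-class scaling).  Bases are indexed A=0, C=1, G=2, T=3.

Among-site rate variation follows the discrete-Gamma approximation with
equal-weight categories (category rates are the means of the Gamma
quantile bins) plus an optional proportion of invariant sites; category
rates are rescaled so the mixture mean is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible rate matrix plus discrete rate-class mixture.

    Parameters
    ----------
    name:
        Model label ("JC", "HKY", "GTR", possibly with "+G4+I").
    rates:
        The six GTR exchangeabilities in order (AC, AG, AT, CG, CT, GT).
    freqs:
        Stationary base frequencies (A, C, G, T), summing to 1.
    gamma_shape:
        Shape of the Gamma rate distribution; ``None`` disables Gamma
        rate variation.
    gamma_categories:
        Number of discrete Gamma categories (ignored without a shape).
    prop_invariant:
        Proportion of invariant (rate-zero) sites.
    """

    name: str
    rates: tuple[float, float, float, float, float, float]
    freqs: tuple[float, float, float, float]
    gamma_shape: float | None = None
    gamma_categories: int = 4
    prop_invariant: float = 0.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("base frequencies must be 4 non-negative values summing to 1 (tol 1e-9)")
        r = np.asarray(self.rates, dtype=float)
        if r.shape != (6,) or np.any(r <= 0):
            raise ValueError("exchangeability rates must be 6 positive values")
        if not (0.0 <= self.prop_invariant < 1.0):
            raise ValueError("prop_invariant must be in [0, 1)")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    # -- rate matrix ------------------------------------------------------

    def q_matrix(self) -> np.ndarray:
        """Normalized 4x4 rate matrix Q with -sum_i pi_i Q_ii = 1."""
        if "Q" in self._cache:
            return self._cache["Q"]
        ac, ag, at, cg, ct, gt = self.rates
        pi = np.asarray(self.freqs)
        R = np.array([
            [0.0, ac, ag, at],
            [ac, 0.0, cg, ct],
            [ag, cg, 0.0, gt],
            [at, ct, gt, 0.0],
        ])
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        Q = Q / mu
        self._cache["Q"] = Q
        return Q

    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q via the symmetrizing similarity transform."""
        if "eig" in self._cache:
            return self._cache["eig"]
        pi = np.asarray(self.freqs)
        Q = self.q_matrix()
        sq = np.sqrt(pi)
        S = (sq[:, None] * Q) / sq[None, :]
        lam, U = np.linalg.eigh((S + S.T) / 2.0)
        left = U.T * sq[None, :]            # rows: u_k^T diag(sqrt pi)
        right = (1.0 / sq)[:, None] * U     # diag(1/sqrt pi) u_k
        self._cache["eig"] = (lam, right, left)
        return self._cache["eig"]

    def transition_matrices(self, t: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch lengths; shape ``t.shape + (4, 4)``."""
        t = np.asarray(t, dtype=float)
        lam, right, left = self._eigen()
        expd = np.exp(np.multiply.outer(t, lam))          # t.shape + (4,)
        P = np.einsum("...k,ik,kj->...ij", expd, right, left)
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=-1, keepdims=True)
        return P

    # -- rate classes -----------------------------------------------------

    def rate_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the discrete rate mixture, mean rate 1."""
        if "classes" in self._cache:
            return self._cache["classes"]
        if self.gamma_shape is None:
            cats = np.array([1.0])
            w = np.array([1.0])
        else:
            k = self.gamma_categories
            a = self.gamma_shape
            edges = _gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
            # mean of the Gamma within each equal-probability bin
            cdf2 = _gamma_dist.cdf(edges, a + 1, scale=1.0 / a)
            cats = (cdf2[1:] - cdf2[:-1]) * k
            w = np.full(k, 1.0 / k)
        if self.prop_invariant > 0:
            cats = np.concatenate([[0.0], cats])
            w = np.concatenate([[self.prop_invariant], w * (1.0 - self.prop_invariant)])
        mean = float(np.dot(cats, w))
        cats = cats / mean
        self._cache["classes"] = (cats, w)
        return self._cache["classes"]


def jc69() -> SubstitutionModel:
    """Jukes-Cantor: equal frequencies, equal exchangeabilities."""
    return SubstitutionModel("JC", (1.0,) * 6, (0.25,) * 4)


def hky85(kappa: float = 2.0, freqs=(0.25, 0.25, 0.25, 0.25)) -> SubstitutionModel:
    """HKY85 with transition/transversion ratio ``kappa``."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    # transitions: A<->G and C<->T
    return SubstitutionModel("HKY", (1.0, kappa, 1.0, 1.0, kappa, 1.0), tuple(freqs))


def gtr(
    rates=(1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    freqs=(0.25, 0.25, 0.25, 0.25),
    gamma_shape: float | None = None,
    gamma_categories: int = 4,
    prop_invariant: float = 0.0,
) -> SubstitutionModel:
    """General time-reversible model, optionally with Gamma+I rate variation."""
    name = "GTR"
    if gamma_shape is not None:
        name += f"+G{gamma_categories}"
    if prop_invariant > 0:
        name += "+I"
    return SubstitutionModel(name, tuple(rates), tuple(freqs), gamma_shape, gamma_categories, prop_invariant)


def empirical_frequencies(seqs: np.ndarray) -> np.ndarray:
    """Base frequencies counted over an encoded alignment (codes 0..3)."""
    counts = np.bincount(seqs[seqs >= 0].ravel(), minlength=4).astype(float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    f = counts / counts.sum()
    # keep frequencies strictly positive so Q stays irreducible
    f = np.clip(f, 1e-6, None)
    return f / f.sum()


def encode_sequences(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Encode ACGT strings to an int8 matrix (A=0..T=3); other symbols -> -1."""
    ids = list(seqs)
    L = {len(s) for s in seqs.values()}
    if len(L) > 1:
        raise ValueError("sequences must be aligned to equal length")
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    mat = np.vstack([lut[np.frombuffer(seqs[i].encode(), dtype=np.uint8)] for i in ids])
    return ids, mat


def decode_sequences(mat: np.ndarray) -> list[str]:
    arr = np.array(list(BASES))
    return ["".join(arr[row]) for row in mat]
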