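"""Felsenstein pruning likelihood of an alignment on a timed genealogy.

Sites are compressed to patterns; partial likelihoods are propagated
post-order with per-pattern rescaling, mixing over the substitution
model's discrete rate classes.  The numba kernel is shared by the
one-shot :func:`pruning_loglik` and by the samplers, which re-evaluate
thousands of candidate genealogies on a fixed alignment through
:class:`TreeLikelihood`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from phylodeme.genealogy import Genealogy
from phylodeme.substitution import SubstitutionModel, encode_sequences


@njit(cache=True)
def _prune_fused(bl, rates, lam, right, left, children, tipstates, pi, weights, counts):
    """Pruning with per-branch transition matrices built in-kernel from the
    eigendecomposition Q = right diag(lam) left."""
    n_nodes = children.shape[0]
    ncat = rates.shape[0]
    P = np.empty((n_nodes, ncat, 4, 4))
    for v in range(n_nodes):
        for cat in range(ncat):
            t = bl[v] * rates[cat]
            e0 = np.exp(lam[0] * t)
            e1 = np.exp(lam[1] * t)
            e2 = np.exp(lam[2] * t)
            e3 = np.exp(lam[3] * t)
            for i in range(4):
                r0 = right[i, 0] * e0
                r1 = right[i, 1] * e1
                r2 = right[i, 2] * e2
                r3 = right[i, 3] * e3
                rowsum = 0.0
                for j in range(4):
                    p = (r0 * left[0, j] + r1 * left[1, j]
                         + r2 * left[2, j] + r3 * left[3, j])
                    if p < 0.0:
                        p = 0.0
                    P[v, cat, i, j] = p
                    rowsum += p
                for j in range(4):
                    P[v, cat, i, j] /= rowsum
    return _prune(children, P, tipstates, pi, weights, counts)


@njit(cache=True)
def _prune(children, P, tipstates, pi, weights, counts):
    n_nodes = children.shape[0]
    n_tips = tipstates.shape[0]
    ncat = P.shape[1]
    npat = tipstates.shape[1]
    L = np.empty((n_nodes - n_tips, ncat, npat, 4))
    logscale = np.zeros(npat)
    for v in range(n_tips, n_nodes):
        vi = v - n_tips
        for cat in range(ncat):
            for p in range(npat):
                for x in range(4):
                    L[vi, cat, p, x] = 1.0
        for ci in range(2):
            c = children[v, ci]
            if c < n_tips:
                for cat in range(ncat):
                    for p in range(npat):
                        s = tipstates[c, p]
                        if s < 0:
                            continue  # missing data: row sums to 1
                        for x in range(4):
                            L[vi, cat, p, x] *= P[c, cat, x, s]
            else:
                cidx = c - n_tips
                for cat in range(ncat):
                    for p in range(npat):
                        for x in range(4):
                            acc = 0.0
                            for s in range(4):
                                acc += P[c, cat, x, s] * L[cidx, cat, p, s]
                            L[vi, cat, p, x] = L[vi, cat, p, x] * acc
        for p in range(npat):
            m = 0.0
            for cat in range(ncat):
                for x in range(4):
                    if L[vi, cat, p, x] > m:
                        m = L[vi, cat, p, x]
            if m > 0 and (m < 1e-50 or m > 1e50):
                logscale[p] += np.log(m)
                for cat in range(ncat):
                    for x in range(4):
                        L[vi, cat, p, x] /= m
    root = n_nodes - n_tips - 1
    total = 0.0
    for p in range(npat):
        lsum = 0.0
        for cat in range(ncat):
            acc = 0.0
            for x in range(4):
                acc += pi[x] * L[root, cat, p, x]
            lsum += weights[cat] * acc
        if lsum <= 0.0:
            return -np.inf
        total += counts[p] * (np.log(lsum) + logscale[p])
    return total


def compress_patterns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique alignment columns and their multiplicities.

    ``mat`` is (n_seqs, L) with codes 0..3 (or -1 for missing); returns
    (patterns, counts) with patterns of shape (n_seqs, n_patterns).
    """
    cols = np.ascontiguousarray(mat.T)
    uniq, counts = np.unique(cols, axis=0, return_counts=True)
    return np.ascontiguousarray(uniq.T), counts.astype(np.float64)


class TreeLikelihood:
    """Pruning likelihood of a fixed alignment, re-evaluated on many trees."""

    def __init__(self, alignment: dict[str, str], model: SubstitutionModel,
                 tip_order: list[str] | None = None):
        ids, mat = encode_sequences(alignment)
        if tip_order is not None:
            if set(tip_order) != set(ids):
                raise ValueError("tip ids of genealogy do not match alignment ids")
            idx = [ids.index(t) for t in tip_order]
            mat = mat[idx]
            ids = list(tip_order)
        self.tip_ids = ids
        self.model = model
        self.patterns, self.pattern_counts = compress_patterns(mat)
        self.rates, self.weights = model.rate_classes()
        self.pi = np.asarray(model.freqs)
        self.n_tips = len(ids)
        lam, right, left = model._eigen()
        self._lam = np.ascontiguousarray(lam)
        self._right = np.ascontiguousarray(right)
        self._left = np.ascontiguousarray(left)

    def loglik_arrays(self, times: np.ndarray, children: np.ndarray) -> float:
        """Log-likelihood given node times and a children table.

        Internal nodes must be in increasing time order after the tips
        (the canonical :class:`Genealogy` layout).
        """
        n_nodes = len(times)
        if n_nodes == 1:
            # single sequence: stationary draw
            state_counts = np.zeros(4)
            for p, c in zip(self.patterns[0], self.pattern_counts):
                if p >= 0:
                    state_counts[p] += c
            return float(np.sum(state_counts * np.log(self.pi)))
        par = np.full(n_nodes, -1, dtype=np.int64)
        for v in range(self.n_tips, n_nodes):
            par[children[v, 0]] = v
            par[children[v, 1]] = v
        bl = np.zeros(n_nodes)
        has = par >= 0
        bl[has] = times[par[has]] - times[has]
        return float(_prune_fused(bl, self.rates, self._lam, self._right, self._left,
                                  children, self.patterns, self.pi, self.weights,
                                  self.pattern_counts))

    def loglik(self, gen: Genealogy) -> float:
        if list(gen.tip_ids) != self.tip_ids:
            raise ValueError("genealogy tip order does not match this likelihood object")
        return self.loglik_arrays(gen.times, gen.children)


def pruning_loglik(gen: Genealogy, alignment: dict[str, str],
                   model: SubstitutionModel) -> float:
    """Exact log P(alignment | genealogy, model), summed over sites."""
    tl = TreeLikelihood(alignment, model, tip_order=list(gen.tip_ids))
    return tl.loglik(gen)
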