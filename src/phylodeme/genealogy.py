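"""Timed structured genealogies with explicit migration histories.

A :class:`Genealogy` is a binary ultrametric coalescent tree whose tips sit
at time 0 and whose internal-node times increase into the past, together
with the full backward-in-time migration history of every lineage.  Nodes
``0..n-1`` are tips; internal nodes ``n..2n-2`` are numbered in
chronological (coalescence) order, so the root is node ``2n-2``.

Each migration record ``(time, node, src, dst)`` states that the lineage
represented by subtree-root ``node`` jumped, backward in time, from deme
``src`` to deme ``dst`` at ``time``.  Coalescences may only join lineages
that currently occupy the same deme; :meth:`Genealogy.validate` replays
the event history to enforce this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Genealogy:
    tip_ids: list[str]
    tip_demes: np.ndarray          # (n,) int deme index per tip
    deme_labels: tuple[str, ...]
    times: np.ndarray              # (2n-1,) node times, tips at 0
    children: np.ndarray           # (2n-1, 2) child node ids, -1 for tips
    coal_demes: np.ndarray         # (n-1,) deme of coalescence for node n+i
    mig_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    mig_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    mig_src: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    mig_dst: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def parents(self) -> np.ndarray:
        """Parent node per node (-1 for the root)."""
        par = np.full(self.n_nodes, -1, dtype=np.int64)
        for v in range(self.n_tips, self.n_nodes):
            for c in self.children[v]:
                par[c] = v
        return par

    def branch_lengths(self) -> np.ndarray:
        par = self.parents()
        bl = np.zeros(self.n_nodes)
        has_par = par >= 0
        bl[has_par] = self.times[par[has_par]] - self.times[has_par]
        return bl

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    # -- deme bookkeeping -------------------------------------------------

    def node_birth_deme(self, v: int) -> int:
        """Deme in which lineage ``v`` starts (tip deme or coalescence deme)."""
        if v < self.n_tips:
            return int(self.tip_demes[v])
        return int(self.coal_demes[v - self.n_tips])

    def deme_path(self, v: int) -> list[tuple[int, float, float]]:
        """(deme, start, end) intervals covering the lifetime of lineage ``v``.

        The lifetime runs from the node's own time to its parent's time
        (to +inf conceptually for the root; the root's path is the single
        interval at its birth deme unless migrations are recorded on it).
        """
        par = self.parents()
        t0 = float(self.times[v])
        t1 = float(self.times[par[v]]) if par[v] >= 0 else t0
        mask = self.mig_nodes == v
        mt = self.mig_times[mask]
        md_src = self.mig_src[mask]
        md_dst = self.mig_dst[mask]
        order = np.argsort(mt)
        path = []
        cur_deme = self.node_birth_deme(v)
        cur_t = t0
        for i in order:
            assert md_src[i] == cur_deme
            path.append((cur_deme, cur_t, float(mt[i])))
            cur_t = float(mt[i])
            cur_deme = int(md_dst[i])
        path.append((cur_deme, cur_t, max(t1, cur_t)))
        return path

    def deme_at(self, v: int, t: float) -> int:
        """Deme of lineage ``v`` at time ``t`` within its lifetime."""
        for deme, a, b in self.deme_path(v):
            if a <= t <= b:
                return deme
        raise ValueError(f"time {t} outside lifetime of node {v}")

    def root_deme(self) -> int:
        """Deme occupied immediately above the final coalescence."""
        if self.n_tips == 1:
            path = self.deme_path(0)
            return path[-1][0]
        return self.node_birth_deme(self.root)

    # -- event replay -----------------------------------------------------

    def event_stream(self):
        """Yield events in chronological order.

        Events are ``("mig", time, node, src, dst)`` and
        ``("coal", time, child1, child2, parent, deme)``.
        """
        n = self.n_tips
        mig_order = np.argsort(self.mig_times, kind="stable")
        mi = 0
        for k in range(n - 1):
            parent = n + k
            t = float(self.times[parent])
            while mi < len(mig_order) and float(self.mig_times[mig_order[mi]]) <= t:
                j = mig_order[mi]
                yield ("mig", float(self.mig_times[j]), int(self.mig_nodes[j]),
                       int(self.mig_src[j]), int(self.mig_dst[j]))
                mi += 1
            c1, c2 = self.children[parent]
            yield ("coal", t, int(c1), int(c2), parent, int(self.coal_demes[k]))
        while mi < len(mig_order):
            j = mig_order[mi]
            yield ("mig", float(self.mig_times[j]), int(self.mig_nodes[j]),
                   int(self.mig_src[j]), int(self.mig_dst[j]))
            mi += 1

    def validate(self) -> None:
        """Replay the history, checking the structural invariants.

        Raises ``ValueError`` on non-increasing node times, a migration
        attributed to an inactive lineage or wrong source deme, or a
        coalescence joining lineages in different demes.
        """
        n = self.n_tips
        state = {v: int(self.tip_demes[v]) for v in range(n)}
        last_t = 0.0
        for ev in self.event_stream():
            t = ev[1]
            if t < last_t - 1e-12:
                raise ValueError("events out of chronological order")
            last_t = t
            if ev[0] == "mig":
                _, _, v, src, dst = ev
                if v not in state:
                    raise ValueError(f"migration on inactive lineage {v}")
                if state[v] != src:
                    raise ValueError(f"migration source deme mismatch on lineage {v}")
                state[v] = dst
            else:
                _, _, c1, c2, parent, deme = ev
                if c1 not in state or c2 not in state:
                    raise ValueError("coalescence of inactive lineage")
                if state[c1] != state[c2] or state[c1] != deme:
                    raise ValueError("coalescence joining lineages in different demes")
                del state[c1], state[c2]
                state[parent] = deme
        if len(state) != 1:
            raise ValueError("history does not end with a single lineage")

    # -- sufficient statistics -------------------------------------------

    def sufficient_stats(self, n_demes: int):
        """Per-deme statistics determining the structured-coalescent density.

        Returns ``(coal_counts, coal_weights, mig_counts, lineage_time)``:

        * ``coal_counts[i]`` — number of coalescences in deme *i*;
        * ``coal_weights[i]`` — integral of ``k_i (k_i - 1)`` over time;
        * ``mig_counts[i, j]`` — backward migrations from deme *i* to *j*;
        * ``lineage_time[i]`` — integral of ``k_i`` over time.

        With constant scaled sizes ``theta`` and backward rates ``M`` the
        log-density of the full history is::

            sum_i [ c_i ln(2/theta_i) - A_i / theta_i ]
            + sum_{i != j} n_ij ln M_ij - sum_i B_i sum_j M_ij
        """
        c = np.zeros(n_demes)
        A = np.zeros(n_demes)
        nmat = np.zeros((n_demes, n_demes))
        B = np.zeros(n_demes)
        k = np.bincount(self.tip_demes, minlength=n_demes).astype(float)
        t_prev = 0.0
        for ev in self.event_stream():
            t = ev[1]
            dt = t - t_prev
            if dt > 0:
                A += k * (k - 1) * dt
                B += k * dt
                t_prev = t
            if ev[0] == "mig":
                _, _, _, src, dst = ev
                nmat[src, dst] += 1
                k[src] -= 1
                k[dst] += 1
            else:
                deme = ev[5]
                c[deme] += 1
                k[deme] -= 1
        return c, A, nmat, B

    def log_density(self, thetas: np.ndarray, M: np.ndarray) -> float:
        """Log-density of this history under constant ``thetas`` and rates ``M``."""
        c, A, nmat, B = self.sufficient_stats(len(thetas))
        return structured_log_density(c, A, nmat, B, thetas, M)


def structured_log_density(c, A, nmat, B, thetas, M) -> float:
    """Structured-coalescent log-density from sufficient statistics."""
    thetas = np.asarray(thetas, dtype=float)
    M = np.asarray(M, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mig_term = np.where(nmat > 0, nmat * np.log(np.where(M > 0, M, 1.0)), 0.0)
        if np.any((nmat > 0) & (M <= 0)):
            return -np.inf
    val = float(np.sum(c * np.log(2.0 / thetas)) - np.sum(A / thetas)
                + np.sum(mig_term) - np.sum(B * M.sum(axis=1)))
    return val
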