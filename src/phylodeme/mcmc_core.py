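"""Genealogy MCMC machinery shared by the migration and skyline samplers.

A :class:`History` stores a structured-coalescent realization as a
chronological event list (coalescences and backward migrations) over
tips ``0..n-1``.  Two proposal moves are provided, both with the
property that — when the driving parameters of the proposal equal the
parameters of the coalescent prior — the Metropolis-Hastings acceptance
ratio reduces to the (tempered) sequence-likelihood ratio:

* ``regrow``: erase everything above a time ``tau`` drawn uniformly on a
  fixed window and resimulate from the lineages extant at ``tau``.  The
  erased portion's prior density cancels against the proposal density.

* ``regraft``: detach the edge above a uniformly chosen non-root node
  and resimulate that single lineage — migrating at the driving rates
  and coalescing with the remaining forest's lineages at the driving
  coalescent intensity (jointly with the last surviving forest lineage
  once the forest has fully coalesced).  The structured-coalescent
  density factorizes exactly into the forest density times this
  resimulation measure, so priors and proposals cancel.

Both cancellations also hold with a time-varying population-size factor
(the ``env`` argument), which the skyline sampler exploits.
"""

from __future__ import annotations

import numpy as np

from phylodeme.genealogy import Genealogy
from phylodeme.simulate import simulate_history


class ConstantEnv:
    """No population-size change: size factor 1 at all times."""

    def size_factor(self, t: float) -> float:
        return 1.0

    def min_future_factor(self, t: float) -> float:
        return 1.0

    def window(self, t: float) -> tuple[float, float]:
        return np.inf, 1.0


CONSTANT_ENV = ConstantEnv()


class History:
    """A full structured-coalescent event history over ``n`` tips.

    ``events`` is a chronological list of
    ``("c", t, child1, child2, parent, deme)`` and
    ``("m", t, node, src, dst)`` tuples; node ids are arbitrary ints
    (tips are ``0..n-1``).
    """

    __slots__ = ("n_tips", "tip_demes", "events", "_next_id", "_stats")

    def __init__(self, n_tips: int, tip_demes: np.ndarray, events: list):
        self.n_tips = n_tips
        self.tip_demes = np.asarray(tip_demes, dtype=np.int64)
        self.events = events
        self._stats = None
        used = [n_tips - 1] + [e[4] for e in events if e[0] == "c"]
        self._next_id = max(used) + 1

    # -- construction -----------------------------------------------------

    @staticmethod
    def simulate(rng, tip_demes, thetas, M, env=None) -> "History":
        tip_demes = np.asarray(tip_demes, dtype=np.int64)
        n = len(tip_demes)
        coal, mig = simulate_history(rng, list(range(n)), list(tip_demes), 0.0,
                                     np.asarray(thetas, float), np.asarray(M, float),
                                     growth=env, next_parent=n)
        events = sorted([("c", t, c1, c2, p, d) for t, c1, c2, p, d in coal]
                        + [("m", t, v, s, d) for t, v, s, d in mig], key=lambda e: e[1])
        return History(n, tip_demes, events)

    def copy(self) -> "History":
        return History(self.n_tips, self.tip_demes, list(self.events))

    # -- views -------------------------------------------------------------

    def root_time(self) -> float:
        coals = [e[1] for e in self.events if e[0] == "c"]
        return max(coals) if coals else 0.0

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Canonical (times, children) arrays with chronological internal ids."""
        n = self.n_tips
        times = np.zeros(2 * n - 1)
        children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
        remap = {}
        k = 0
        for e in self.events:
            if e[0] != "c":
                continue
            _, t, c1, c2, p, _ = e
            new_id = n + k
            remap[p] = new_id
            times[new_id] = t
            children[new_id, 0] = c1 if c1 < n else remap[c1]
            children[new_id, 1] = c2 if c2 < n else remap[c2]
            k += 1
        if k != n - 1:
            raise ValueError("history is not fully coalesced")
        return times, children

    def to_genealogy(self, tip_ids, deme_labels) -> Genealogy:
        from phylodeme.simulate import assemble_genealogy
        coal = [(t, c1, c2, p, d) for tag, t, c1, c2, p, d in
                [e for e in self.events if e[0] == "c"]]
        mig = [(t, v, s, d) for tag, t, v, s, d in
               [e for e in self.events if e[0] == "m"]]
        return assemble_genealogy(tip_ids, self.tip_demes, deme_labels, coal, mig)

    def suffstats(self, n_demes: int):
        """(coal counts, k(k-1) integrals, migration counts, k integrals).

        Cached per history (the event list is never mutated in place)."""
        if self._stats is not None and self._stats[0].shape[0] == n_demes:
            return self._stats
        c = np.zeros(n_demes)
        A = np.zeros(n_demes)
        nmat = np.zeros((n_demes, n_demes))
        B = np.zeros(n_demes)
        k = np.bincount(self.tip_demes, minlength=n_demes).astype(float)
        t_prev = 0.0
        for e in self.events:
            t = e[1]
            dt = t - t_prev
            if dt > 0:
                A += k * (k - 1) * dt
                B += k * dt
                t_prev = t
            if e[0] == "m":
                _, _, _, src, dst = e
                nmat[src, dst] += 1
                k[src] -= 1
                k[dst] += 1
            else:
                d = e[5]
                c[d] += 1
                k[d] -= 1
        self._stats = (c, A, nmat, B)
        return self._stats

    def coal_times_and_counts(self):
        """(coal times ascending, lineage count entering each inter-event
        interval) for single-deme densities; migrations are ignored."""
        times = [e[1] for e in self.events if e[0] == "c"]
        return np.asarray(times), self.n_tips

    # -- replay -------------------------------------------------------------

    def state_at(self, tau: float):
        """(active node -> deme, index of first event above tau)."""
        state = {v: int(d) for v, d in enumerate(self.tip_demes)}
        for i, e in enumerate(self.events):
            if e[1] > tau:
                return state, i
            if e[0] == "m":
                _, _, v, src, dst = e
                state[v] = dst
            else:
                _, _, c1, c2, p, d = e
                del state[c1], state[c2]
                state[p] = d
        return state, len(self.events)

    def scaled(self, c: float) -> "History":
        """All event times multiplied by ``c`` (a depth-scaling proposal)."""
        events = [(e[0], e[1] * c, *e[2:]) for e in self.events]
        return History(self.n_tips, self.tip_demes, events)

    # -- moves --------------------------------------------------------------

    def regrown(self, rng, tau: float, thetas, M, env=None) -> "History":
        """New history: events below ``tau`` kept, everything above resimulated."""
        state, cut = self.state_at(tau)
        if len(state) <= 1:
            return self
        nodes = list(state)
        demes = [state[v] for v in nodes]
        coal, mig = simulate_history(rng, nodes, demes, tau, np.asarray(thetas, float),
                                     np.asarray(M, float), growth=env,
                                     next_parent=self._next_id)
        events = self.events[:cut] + sorted(
            [("c", t, c1, c2, p, d) for t, c1, c2, p, d in coal]
            + [("m", t, v, s, d) for t, v, s, d in mig], key=lambda e: e[1])
        return History(self.n_tips, self.tip_demes, events)

    def _birth(self, v: int) -> tuple[float, int]:
        """(birth time, birth deme) of lineage ``v``."""
        if v < self.n_tips:
            return 0.0, int(self.tip_demes[v])
        for e in self.events:
            if e[0] == "c" and e[4] == v:
                return e[1], e[5]
        raise KeyError(v)

    def _nonroot_nodes(self) -> list[int]:
        children = []
        for e in self.events:
            if e[0] == "c":
                children.extend([e[2], e[3]])
        return children

    def regrafted(self, rng, thetas, M, env=None) -> "History":
        """Detach the edge above a random non-root node and resimulate it."""
        thetas = np.asarray(thetas, float)
        M = np.asarray(M, float)
        if env is None:
            env = CONSTANT_ENV
        candidates = self._nonroot_nodes()
        v = candidates[rng.integers(len(candidates))]
        t_v, deme_v = self._birth(v)

        # ---- detach: drop v's edge, its parent's coalescence, and the
        # migrations above the forest's own MRCA ----
        parent_ev = next(e for e in self.events if e[0] == "c" and v in (e[2], e[3]))
        p = parent_ev[4]
        t_p = parent_ev[1]
        sib = parent_ev[2] if parent_ev[3] == v else parent_ev[3]
        forest = []
        for e in self.events:
            if e is parent_ev:
                continue
            if e[0] == "m":
                _, t, node, src, dst = e
                if node == v and t_v < t <= t_p:
                    continue
                if node == p:
                    node = sib
                forest.append(("m", t, node, src, dst))
            else:
                _, t, c1, c2, par, d = e
                if c1 == p:
                    c1 = sib
                if c2 == p:
                    c2 = sib
                forest.append(("c", t, c1, c2, par, d))
        # the forest (excluding lineage v) reduces to one lineage after its
        # last coalescence; migrations recorded above that point belong to
        # the joint phase and are regenerated
        T_R = max((e[1] for e in forest if e[0] == "c"), default=0.0)
        fstate = {u for u in range(self.n_tips) if u != v}
        for e in forest:
            if e[0] == "c":
                fstate.discard(e[2])
                fstate.discard(e[3])
                if e[4] != v:
                    fstate.add(e[4])
        assert len(fstate) == 1
        last = next(iter(fstate))
        forest = [e for e in forest
                  if not (e[0] == "m" and e[2] == last and e[1] > T_R)]

        # ---- resimulate the single lineage against the forest ----
        new_migs, attach = _simulate_path(rng, forest, self.n_tips, self.tip_demes,
                                          v, t_v, deme_v, last, T_R,
                                          thetas, M, env, self._next_id)
        t_att, target, deme_att, joint_events, new_parent = attach
        events = []
        for e in forest:
            if e[0] == "m" and e[2] == target and e[1] > t_att:
                events.append(("m", e[1], new_parent, e[3], e[4]))
            elif e[0] == "c" and target in (e[2], e[3]) and e[1] > t_att:
                c1 = new_parent if e[2] == target else e[2]
                c2 = new_parent if e[3] == target else e[3]
                events.append(("c", e[1], c1, c2, e[4], e[5]))
            else:
                events.append(e)
        events.append(("c", t_att, v, target, new_parent, deme_att))
        events.extend(("m", t, node, src, dst) for t, node, src, dst in new_migs)
        events.extend(joint_events)
        events.sort(key=lambda e: e[1])
        return History(self.n_tips, self.tip_demes, events)


def _forest_intervals(forest, n_tips, tip_demes, exclude):
    """Replay a forest, yielding (t_start, t_end, {node: deme}) intervals.

    ``exclude`` (the detached lineage) is removed from the active set as
    soon as it appears.  The final interval extends to +inf.
    """
    state = {u: int(d) for u, d in enumerate(tip_demes) if u != exclude}
    t = 0.0
    for e in forest:
        yield t, e[1], state
        t = e[1]
        if e[0] == "m":
            _, _, node, src, dst = e
            if node in state:
                state[node] = dst
        else:
            _, _, c1, c2, par, d = e
            state.pop(c1, None)
            state.pop(c2, None)
            if par != exclude:
                state[par] = d
    yield t, np.inf, state


def _simulate_path(rng, forest, n_tips, tip_demes, v, t_v, deme_v, last, T_R,
                   thetas, M, env, next_id):
    """Resimulate the detached lineage ``v`` from ``t_v`` until it re-attaches.

    The lineage migrates at the driving rates and, while co-located with
    ``k`` forest lineages in deme ``d``, coalesces with a specific one at
    rate ``2 / (theta_d * s(t))``.  If the forest has fully coalesced
    (above ``T_R``) the lineage and the last forest lineage are simulated
    jointly.  Returns ``(migrations, (t_att, target, deme, joint_events,
    new_parent))``.
    """
    row_m = M.sum(axis=1)
    migs = []
    d = deme_v
    t = t_v
    for a, b, state in _forest_intervals(forest, n_tips, tip_demes, v):
        if b <= t:
            continue
        a = max(a, t)
        if a >= T_R and len(state) <= 1:
            break
        in_deme = [u for u, dd in state.items() if dd == d]
        while True:
            w_end, s_min = env.window(t)
            b_eff = min(b, w_end)
            coal_max = 2.0 * len(in_deme) / (thetas[d] * s_min)
            lam = coal_max + row_m[d]
            if lam <= 0:
                t = b_eff
                if t >= b:
                    break
                continue
            t_cand = t + rng.exponential(1.0 / lam)
            if t_cand >= b_eff:
                t = b_eff
                if t >= b:
                    break
                continue
            t = t_cand
            u = rng.random() * lam
            if u < row_m[d]:
                dst = int(rng.choice(len(thetas), p=M[d] / row_m[d]))
                migs.append((t, v, d, dst))
                d = dst
                in_deme = [uu for uu, dd in state.items() if dd == d]
            elif u < row_m[d] + 2.0 * len(in_deme) / (thetas[d] * env.size_factor(t)):
                target = in_deme[rng.integers(len(in_deme))]
                return migs, (t, target, d, [], next_id)
            # else: thinning rejection
        if np.isinf(b):
            break
    # joint phase: v and the last forest lineage
    t0 = max(t, T_R)
    # deme of the last forest lineage at t0
    last_deme = None
    for a, b, state in _forest_intervals(forest, n_tips, tip_demes, v):
        if last in state:
            last_deme = state[last]
    coal, mig = simulate_history(rng, [v, last], [d, last_deme], t0,
                                 thetas, M, growth=env, next_parent=next_id)
    (t_att, c1, c2, par, dd) = coal[0]
    joint = [("m", tt, node, src, dst) for tt, node, src, dst in mig]
    return migs, (t_att, last, dd, joint, par)
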