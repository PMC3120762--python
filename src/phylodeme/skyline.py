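"""Coalescent skyline reconstruction and expansion dating under a strict clock.

The model: a single-deme coalescent whose scaled population size
``phi(t)`` (theta-scale: pairwise coalescence rate ``2/phi``) is
piecewise linear between K change points, with K given a (truncated)
Poisson prior, change times uniform, and knot sizes exponentially
distributed around a population mean with a broad uniform prior (the
hierarchical size prior of the extended skyline).  Sequences evolve under
a reversible substitution model (default GTR+Gamma4+I with empirical
base frequencies) along the genealogy; a strict molecular clock converts
internal substitution-time units to years only at reporting time, so all
reported times scale exactly inversely with the clock rate.

Change-point number is sampled by reversible jump (birth/death moves);
the constant-size special case pins K = 0.  Marginal likelihoods for the
skyline-vs-constant Bayes factor come from stepping-stone sampling, with
a thermodynamic-integration estimate available as a cross-check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import poisson

from phylodeme.likelihood import TreeLikelihood
from phylodeme.mcmc_core import History
from phylodeme.substitution import SubstitutionModel, gtr, encode_sequences, empirical_frequencies

logger = logging.getLogger(__name__)

DEFAULT_CLOCK_RATE = 4.28e-8   # substitutions per site per year


@dataclass(frozen=True)
class ClockModel:
    """Strict molecular clock in substitutions per site per year."""

    rate: float = DEFAULT_CLOCK_RATE

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("clock rate must be positive")


def time_to_years(height: float, clock: ClockModel) -> float:
    """Convert a tree height (substitutions per site) to years."""
    if height < 0:
        raise ValueError("height must be non-negative")
    return height / clock.rate


@dataclass(frozen=True)
class SkylinePriors:
    """Priors of the skyline model.

    Hierarchical population-size prior: knot sizes are exponentially
    distributed (truncated to the bounds) around a population mean whose
    prior is uniform between ``pop_low`` and ``pop_high`` with initial
    value ``pop_init``.  Sizes are mapped once, at construction, to the
    coalescent-scaled ``phi = Ne * reference_rate``, so the sampled
    chain is independent of the clock rate used for reporting — doubling
    the clock rate exactly halves every reported time.
    """

    cp_mean: float = 2.0           # Poisson mean of the change-point count
    cp_max: int = 4                # truncation of the change-point count
    pop_low: float = 1e4
    pop_high: float = 1e12
    pop_init: float = 1e6
    reference_rate: float = DEFAULT_CLOCK_RATE

    def __post_init__(self) -> None:
        if not (0 < self.pop_low < self.pop_high):
            raise ValueError("population bounds must be positive with low < high")
        if self.pop_init <= 0 or self.cp_mean <= 0 or self.cp_max < 0:
            raise ValueError("invalid prior settings")

    @property
    def phi_bounds(self) -> tuple[float, float]:
        return (self.pop_low * self.reference_rate, self.pop_high * self.reference_rate)

    @property
    def phi_init(self) -> float:
        return self.pop_init * self.reference_rate

    def log_p_size(self, phi: float, phi_mu: float) -> float:
        """Truncated-exponential knot-size log-density given the mean."""
        lo, hi = self.phi_bounds
        if not (lo <= phi <= hi):
            return -np.inf
        z = math.exp(-lo / phi_mu) - math.exp(-hi / phi_mu)
        return -math.log(phi_mu) - phi / phi_mu - math.log(z)

    def log_p_k(self, k: int) -> float:
        ks = np.arange(self.cp_max + 1)
        w = poisson.pmf(ks, self.cp_mean)
        return float(np.log(w[k] / w.sum()))

    def prior_p_k_geq(self, k: int) -> float:
        ks = np.arange(self.cp_max + 1)
        w = poisson.pmf(ks, self.cp_mean)
        w /= w.sum()
        return float(w[k:].sum())


@dataclass
class SkylineSettings:
    chain_length: int = 6000
    burn_in: int = 1500
    thin: int = 5
    p_regraft: float = 0.35
    p_regrow: float = 0.08
    p_tree_scale: float = 0.07
    p_size: float = 0.20
    p_time: float = 0.10
    p_mu: float = 0.05
    sigma_size: float = 0.7
    sigma_birth: float = 1.0
    sigma_mu: float = 0.7
    sigma_tree_scale: float = 0.3
    tcap_factor: float = 1.5
    ss_powers: int = 12
    ss_chain_length: int = 300
    ss_burn_in: int = 80
    ss_alpha: float = 0.3
    ess_floor: float = 25.0
    seed: int = 0


class Trajectory:
    """Piecewise-linear scaled size phi(t): knots (0, phi0), (t_i, phi_i)."""

    __slots__ = ("ts", "phis")

    def __init__(self, ts: np.ndarray, phis: np.ndarray):
        self.ts = np.asarray(ts, dtype=float)
        self.phis = np.asarray(phis, dtype=float)

    @property
    def k(self) -> int:
        return len(self.ts)

    def value(self, t: float) -> float:
        xs = np.concatenate([[0.0], self.ts])
        return float(np.interp(t, xs, self.phis))

    def min_after(self, t: float) -> float:
        xs = np.concatenate([[0.0], self.ts])
        later = self.phis[xs >= t]
        m = later.min() if len(later) else self.phis[-1]
        return float(min(self.value(t), m))

    # env protocol for the coalescent simulator (theta base 1.0)
    def size_factor(self, t: float) -> float:
        return self.value(t)

    def min_future_factor(self, t: float) -> float:
        return self.min_after(t)

    def window(self, t: float) -> tuple[float, float]:
        """(window end, min phi within): adaptive-thinning windows in which
        phi varies at most 2-fold."""
        if self.k == 0 or t >= self.ts[-1]:
            return np.inf, float(self.phis[-1])
        xs = np.concatenate([[0.0], self.ts])
        i = int(np.searchsorted(xs, t, side="right")) - 1
        x_end = xs[i + 1]
        y_t = self.value(t)
        y_end = float(self.phis[i + 1])
        if y_end >= y_t:
            return float(x_end), y_t
        if y_end >= y_t / 2.0:
            return float(x_end), y_end
        # steep drop: cut the window where phi has halved
        m = (y_end - self.value(float(xs[i]))) / (x_end - xs[i])
        x_half = t + (y_t / 2.0 - y_t) / m
        return float(min(x_half, x_end)), y_t / 2.0

    def integrate_inverse(self, a: float, b: float) -> float:
        """Integral of 1/phi(t) over [a, b] in closed form per segment."""
        if b <= a:
            return 0.0
        xs = np.concatenate([[0.0], self.ts, [np.inf]])
        ys = np.concatenate([self.phis, [self.phis[-1]]])
        total = 0.0
        for i in range(len(xs) - 1):
            lo, hi = max(a, xs[i]), min(b, xs[i + 1])
            if hi <= lo:
                continue
            if np.isinf(xs[i + 1]) or ys[i + 1] == ys[i]:
                total += (hi - lo) / ys[i]
            else:
                m = (ys[i + 1] - ys[i]) / (xs[i + 1] - xs[i])
                ya = ys[i] + m * (lo - xs[i])
                yb = ys[i] + m * (hi - xs[i])
                total += math.log(yb / ya) / m
        return total


def coal_log_density(coal_times: np.ndarray, n_tips: int, traj: Trajectory) -> float:
    """Log-density of an ultrametric coalescent under the trajectory
    (pairwise rate 2/phi(t), so j lineages coalesce at j(j-1)/phi)."""
    lp = 0.0
    t_prev = 0.0
    k = n_tips
    for t in coal_times:
        lp -= k * (k - 1) * traj.integrate_inverse(t_prev, t)
        lp += math.log(2.0 / traj.value(t))
        k -= 1
        t_prev = t
    return lp


def upgma_history(mat: np.ndarray) -> History:
    """UPGMA starting genealogy from per-site mismatch distances."""
    n = mat.shape[0]
    use = mat.min(axis=0) >= 0
    m = mat[:, use]
    L = max(m.shape[1], 1)
    D = np.zeros((n, n))
    for i in range(n):
        D[i] = (m != m[i]).sum(axis=1) / L
    Z = linkage(squareform(D, checks=False), method="average")
    events = []
    for k, (a, b, dist, _cnt) in enumerate(Z):
        events.append(("c", max(dist / 2.0, 1e-9 * (k + 1)), int(a), int(b), n + k, 0))
    events.sort(key=lambda e: e[1])
    return History(n, np.zeros(n, dtype=np.int64), events)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class SkylineChain:
    """Reversible-jump MCMC over (genealogy, size trajectory)."""

    def __init__(self, treelik: TreeLikelihood, priors: SkylinePriors,
                 settings: SkylineSettings, rng: np.random.Generator,
                 init_hist: History, allow_changepoints: bool = True,
                 beta: float = 1.0):
        self.tl = treelik
        self.priors = priors
        self.s = settings
        self.rng = rng
        self.beta = beta
        self.allow_cp = allow_changepoints and priors.cp_max > 0
        self.hist = init_hist.copy()
        self.traj = Trajectory(np.empty(0), np.array([priors.phi_init]))
        self.phi_mu = priors.phi_init
        self.t_cap = max(settings.tcap_factor * self.hist.root_time(), 1e-9)
        self.ll = self._loglik(self.hist)
        self.coal_lp = self._coal_lp(self.hist, self.traj)
        self.n_accept = 0
        self.n_steps = 0

    def _loglik(self, hist: History) -> float:
        times, children = hist.to_arrays()
        return self.tl.loglik_arrays(times, children)

    def _coal_lp(self, hist: History, traj: Trajectory) -> float:
        times, _ = hist.coal_times_and_counts()
        return coal_log_density(np.sort(times), hist.n_tips, traj)

    # -- moves ------------------------------------------------------------

    def _move_genealogy(self, regraft: bool) -> None:
        one = np.ones(1)
        M = np.zeros((1, 1))
        if regraft and self.hist.n_tips >= 3:
            prop = self.hist.regrafted(self.rng, one, M, env=self.traj)
        else:
            tau = self.rng.uniform(0.0, self.s.tcap_factor * max(self.hist.root_time(), 1e-9))
            prop = self.hist.regrown(self.rng, tau, one, M, env=self.traj)
            if prop is self.hist:
                self.n_accept += 1
                return
        ll_new = self._loglik(prop)
        if np.log(self.rng.random()) < self.beta * (ll_new - self.ll):
            self.hist = prop
            self.ll = ll_new
            self.coal_lp = self._coal_lp(prop, self.traj)
            self.n_accept += 1

    def _move_tree_scale(self) -> None:
        """Multiply all coalescence times by a common factor (Jacobian
        c^(n-1)); the coalescent prior is re-evaluated under the current
        trajectory, so depth and size trade off directly."""
        c = math.exp(self.s.sigma_tree_scale * self.rng.normal())
        prop = self.hist.scaled(c)
        lp_new = self._coal_lp(prop, self.traj)
        ll_new = self._loglik(prop)
        dim = self.hist.n_tips - 1
        log_acc = (self.beta * (ll_new - self.ll) + lp_new - self.coal_lp
                   + dim * math.log(c))
        if np.log(self.rng.random()) < log_acc:
            self.hist = prop
            self.ll = ll_new
            self.coal_lp = lp_new
            self.n_accept += 1

    def _move_size(self) -> None:
        i = int(self.rng.integers(len(self.traj.phis)))
        phi_old = self.traj.phis[i]
        phi_new = phi_old * math.exp(self.s.sigma_size * self.rng.normal())
        dprior = (self.priors.log_p_size(phi_new, self.phi_mu)
                  - self.priors.log_p_size(phi_old, self.phi_mu))
        if not np.isfinite(dprior):
            return
        phis = self.traj.phis.copy()
        phis[i] = phi_new
        cand = Trajectory(self.traj.ts, phis)
        lp_new = self._coal_lp(self.hist, cand)
        log_acc = lp_new - self.coal_lp + dprior + math.log(phi_new / phi_old)
        if np.log(self.rng.random()) < log_acc:
            self.traj = cand
            self.coal_lp = lp_new
            self.n_accept += 1

    def _move_mu(self) -> None:
        lo, hi = self.priors.phi_bounds
        mu_new = self.phi_mu * math.exp(self.s.sigma_mu * self.rng.normal())
        if not (lo <= mu_new <= hi):
            return
        dprior = sum(self.priors.log_p_size(phi, mu_new)
                     - self.priors.log_p_size(phi, self.phi_mu)
                     for phi in self.traj.phis)
        if np.log(self.rng.random()) < dprior + math.log(mu_new / self.phi_mu):
            self.phi_mu = mu_new
            self.n_accept += 1

    def _move_time(self) -> None:
        k = self.traj.k
        if k == 0:
            return
        i = int(self.rng.integers(k))
        lo = self.traj.ts[i - 1] if i > 0 else 0.0
        hi = self.traj.ts[i + 1] if i < k - 1 else self.t_cap
        t_new = self.rng.uniform(lo, hi)
        ts = self.traj.ts.copy()
        ts[i] = t_new
        cand = Trajectory(ts, self.traj.phis)
        lp_new = self._coal_lp(self.hist, cand)
        if np.log(self.rng.random()) < lp_new - self.coal_lp:
            self.traj = cand
            self.coal_lp = lp_new
            self.n_accept += 1

    def _log_q_size(self, phi: float, center: float) -> float:
        z = (math.log(phi) - math.log(center)) / self.s.sigma_birth
        return -math.log(phi * self.s.sigma_birth * math.sqrt(2 * math.pi)) - 0.5 * z * z

    def _move_jump(self) -> None:
        k = self.traj.k
        lo, hi = self.priors.phi_bounds
        lam = self.priors.cp_mean
        birth_prob = 1.0 if k == 0 else (0.0 if k >= self.priors.cp_max else 0.5)
        if self.rng.random() < birth_prob:
            # birth
            t_star = self.rng.uniform(0.0, self.t_cap)
            center = self.traj.value(t_star)
            phi_star = center * math.exp(self.s.sigma_birth * self.rng.normal())
            if not (lo <= phi_star <= hi):
                return
            pos = int(np.searchsorted(self.traj.ts, t_star))
            ts = np.insert(self.traj.ts, pos, t_star)
            phis = np.insert(self.traj.phis, pos + 1, phi_star)
            cand = Trajectory(ts, phis)
            lp_new = self._coal_lp(self.hist, cand)
            d_next = 1.0 if k + 1 >= self.priors.cp_max else 0.5
            log_acc = (math.log(lam / (k + 1)) + lp_new - self.coal_lp
                       + self.priors.log_p_size(phi_star, self.phi_mu)
                       - self._log_q_size(phi_star, center)
                       + math.log(d_next / birth_prob))
            if np.log(self.rng.random()) < log_acc:
                self.traj = cand
                self.coal_lp = lp_new
                self.n_accept += 1
        elif k > 0:
            # death
            death_prob = 1.0 if k >= self.priors.cp_max else 0.5
            j = int(self.rng.integers(k))
            t_rm, phi_rm = self.traj.ts[j], self.traj.phis[j + 1]
            ts = np.delete(self.traj.ts, j)
            phis = np.delete(self.traj.phis, j + 1)
            cand = Trajectory(ts, phis)
            lp_new = self._coal_lp(self.hist, cand)
            b_prev = 1.0 if k - 1 == 0 else 0.5
            log_acc = (math.log(k / lam) + lp_new - self.coal_lp
                       - self.priors.log_p_size(phi_rm, self.phi_mu)
                       + self._log_q_size(phi_rm, cand.value(t_rm))
                       + math.log(b_prev / death_prob))
            if np.log(self.rng.random()) < log_acc:
                self.traj = cand
                self.coal_lp = lp_new
                self.n_accept += 1

    def step(self) -> None:
        self.n_steps += 1
        s = self.s
        p_rj = max(0.0, 1.0 - s.p_regraft - s.p_regrow - s.p_tree_scale
                   - s.p_size - s.p_mu - s.p_time)
        if not self.allow_cp:
            tot = s.p_regraft + s.p_regrow + s.p_tree_scale + s.p_size + s.p_mu
            u = self.rng.random() * tot
            if u < s.p_regraft:
                self._move_genealogy(True)
            elif u < s.p_regraft + s.p_regrow:
                self._move_genealogy(False)
            elif u < s.p_regraft + s.p_regrow + s.p_tree_scale:
                self._move_tree_scale()
            elif u < s.p_regraft + s.p_regrow + s.p_tree_scale + s.p_size:
                self._move_size()
            else:
                self._move_mu()
            return
        u = self.rng.random()
        if u < s.p_regraft:
            self._move_genealogy(True)
        elif u < s.p_regraft + s.p_regrow:
            self._move_genealogy(False)
        elif u < s.p_regraft + s.p_regrow + s.p_tree_scale:
            self._move_tree_scale()
        elif u < s.p_regraft + s.p_regrow + s.p_tree_scale + s.p_size:
            self._move_size()
        elif u < s.p_regraft + s.p_regrow + s.p_tree_scale + s.p_size + s.p_mu:
            self._move_mu()
        elif u < (s.p_regraft + s.p_regrow + s.p_tree_scale + s.p_size
                  + s.p_mu + s.p_time):
            self._move_time()
        elif p_rj > 0:
            self._move_jump()


# ---------------------------------------------------------------------------
# posterior container and public operations
# ---------------------------------------------------------------------------

@dataclass
class SkylinePosterior:
    """Thinned posterior samples and their summaries.

    ``onset`` per sample is the beginning of growth (in substitution
    units) of trajectories whose modern size is at least twice the
    ancestral size: the most recent time at which the size was still
    within two-fold of the ancestral size (see ``_expansion_onset``) —
    NaN when undefined (no change point or no 2-fold growth).
    """

    clock: ClockModel
    priors: SkylinePriors
    n_tips: int
    k_samples: np.ndarray
    onset_samples: np.ndarray          # substitution units; NaN if undefined
    phi_modern: np.ndarray
    phi_ancestral: np.ndarray
    root_heights: np.ndarray
    ll_samples: np.ndarray
    trajectories: list                 # (ts, phis) per retained sample
    ess: dict = field(default_factory=dict)
    flagged: bool = False

    def p_k_geq(self, k: int) -> float:
        return float(np.mean(self.k_samples >= k))

    def onset_summary_years(self) -> tuple[float, float, float]:
        """(median, 2.5%, 97.5%) of the expansion onset, in years."""
        vals = self.onset_samples[~np.isnan(self.onset_samples)]
        if len(vals) == 0:
            return (math.nan,) * 3
        yrs = vals / self.clock.rate
        return (float(np.median(yrs)), float(np.quantile(yrs, 0.025)),
                float(np.quantile(yrs, 0.975)))

    def root_height_years(self) -> float:
        return float(np.median(self.root_heights) / self.clock.rate)

    def ne_grid(self, n_points: int = 50):
        """(times_years, median, lo, hi) of Ne(t) = phi(t)/rate."""
        tmax = float(np.quantile(self.root_heights, 0.9))
        grid = np.linspace(0.0, tmax, n_points)
        vals = np.empty((len(self.trajectories), n_points))
        for i, (ts, phis) in enumerate(self.trajectories):
            tr = Trajectory(ts, phis)
            vals[i] = [tr.value(t) for t in grid]
        ne = vals / self.clock.rate
        return (grid / self.clock.rate, np.median(ne, axis=0),
                np.quantile(ne, 0.025, axis=0), np.quantile(ne, 0.975, axis=0))

    def to_dict(self) -> dict:
        med, lo, hi = self.onset_summary_years()
        return {"onset_median_years": med, "onset_ci95_years": [lo, hi],
                "p_expansion": float(np.mean(~np.isnan(self.onset_samples))),
                "p_k_geq_1": self.p_k_geq(1),
                "root_height_years_median": self.root_height_years(),
                "ess": self.ess, "flagged": self.flagged}


def _expansion_onset(tr: Trajectory) -> float:
    """Beginning of growth, per trajectory, in substitution units.

    Defined for trajectories whose modern size is at least twice the
    ancestral size, as the most recent time at which the population was
    still within two-fold of its ancestral size — the boundary between
    the small ancestral regime and the growth toward the present,
    obtained by linear interpolation on the trajectory.  (Reading off
    the most recent change-point time instead would report prior-noise
    knots near the present whenever K > 1.)  NaN when undefined.
    """
    phi_anc = float(tr.phis[-1])
    if tr.k < 1 or tr.phis[0] < 2.0 * phi_anc:
        return math.nan
    level = 2.0 * phi_anc
    xs = np.concatenate([[0.0], tr.ts])
    ys = tr.phis
    # walk from the present into the past; first segment dipping to <= level
    for i in range(len(xs) - 1):
        y0, y1 = float(ys[i]), float(ys[i + 1])
        if y0 <= level:
            return float(xs[i])
        if y1 <= level:
            frac = (y0 - level) / (y0 - y1)
            return float(xs[i] + frac * (xs[i + 1] - xs[i]))
    return float(xs[-1])


def _default_skyline_model(mat: np.ndarray) -> SubstitutionModel:
    return gtr(rates=(1.0, 4.0, 1.0, 1.0, 4.0, 1.0),
               freqs=tuple(empirical_frequencies(mat)),
               gamma_shape=0.5, gamma_categories=4, prop_invariant=0.5)


def skyline_mcmc(alignment: dict[str, str], clock: ClockModel | None = None,
                 priors: SkylinePriors | None = None,
                 settings: SkylineSettings | None = None,
                 mutation_model: SubstitutionModel | None = None,
                 constant_size: bool = False) -> SkylinePosterior:
    """Sample the posterior of the skyline model on one alignment.

    Starts from a UPGMA genealogy; reports are converted to years via
    the strict clock.  ``constant_size=True`` pins the change-point
    count at zero (the null demography).
    """
    clock = clock or ClockModel()
    priors = priors or SkylinePriors()
    settings = settings or SkylineSettings()
    if len(alignment) < 3:
        raise ValueError("skyline analysis requires at least 3 sequences")
    ids, mat = encode_sequences(alignment)
    model = mutation_model or _default_skyline_model(mat)
    treelik = TreeLikelihood(dict(zip(ids, [alignment[i] for i in ids])), model)
    rng = np.random.default_rng(np.random.SeedSequence(settings.seed).spawn(1)[0])
    chain = SkylineChain(treelik, priors, settings, rng, upgma_history(mat),
                         allow_changepoints=not constant_size)
    chain_len, burn = settings.chain_length, settings.burn_in
    ks, onsets, phi0, phiA, roots, lls, trajs = [], [], [], [], [], [], []
    for i in range(burn + chain_len):
        chain.step()
        if i >= burn and (i - burn) % settings.thin == 0:
            tr = chain.traj
            ks.append(tr.k)
            onsets.append(_expansion_onset(tr))
            phi0.append(float(tr.phis[0]))
            phiA.append(float(tr.phis[-1]))
            roots.append(chain.hist.root_time())
            lls.append(chain.ll)
            trajs.append((tr.ts.copy(), tr.phis.copy()))
    from phylodeme.migration_fit import _ess
    ess = {"loglik": _ess(np.asarray(lls)), "phi_modern": _ess(np.asarray(phi0)),
           "root_height": _ess(np.asarray(roots))}
    flagged = min(ess.values()) < settings.ess_floor
    if flagged:
        logger.warning("skyline chain ESS %s below floor %.0f", ess, settings.ess_floor)
    return SkylinePosterior(clock, priors, len(ids), np.asarray(ks), np.asarray(onsets),
                            np.asarray(phi0), np.asarray(phiA), np.asarray(roots),
                            np.asarray(lls), trajs, ess, flagged)


def _ladder_samples(alignment, priors, settings, mutation_model, constant_size, seed):
    """Per-rung log-likelihood samples along the power ladder (incl. beta=1)."""
    ids, mat = encode_sequences(alignment)
    model = mutation_model or _default_skyline_model(mat)
    treelik = TreeLikelihood(dict(zip(ids, [alignment[i] for i in ids])), model)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    chain = SkylineChain(treelik, priors, settings, rng, upgma_history(mat),
                         allow_changepoints=not constant_size, beta=1.0)
    # equilibrate at the posterior, then anneal down the ladder so the
    # hardest (high-power) rungs start from a converged state
    for _ in range(settings.burn_in):
        chain.step()
    J = settings.ss_powers
    betas = (np.arange(J + 1) / J) ** (1.0 / settings.ss_alpha)
    rung_lls = [None] * (J + 1)
    for j in range(J, -1, -1):
        chain.beta = betas[j]
        for _ in range(settings.ss_burn_in):
            chain.step()
        lls = np.empty(settings.ss_chain_length)
        for i in range(settings.ss_chain_length):
            chain.step()
            lls[i] = chain.ll
        rung_lls[j] = lls
    return betas, rung_lls


def log_marginal_likelihood(alignment: dict[str, str], model: str = "skyline",
                            priors: SkylinePriors | None = None,
                            settings: SkylineSettings | None = None,
                            mutation_model: SubstitutionModel | None = None,
                            method: str = "stepping-stone"):
    """Marginal likelihood of the skyline or constant-size model.

    Stepping-stone by default; ``method="ti"`` gives the thermodynamic-
    integration (trapezoid) estimate from the same ladder.  Returns
    ``(log_ml, mc_se, diagnostics)``.
    """
    if model not in ("skyline", "constant"):
        raise ValueError("model must be 'skyline' or 'constant'")
    priors = priors or SkylinePriors()
    settings = settings or SkylineSettings()
    from phylodeme.migration_fit import _ess
    betas, rung_lls = _ladder_samples(alignment, priors, settings, mutation_model,
                                      model == "constant", settings.seed)
    min_ess = min(_ess(l) for l in rung_lls)
    if method == "stepping-stone":
        total, var_total = 0.0, 0.0
        for j in range(len(betas) - 1):
            lls = rung_lls[j]
            z = (betas[j + 1] - betas[j]) * lls
            zmax = z.max()
            w = np.exp(z - zmax)
            total += zmax + np.log(w.mean())
            var_total += np.var(w) / (max(_ess(w), 1.0) * w.mean() ** 2)
        se = float(np.sqrt(var_total))
    elif method == "ti":
        means = np.array([l.mean() for l in rung_lls])
        total = float(np.trapezoid(means, betas))
        sev = np.array([np.var(l) / max(_ess(l), 1.0) for l in rung_lls])
        dx = np.gradient(betas)
        se = float(np.sqrt(np.sum((dx / 2) ** 2 * sev) * 2))
    else:
        raise ValueError("method must be 'stepping-stone' or 'ti'")
    diag = {"min_rung_ess": float(min_ess),
            "flagged": bool(min_ess < settings.ess_floor)}
    if diag["flagged"]:
        logger.warning("marginal-likelihood ladder ESS %.1f below floor", min_ess)
    return float(total), se, diag


def bayes_factor(alignment: dict[str, str], priors: SkylinePriors | None = None,
                 settings: SkylineSettings | None = None,
                 mutation_model: SubstitutionModel | None = None) -> dict:
    """log Bayes factor of the skyline over the constant-size model."""
    ml_s, se_s, d_s = log_marginal_likelihood(alignment, "skyline", priors,
                                              settings, mutation_model)
    ml_c, se_c, d_c = log_marginal_likelihood(alignment, "constant", priors,
                                              settings, mutation_model)
    return {"log_ml_skyline": ml_s, "log_ml_constant": ml_c,
            "log_bayes_factor": ml_s - ml_c,
            "mc_se": float(np.hypot(se_s, se_c)),
            "diagnostics": {"skyline": d_s, "constant": d_c}}


def skyline_plot(posterior: SkylinePosterior, path) -> None:
    """Median Ne(t) with 95% band, time axis in years before present."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    t, med, lo, hi = posterior.ne_grid()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(t, lo, hi, alpha=0.3, label="95% interval")
    ax.plot(t, med, label="median")
    ax.set_yscale("log")
    ax.set_xlabel("years before present")
    ax.set_ylabel("effective population size")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
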