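"""Maximum-likelihood fitting of colonization scenarios.

For each scenario the likelihood of the data under the structured
coalescent is integrated over genealogies-with-migration-histories by
Markov chain Monte Carlo:

1. driving parameter values come from a moment (F_ST-style) estimate;
2. genealogies are sampled at the driving values by Metropolis-Hastings
   (regraft + regrow moves, see :mod:`phylodeme.mcmc_core`), and the
   maximum-likelihood parameters are found by reweighting the sampled
   histories with the ratio of structured-coalescent prior densities —
   the classic importance-ratio scheme, iterated so the driving values
   converge toward the optimum;
3. the absolute log-likelihood at the fitted parameters is estimated by
   stepping-stone sampling along a power-posterior ladder, which makes
   values comparable across scenarios and loci.

AIC = 2k - 2 LnL is attached to each fit; the mutation model defaults
to HKY with empirical base frequencies, adequate at intraspecific
divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from phylodeme.likelihood import TreeLikelihood
from phylodeme.mcmc_core import History
from phylodeme.model_select import aic, rank_models
from phylodeme.scenarios import MigrationScenario, enumerate_scenarios
from phylodeme.simulate import check_coalescible
from phylodeme.substitution import SubstitutionModel, hky85, encode_sequences, empirical_frequencies

logger = logging.getLogger(__name__)

THETA_BOUNDS = (1e-6, 10.0)
RATE_BOUNDS = (1e-6, 1e5)


@dataclass
class CoalescentParams:
    """Scaled sizes theta (per deme) and backward migration rates M."""

    thetas: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if np.any(self.thetas <= 0):
            raise ValueError("thetas must be positive")
        if np.any(self.M < 0):
            raise ValueError("migration rates must be non-negative")
        np.fill_diagonal(self.M, 0.0)

    def to_dict(self) -> dict:
        return {"thetas": self.thetas.tolist(), "M": self.M.tolist()}


@dataclass
class SamplerSettings:
    """Monte-Carlo budgets; all stages derive their streams from ``seed``."""

    chain_length: int = 1400        # beta=1 steps per driving iteration
    burn_in: int = 500
    thin: int = 2
    n_driving_iterations: int = 2
    ss_powers: int = 16             # stepping-stone rungs
    ss_chain_length: int = 1000
    ss_burn_in: int = 200
    ss_alpha: float = 0.3           # Beta(alpha, 1) rung spacing
    ss_extra_rungs: tuple[float, ...] = (0.82, 0.90, 0.96)
    p_regraft: float = 0.65
    p_scale: float = 0.15           # whole-history depth-scaling move
    scale_sigma: float = 0.25
    ess_floor: float = 10.0
    seed: int = 0


@dataclass
class FitResult:
    """Per-scenario maximum-likelihood fit."""

    scenario: str
    params: CoalescentParams
    lnl: float
    k: int
    mc_se: float
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def aic(self) -> float:
        return aic(self.lnl, self.k)

    def to_dict(self) -> dict:
        return {"scenario": self.scenario, "params": self.params.to_dict(),
                "LnL": self.lnl, "k": self.k, "AIC": self.aic, "mc_se": self.mc_se,
                "converged": self.converged, "diagnostics": self.diagnostics}


# ---------------------------------------------------------------------------
# data preparation and moment initialization
# ---------------------------------------------------------------------------

def _prepare(alignment: dict[str, str], deme_map: dict[str, str], deme_labels):
    ids, mat = encode_sequences(alignment)
    missing = [i for i in ids if i not in deme_map]
    if missing:
        raise ValueError(f"sequence ids missing from deme map: {missing[:5]}")
    bad = sorted({deme_map[i] for i in ids} - set(deme_labels))
    if bad:
        raise ValueError(f"deme labels {bad} not in {deme_labels}")
    lab_idx = {l: i for i, l in enumerate(deme_labels)}
    tip_demes = np.array([lab_idx[deme_map[i]] for i in ids], dtype=np.int64)
    return ids, mat, tip_demes


def moment_init(mat: np.ndarray, tip_demes: np.ndarray, nd: int,
                mask: np.ndarray) -> CoalescentParams:
    """F_ST-style moment starting values with a documented fallback.

    theta per deme is its mean pairwise difference per clean site
    (floored at 1e-4); free migration rates start at
    ``(1/F_ST - 1)/2`` from the global F_ST = 1 - pi_within/pi_total,
    clipped to [1, 500], falling back to 100 when F_ST is tiny or
    undefined.
    """
    use = mat.min(axis=0) >= 0
    m = mat[:, use]
    L = max(m.shape[1], 1)
    n = m.shape[0]
    diffs = np.zeros((n, n))
    for i in range(n):
        diffs[i] = (m != m[i]).sum(axis=1)
    thetas = np.full(nd, 1e-3)
    within = []
    for d in range(nd):
        rows = np.where(tip_demes == d)[0]
        if len(rows) >= 2:
            sub = diffs[np.ix_(rows, rows)]
            pi_d = sub[np.triu_indices(len(rows), 1)].mean() / L
            thetas[d] = max(pi_d, 1e-4)
            within.append(pi_d)
    pi_tot = diffs[np.triu_indices(n, 1)].mean() / L if n >= 2 else 0.0
    m0 = 100.0
    if within and pi_tot > 0:
        fst = 1.0 - np.mean(within) / pi_tot
        if fst > 1e-3:
            m0 = float(np.clip((1.0 / fst - 1.0) / 2.0, 1.0, 500.0))
    M = np.zeros((nd, nd))
    M[mask] = m0
    return CoalescentParams(thetas, M)


# ---------------------------------------------------------------------------
# the genealogy chain
# ---------------------------------------------------------------------------

class GenealogyChain:
    """Metropolis-Hastings over structured genealogies at fixed parameters.

    The target is ``P(D|G)^beta * p(G | params)``; proposals are drawn
    from the prior's own dynamics so acceptance is the tempered
    likelihood ratio.
    """

    def __init__(self, treelik: TreeLikelihood, tip_demes: np.ndarray,
                 params: CoalescentParams, rng: np.random.Generator,
                 beta: float = 1.0, p_regraft: float = 0.65,
                 p_scale: float = 0.15, scale_sigma: float = 0.25,
                 init_hist: History | None = None):
        self.tl = treelik
        self.tip_demes = tip_demes
        self.params = params
        self.rng = rng
        self.beta = beta
        self.p_regraft = p_regraft
        self.p_scale = p_scale
        self.scale_sigma = scale_sigma
        self.hist = (init_hist.copy() if init_hist is not None
                     else History.simulate(rng, tip_demes, params.thetas, params.M))
        self.ll = self._loglik(self.hist)
        self.tau_cap = max(2.0 * self.hist.root_time(), 1e-6)
        self.n_accept = 0
        self.n_steps = 0

    def _loglik(self, hist: History) -> float:
        times, children = hist.to_arrays()
        return self.tl.loglik_arrays(times, children)

    def _scale_move(self) -> None:
        c = float(np.exp(self.scale_sigma * self.rng.normal()))
        prop = self.hist.scaled(c)
        nd = len(self.params.thetas)
        _, A, Nm, B = self.hist.suffstats(nd)
        rowm = self.params.M.sum(axis=1)
        dlp = -(c - 1.0) * (np.sum(A / self.params.thetas) + np.sum(B * rowm))
        dim = (self.hist.n_tips - 1) + int(Nm.sum())
        ll_new = self._loglik(prop)
        if np.log(self.rng.random()) < self.beta * (ll_new - self.ll) + dlp + dim * np.log(c):
            self.hist = prop
            self.ll = ll_new
            self.n_accept += 1

    def step(self) -> None:
        self.n_steps += 1
        th, M = self.params.thetas, self.params.M
        u = self.rng.random()
        if u < self.p_scale and self.hist.n_tips >= 2:
            self._scale_move()
            return
        if u < self.p_scale + self.p_regraft and self.hist.n_tips >= 3:
            prop = self.hist.regrafted(self.rng, th, M)
        else:
            tau = self.rng.uniform(0.0, self.tau_cap)
            prop = self.hist.regrown(self.rng, tau, th, M)
            if prop is self.hist:
                self.n_accept += 1
                return
        ll_new = self._loglik(prop)
        if np.log(self.rng.random()) < self.beta * (ll_new - self.ll):
            self.hist = prop
            self.ll = ll_new
            self.n_accept += 1

    def run(self, n_steps: int, record_every: int = 0, record_stats: bool = False):
        """Advance the chain; optionally record (ll, suffstats) samples."""
        lls, stats = [], []
        for i in range(n_steps):
            self.step()
            if record_every and (i + 1) % record_every == 0:
                lls.append(self.ll)
                if record_stats:
                    stats.append(self.hist.suffstats(len(self.params.thetas)))
        return np.asarray(lls), stats




# ---------------------------------------------------------------------------
# importance-ratio maximization over parameters
# ---------------------------------------------------------------------------

def _stack_stats(stats):
    C = np.stack([s[0] for s in stats])
    A = np.stack([s[1] for s in stats])
    Nm = np.stack([s[2] for s in stats])
    B = np.stack([s[3] for s in stats])
    return C, A, Nm, B


def _log_prior_vec(C, A, Nm, B, thetas, M):
    """Vectorized structured-coalescent log-density over sampled histories.

    Histories with migration events on zero-rate entries get -inf.
    """
    row = M.sum(axis=1)
    safe_logM = np.log(np.where(M > 0, M, 1.0))
    mig = (Nm * safe_logM[None, :, :]).sum(axis=(1, 2))
    out = (C * np.log(2.0 / thetas)[None, :]).sum(1) - (A / thetas[None, :]).sum(1) \
        + mig - (B * row[None, :]).sum(1)
    incompatible = (Nm[:, M <= 0] > 0).any(axis=1)
    out[incompatible] = -np.inf
    return out


def maximize_is_ratio(stats, params0: CoalescentParams, mask: np.ndarray):
    """ML parameters from histories sampled at driving values ``params0``.

    Maximizes the importance-ratio likelihood estimate
    ``log mean_k p(G_k|params) / p(G_k|params0)`` over the free
    parameters (masked rates pinned at 0).  Histories containing
    migration events on masked entries contribute zero weight; if none
    are compatible the ratio is -inf.  Returns
    ``(params, log_ratio, se, n_compatible, success)``.
    """
    C, A, Nm, B = _stack_stats(stats)
    K = len(C)
    lp0 = _log_prior_vec(C, A, Nm, B, params0.thetas, params0.M)
    free = np.argwhere(mask)
    nd = len(params0.thetas)
    masked = ~mask.copy()
    np.fill_diagonal(masked, False)
    compatible = ~(Nm[:, masked] > 0).any(axis=1)
    n_comp = int(compatible.sum())
    if n_comp == 0:
        return (CoalescentParams(params0.thetas, np.where(mask, RATE_BOUNDS[0], 0.0)),
                -np.inf, np.inf, 0, False)
    Cc, Ac, Nc, Bc = C[compatible], A[compatible], Nm[compatible], B[compatible]
    lp0c = lp0[compatible]

    def unpack(x):
        thetas = np.exp(x[:nd])
        M = np.zeros((nd, nd))
        for idx, (i, j) in enumerate(free):
            M[i, j] = np.exp(x[nd + idx])
        return thetas, M

    def log_ratio(x):
        thetas, M = unpack(x)
        lp = _log_prior_vec(Cc, Ac, Nc, Bc, thetas, M)
        return logsumexp(lp - lp0c) - np.log(K)

    th_init = np.clip(params0.thetas, THETA_BOUNDS[0] * 2, THETA_BOUNDS[1] / 2)
    m_init = [np.clip(max(params0.M[i, j], 1.0), RATE_BOUNDS[0] * 2, RATE_BOUNDS[1] / 2)
              for i, j in free]
    x0 = np.concatenate([np.log(th_init), np.log(m_init)])
    bounds = [(np.log(THETA_BOUNDS[0]), np.log(THETA_BOUNDS[1]))] * nd \
        + [(np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1]))] * len(free)
    res = minimize(lambda x: -log_ratio(x), x0, method="L-BFGS-B", bounds=bounds)
    thetas, M = unpack(res.x)
    lr = float(log_ratio(res.x))
    # delta-method MC error of the log-mean of the (autocorrelated) weights
    lw = _log_prior_vec(Cc, Ac, Nc, Bc, thetas, M) - lp0c
    w = np.exp(lw - lw.max())
    se = float(np.std(w) / (w.mean() * np.sqrt(max(_ess(w), 1.0))) * np.sqrt(n_comp / K))
    return CoalescentParams(thetas, M), lr, se, n_comp, bool(res.success)


# ---------------------------------------------------------------------------
# stepping-stone absolute likelihood
# ---------------------------------------------------------------------------

def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive autocorrelation sum."""
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for rho in acf[1:]:
        if rho <= 0:
            break
        s += rho
    return float(n / (1.0 + 2.0 * s))


def stepping_stone(treelik: TreeLikelihood, tip_demes: np.ndarray,
                   params: CoalescentParams, settings: SamplerSettings,
                   rng: np.random.Generator,
                   init_hist: History | None = None):
    """Stepping-stone estimate of ln P(D | params) with a Monte-Carlo SE.

    The power ladder beta_j = (j/J)^(1/alpha) (quantiles of a
    Beta(alpha, 1) spacing) connects prior and posterior; one chain is
    annealed DOWN the ladder, starting from an (ideally equilibrated)
    posterior state so the hardest, high-power rungs need the least
    burn-in.  Each rung contributes
    ``log E_{beta_j}[ P(D|G)^(beta_{j+1}-beta_j) ]``.
    """
    J = settings.ss_powers
    base = (np.arange(J + 1) / J) ** (1.0 / settings.ss_alpha)
    betas = np.unique(np.concatenate([base, np.asarray(settings.ss_extra_rungs)]))
    J = len(betas) - 1
    chain = GenealogyChain(treelik, tip_demes, params, rng, beta=1.0,
                           p_regraft=settings.p_regraft, p_scale=settings.p_scale,
                           scale_sigma=settings.scale_sigma, init_hist=init_hist)
    total = 0.0
    var_total = 0.0
    min_ess = np.inf
    for j in range(J - 1, -1, -1):
        chain.beta = betas[j]
        chain.run(settings.ss_burn_in)
        lls, _ = chain.run(settings.ss_chain_length, record_every=1)
        dbeta = betas[j + 1] - betas[j]
        z = dbeta * lls
        zmax = z.max()
        w = np.exp(z - zmax)
        total += zmax + np.log(w.mean())
        ess = _ess(w)
        min_ess = min(min_ess, ess)
        var_total += np.var(w) / (max(ess, 1.0) * w.mean() ** 2)
    se = float(np.sqrt(var_total))
    diagnostics = {"acceptance": chain.n_accept / max(chain.n_steps, 1),
                   "min_rung_ess": float(min_ess),
                   "degenerate": bool(min_ess < settings.ess_floor)}
    return float(total), se, diagnostics


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def estimate_loglik(alignment: dict[str, str], deme_map: dict[str, str],
                    params: CoalescentParams, settings: SamplerSettings | None = None,
                    deme_labels=("F", "S", "A"),
                    mutation_model: SubstitutionModel | None = None):
    """Monte-Carlo estimate of ln P(data | params) and its standard error.

    Integrates over structured-coalescent genealogies and migration
    histories at the given parameters by stepping-stone sampling;
    reproducible under a fixed ``settings.seed``.
    """
    settings = settings or SamplerSettings()
    ids, mat, tip_demes = _prepare(alignment, deme_map, deme_labels)
    occupied = np.bincount(tip_demes, minlength=len(deme_labels)) > 0
    if len(ids) > 1:
        check_coalescible(occupied, params.M)
    model = mutation_model or hky85(4.0, tuple(empirical_frequencies(mat)))
    treelik = TreeLikelihood(dict(zip(ids, [alignment[i] for i in ids])), model)
    rng = np.random.default_rng(np.random.SeedSequence(settings.seed).spawn(1)[0])
    lnl, se, diag = stepping_stone(treelik, tip_demes, params, settings, rng)
    if diag["degenerate"]:
        logger.warning("stepping-stone rung ESS %.1f below floor %.1f",
                       diag["min_rung_ess"], settings.ess_floor)
    return lnl, se, diag


def _driving_fit(treelik, tip_demes, mat, mask, settings, seedseqs):
    """Iterated importance-ratio maximization at driving values.

    Returns (fitted params, last chain state, diagnostics)."""
    nd = mask.shape[0]
    params = moment_init(mat, tip_demes, nd, mask)
    hist = None
    acc = 0.0
    opt_ok = True
    for it in range(settings.n_driving_iterations):
        rng = np.random.default_rng(seedseqs[it])
        chain = GenealogyChain(treelik, tip_demes, params, rng,
                               p_regraft=settings.p_regraft,
                               p_scale=settings.p_scale,
                               scale_sigma=settings.scale_sigma,
                               init_hist=hist)
        chain.run(settings.burn_in)
        _, stats = chain.run(settings.chain_length, record_every=settings.thin,
                             record_stats=True)
        hist = chain.hist
        acc = chain.n_accept / max(chain.n_steps, 1)
        params, _, _, _, ok = maximize_is_ratio(stats, params, mask)
        opt_ok = opt_ok and ok
    return params, hist, {"acceptance": acc, "optimizer_success": opt_ok}


def fit_scenario(alignment: dict[str, str], deme_map: dict[str, str],
                 scenario: MigrationScenario, settings: SamplerSettings | None = None,
                 deme_labels=("F", "S", "A"),
                 mutation_model: SubstitutionModel | None = None) -> FitResult:
    """Maximum-likelihood theta and migration rates under one scenario.

    Only the scenario's free parameters are optimized (masked rates
    pinned at 0): genealogies-with-histories are sampled at driving
    values (F_ST-style moment estimates, refined by iterated
    importance-ratio maximization) and the absolute LnL at the optimum
    is then estimated by stepping-stone sampling, annealed down a shared
    power ladder — which makes LnL, and hence AIC, comparable across
    scenarios fitted on the same data.
    """
    settings = settings or SamplerSettings()
    ids, mat, tip_demes = _prepare(alignment, deme_map, deme_labels)
    nd = len(deme_labels)
    mask = scenario.backward_mask(tuple(deme_labels))
    occupied = np.bincount(tip_demes, minlength=nd) > 0
    probe = np.zeros((nd, nd))
    probe[mask] = 1.0
    check_coalescible(occupied, probe)
    model = mutation_model or hky85(4.0, tuple(empirical_frequencies(mat)))
    treelik = TreeLikelihood(dict(zip(ids, [alignment[i] for i in ids])), model)
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_driving_iterations + 1)
    params, hist, diag = _driving_fit(treelik, tip_demes, mat, mask, settings, seeds)
    lnl, se, ss_diag = stepping_stone(treelik, tip_demes, params, settings,
                                      np.random.default_rng(seeds[-1]), init_hist=hist)
    diag.update(ss_diag)
    converged = diag["optimizer_success"] and not ss_diag["degenerate"]
    if not converged:
        logger.warning("fit of %s flagged: %s", scenario.name, diag)
    return FitResult(scenario.name, params, float(lnl), scenario.k, float(se),
                     diag, converged)


def fit_all_scenarios(alignment, deme_map, settings: SamplerSettings | None = None,
                      deme_labels=("F", "S", "A"),
                      mutation_model: SubstitutionModel | None = None,
                      include_full: bool = True):
    """Fit the nine constrained scenarios (plus the full model) and rank them.

    Every scenario is fitted with the identical Monte-Carlo budget,
    ladder and seed (common random numbers), so the large shared
    component of the stepping-stone error cancels from the AIC
    differences that drive the ranking; only comparably estimated LnL
    values are ever ranked against each other.
    """
    settings = settings or SamplerSettings()
    scens = enumerate_scenarios(tuple(deme_labels))
    if not include_full:
        scens = [s for s in scens if s.kind != "full"]
    results = [fit_scenario(alignment, deme_map, s, settings, deme_labels,
                            mutation_model) for s in scens]
    table = rank_models([{"scenario": f.scenario, "k": f.k, "LnL": f.lnl}
                         for f in results])
    return results, table
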