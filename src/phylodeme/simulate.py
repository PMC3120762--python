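"""Structured-coalescent simulation with finite-sites mutation.

The simulator is the synthetic counterpart of the inference machinery: it
draws genealogies from the 3-deme structured coalescent under a
colonization scenario's migration mask, optionally with a recent
demographic expansion, and then evolves sequences along the genealogy
under a reversible substitution model.  Defaults emulate the shape of an
intraspecific mitochondrial dataset: three demes, a ~600 bp locus,
shallow diversity, and a recent ~10-fold expansion.

Time is in expected substitutions per site; deme *i* holding *j* lineages
coalesces at rate ``j (j-1) / theta_i`` and each lineage in deme *i*
migrates backward to deme *j* at rate ``M[i, j]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from phylodeme.genealogy import Genealogy
from phylodeme.scenarios import MigrationScenario, enumerate_scenarios
from phylodeme.substitution import SubstitutionModel, hky85, decode_sequences

_MAX_EVENTS = 10_000_000


@dataclass(frozen=True)
class GrowthSpec:
    """Two-epoch expansion: ancestral size constant, linear ramp to present.

    ``onset_time`` is the start of growth, backward from the present, in
    substitution-time units; ``ratio`` is present size / ancestral size
    (>1 for an expansion).  The shared size factor applied to every deme is
    1 at time 0, declines linearly to ``1/ratio`` at ``onset_time`` and
    stays there into the indefinite past.
    """

    onset_time: float
    ratio: float

    def __post_init__(self) -> None:
        if self.onset_time <= 0 or self.ratio <= 0:
            raise ValueError("growth onset time and size ratio must be positive")

    def size_factor(self, t: float) -> float:
        if t >= self.onset_time:
            return 1.0 / self.ratio
        return 1.0 - (1.0 - 1.0 / self.ratio) * (t / self.onset_time)

    def min_future_factor(self, t: float) -> float:
        return min(self.size_factor(t), 1.0 / self.ratio)

    def window(self, t: float) -> tuple[float, float]:
        """(window end, min size factor within) for adaptive thinning.

        Windows are chosen so the size factor varies at most 2-fold,
        keeping the rejection rate of the thinning sampler bounded.
        """
        if t >= self.onset_time or self.ratio == 1.0:
            return np.inf, 1.0 / self.ratio
        s_t = self.size_factor(t)
        if self.ratio < 1.0:    # size grows into the past: min on window is s(t)
            return self.onset_time, s_t
        target = max(s_t / 2.0, 1.0 / self.ratio)
        x = self.onset_time * (1.0 - target) / (1.0 - 1.0 / self.ratio)
        x = min(max(x, np.nextafter(t, np.inf)), self.onset_time)
        return x, target


def _default_scenario() -> MigrationScenario:
    return next(s for s in enumerate_scenarios(("F", "S", "A")) if s.name == "S>A>F")


def _default_model() -> SubstitutionModel:
    # AT-rich composition and elevated transition bias typical of
    # invertebrate mitochondrial protein-coding sequence
    return hky85(kappa=4.0, freqs=(0.25, 0.15, 0.15, 0.45))


@dataclass
class SimulationConfig:
    """Full specification of one synthetic single-locus dataset.

    Defaults reproduce the COI-like study condition: demes F/S/A with
    34/52/52 sequences (138 total) of a 604 bp maternally inherited
    haploid locus under the sequential S>A>F colonization scenario, with
    a founder-style expansion (size ratio 5000) beginning 1.5e-4
    substitution-time units ago (about 3,500 years at a clock of
    4.28e-8 substitutions/site/year).  The large present-day theta makes
    the genealogy star-like inside the expansion epoch, which yields the
    singleton-dominated shallow diversity of the emulated data
    (about 13 haplotypes and about 17 segregating sites, most of them
    singletons, among 138 sequences).
    """

    deme_labels: tuple[str, ...] = ("F", "S", "A")
    sample_sizes: tuple[int, ...] = (34, 52, 52)
    scenario: MigrationScenario = field(default_factory=_default_scenario)
    theta: float | tuple[float, ...] = 0.5
    migration_rates: float | dict[tuple[str, str], float] = 500.0
    growth: GrowthSpec | None = field(default_factory=lambda: GrowthSpec(1.5e-4, 5000.0))
    locus_length: int = 604
    mutation_model: SubstitutionModel = field(default_factory=_default_model)
    ploidy_mode: str = "haploid-maternal"
    inheritance_scalar: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy_mode not in ("haploid-maternal", "diploid-phased"):
            raise ValueError("ploidy_mode must be 'haploid-maternal' or 'diploid-phased'")
        if len(self.sample_sizes) != len(self.deme_labels):
            raise ValueError("one sample size per deme required")
        if any(s < 0 for s in self.sample_sizes):
            raise ValueError("sample sizes must be non-negative")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")
        if np.any(np.asarray(self.thetas()) <= 0):
            raise ValueError("theta must be positive in every deme")
        if np.any(self.migration_matrix() < 0):
            raise ValueError("migration rates must be non-negative")

    @classmethod
    def coi_like(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """The default mitochondrial study condition (see class docstring)."""
        return cls(seed=seed, **overrides)

    @classmethod
    def hsp70_like(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Nuclear diploid study condition: 38 individuals (10/14/14 per
        deme, 76 phased sequences) of a 219 bp locus; theta is 4x the
        mitochondrial value (autosomal inheritance scalar), giving the
        deeper coalescent and cross-deme haplotype sharing expected of a
        nuclear marker."""
        kw = dict(sample_sizes=(10, 14, 14), theta=2.0, locus_length=219,
                  growth=GrowthSpec(1.5e-4, 2000.0),
                  ploidy_mode="diploid-phased", inheritance_scalar=4.0,
                  mutation_model=hky85(2.0, (0.3, 0.2, 0.25, 0.25)))
        kw.update(overrides)
        return cls(seed=seed, **kw)

    def n_demes(self) -> int:
        return len(self.deme_labels)

    def n_sequences(self) -> tuple[int, ...]:
        """Sequences (tips) per deme; 2x individuals in diploid mode."""
        mult = 2 if self.ploidy_mode == "diploid-phased" else 1
        return tuple(mult * s for s in self.sample_sizes)

    def thetas(self) -> np.ndarray:
        th = self.theta
        if np.isscalar(th):
            return np.full(self.n_demes(), float(th))
        th = np.asarray(th, dtype=float)
        if th.shape != (self.n_demes(),):
            raise ValueError("theta must be scalar or one value per deme")
        return th

    def migration_matrix(self) -> np.ndarray:
        """Backward rate matrix with the scenario mask applied."""
        mask = self.scenario.backward_mask(self.deme_labels)
        M = np.zeros_like(mask, dtype=float)
        if np.isscalar(self.migration_rates):
            M[mask] = float(self.migration_rates)
        else:
            lab = {l: i for i, l in enumerate(self.deme_labels)}
            for (src, dst), v in self.migration_rates.items():
                i, j = lab[src], lab[dst]
                if not mask[i, j] and v != 0:
                    raise ValueError(f"rate {src}->{dst} is masked to zero by scenario {self.scenario.name}")
                M[i, j] = float(v)
        return M


# ---------------------------------------------------------------------------
# coalescent core
# ---------------------------------------------------------------------------

def check_coalescible(occupied: np.ndarray, M: np.ndarray) -> None:
    """Raise if lineages in the occupied demes cannot a.s. find a common deme.

    Tracing a lineage backward, its deme follows a Markov chain on the
    digraph of positive backward rates; it is eventually absorbed into a
    closed communicating class.  All lineages coalesce with probability 1
    iff every occupied deme reaches exactly one closed class and it is the
    same class for all of them.
    """
    d = M.shape[0]
    adj = (M > 0)
    reach = np.eye(d, dtype=bool) | adj
    for _ in range(d):
        reach = reach | (reach @ reach)
    scc_id = np.full(d, -1)
    n_scc = 0
    for i in range(d):
        if scc_id[i] < 0:
            members = np.where(reach[i] & reach[:, i])[0]
            scc_id[members] = n_scc
            n_scc += 1
    closed = []
    for s in range(n_scc):
        members = np.where(scc_id == s)[0]
        if np.all(scc_id[np.where(reach[members[0]])[0]] == s):
            closed.append(s)
    targets = set()
    for o in np.where(occupied)[0]:
        reached = {s for s in closed if np.any(scc_id[np.where(reach[o])[0]] == s)}
        if len(reached) != 1:
            raise ValueError("non-coalescible configuration: deme "
                             f"{o} can be absorbed into {len(reached)} closed deme classes")
        targets |= reached
    if len(targets) != 1:
        raise ValueError("non-coalescible configuration: occupied demes are "
                         "absorbed into different closed deme classes")


def simulate_history(
    rng: np.random.Generator,
    nodes: list[int],
    node_demes: list[int],
    t0: float,
    thetas: np.ndarray,
    M: np.ndarray,
    growth: GrowthSpec | None = None,
    next_parent: int = None,
):
    """Run the structured coalescent from an arbitrary starting state.

    ``nodes`` are subtree-root identifiers active at time ``t0`` with
    current demes ``node_demes``.  Returns ``(coal_events, mig_events)``
    where coalescences are ``(t, child1, child2, parent, deme)`` with
    fresh ``parent`` ids counting up from ``next_parent``, and migrations
    are ``(t, node, src, dst)``.
    """
    nd = len(thetas)
    by_deme = [[] for _ in range(nd)]
    for v, dm in zip(nodes, node_demes):
        by_deme[dm].append(v)
    k = np.array([len(b) for b in by_deme], dtype=float)
    if next_parent is None:
        next_parent = (max(nodes) + 1) if nodes else 0
    row_m = M.sum(axis=1)
    coal_events, mig_events = [], []
    t = t0
    n_active = int(k.sum())
    guard = 0
    while n_active > 1:
        guard += 1
        if guard > _MAX_EVENTS:
            raise RuntimeError("event budget exhausted; configuration may be effectively non-coalescible")
        if growth is not None:
            w_end, s_min = growth.window(t)
        else:
            w_end, s_min = np.inf, 1.0
        coal_base = k * (k - 1) / thetas
        coal_max = coal_base.sum() / s_min
        mig_tot = float((k * row_m).sum())
        lam = coal_max + mig_tot
        if lam <= 0:
            if np.isinf(w_end):
                raise ValueError("non-coalescible configuration: all rates zero with >1 lineage")
            t = w_end
            continue
        t_cand = t + rng.exponential(1.0 / lam)
        if t_cand >= w_end:
            t = w_end
            continue
        t = t_cand
        s_now = growth.size_factor(t) if growth else 1.0
        coal_now = coal_base.sum() / s_now
        u = rng.random() * lam
        if u < coal_now:
            # coalescence; deme proportional to k_i(k_i-1)/theta_i
            p = coal_base / coal_base.sum()
            deme = rng.choice(nd, p=p)
            group = by_deme[deme]
            i1, i2 = rng.choice(len(group), size=2, replace=False)
            c1, c2 = group[i1], group[i2]
            parent = next_parent
            next_parent += 1
            for c in sorted((i1, i2), reverse=True):
                group.pop(c)
            group.append(parent)
            coal_events.append((t, c1, c2, parent, int(deme)))
            k[deme] -= 1
            n_active -= 1
        elif u < coal_max:
            continue  # thinning rejection of a time-varying coalescence
        else:
            w = (k * row_m)
            src = rng.choice(nd, p=w / w.sum())
            dst = rng.choice(nd, p=M[src] / M[src].sum())
            group = by_deme[src]
            idx = rng.integers(len(group))
            v = group.pop(idx)
            by_deme[dst].append(v)
            mig_events.append((t, v, int(src), int(dst)))
            k[src] -= 1
            k[dst] += 1
    return coal_events, mig_events


def assemble_genealogy(tip_ids, tip_demes, deme_labels, coal_events, mig_events) -> Genealogy:
    """Build a canonical :class:`Genealogy` from raw event lists.

    Internal nodes are renumbered chronologically to ``n..2n-2``
    regardless of the temporary parent ids used during simulation.
    """
    n = len(tip_ids)
    coal_events = sorted(coal_events, key=lambda e: e[0])
    remap = {v: v for v in range(n)}
    times = np.zeros(2 * n - 1)
    children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
    coal_demes = np.zeros(max(n - 1, 0), dtype=np.int64)
    for idx, (t, c1, c2, parent, deme) in enumerate(coal_events):
        new_id = n + idx
        remap[parent] = new_id
        times[new_id] = t
        children[new_id] = (remap[c1], remap[c2])
        coal_demes[idx] = deme
    mig_events = sorted(mig_events, key=lambda e: e[0])
    mt = np.array([e[0] for e in mig_events], dtype=float)
    mn = np.array([remap[e[1]] for e in mig_events], dtype=np.int64)
    ms = np.array([e[2] for e in mig_events], dtype=np.int64)
    md = np.array([e[3] for e in mig_events], dtype=np.int64)
    return Genealogy(list(tip_ids), np.asarray(tip_demes, dtype=np.int64), tuple(deme_labels),
                     times, children, coal_demes, mt, mn, ms, md)


def _tip_layout(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    """Sequence record ids and deme indices, in deme order."""
    ids, demes = [], []
    for d, (label, n_ind) in enumerate(zip(config.deme_labels, config.sample_sizes)):
        for i in range(n_ind):
            sid = f"{label}{i + 1:03d}"
            if config.ploidy_mode == "diploid-phased":
                for allele in (1, 2):
                    ids.append(f"{sid}|{label}|{allele}")
                    demes.append(d)
            else:
                ids.append(f"{sid}|{label}")
                demes.append(d)
    return ids, np.array(demes, dtype=np.int64)


def simulate_genealogy(config: SimulationConfig, rng: np.random.Generator | None = None) -> Genealogy:
    """Draw one genealogy under the configured structured coalescent."""
    tip_ids, tip_demes = _tip_layout(config)
    if len(tip_ids) == 0:
        raise ValueError("at least one sample is required")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    thetas = config.thetas()
    M = config.migration_matrix()
    occupied = np.bincount(tip_demes, minlength=config.n_demes()) > 0
    if occupied.sum() >= 1 and len(tip_ids) > 1:
        check_coalescible(occupied, M)
    if len(tip_ids) == 1:
        return assemble_genealogy(tip_ids, tip_demes, config.deme_labels, [], [])
    coal, mig = simulate_history(rng, list(range(len(tip_ids))), list(tip_demes), 0.0,
                                 thetas, M, config.growth, next_parent=len(tip_ids))
    return assemble_genealogy(tip_ids, tip_demes, config.deme_labels, coal, mig)


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

def mutate_encoded(gen: Genealogy, model: SubstitutionModel, length: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Evolve encoded sequences (codes 0..3) down the genealogy.

    The root sequence is drawn from the stationary frequencies; each
    branch applies the model's transition matrices at the branch length
    scaled by the site's rate class.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    cats, w = model.rate_classes()
    site_cat = rng.choice(len(cats), size=length, p=w)
    n = gen.n_tips
    states = np.empty((gen.n_nodes, length), dtype=np.int8)
    pi = np.asarray(model.freqs)
    states[gen.root] = rng.choice(4, size=length, p=pi)
    bl = gen.branch_lengths()
    for v in range(gen.root, n - 1, -1):
        for c in gen.children[v]:
            P = model.transition_matrices(bl[c] * cats)     # (ncat, 4, 4)
            cum = np.cumsum(P, axis=-1)
            rows = cum[site_cat, states[v], :]              # (L, 4)
            u = rng.random(length)
            states[c] = (u[:, None] > rows).sum(axis=1).astype(np.int8)
    return states[:n]


def mutate_on_genealogy(gen: Genealogy, model: SubstitutionModel, length: int,
                        seed: int) -> dict[str, str]:
    """One aligned sequence per tip, as id -> ACGT string."""
    rng = np.random.default_rng(seed)
    mat = mutate_encoded(gen, model, length, rng)
    return dict(zip(gen.tip_ids, decode_sequences(mat)))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def truth_record(config: SimulationConfig) -> dict:
    """JSON-serializable record of the generating process."""
    return {
        "deme_labels": list(config.deme_labels),
        "sample_sizes": list(config.sample_sizes),
        "n_sequences": list(config.n_sequences()),
        "scenario": config.scenario.name,
        "theta": config.thetas().tolist(),
        "migration_matrix": config.migration_matrix().tolist(),
        "growth": None if config.growth is None else
            {"onset_time": config.growth.onset_time, "ratio": config.growth.ratio},
        "locus_length": config.locus_length,
        "mutation_model": config.mutation_model.name,
        "base_frequencies": list(config.mutation_model.freqs),
        "ploidy_mode": config.ploidy_mode,
        "inheritance_scalar": config.inheritance_scalar,
        "seed": config.seed,
        "seed_streams": "SeedSequence(seed).spawn(2) -> [genealogy, mutation]",
    }


def generate_dataset(config: SimulationConfig, out_dir: str | Path | None = None):
    """Simulate an aligned dataset; optionally write FASTA/TSV/JSON.

    Returns ``(alignment, deme_map, truth)`` where ``alignment`` maps
    sequence id to ACGT string and ``deme_map`` maps sequence id to deme
    label.  With ``out_dir`` set, writes ``alignment.fasta``,
    ``deme_map.tsv`` and ``truth.json`` there; identical config and seed
    produce byte-identical files.
    """
    ss = np.random.SeedSequence(config.seed)
    gen_ss, mut_ss = ss.spawn(2)
    gen = simulate_genealogy(config, rng=np.random.default_rng(gen_ss))
    mat = mutate_encoded(gen, config.mutation_model, config.locus_length,
                         np.random.default_rng(mut_ss))
    alignment = dict(zip(gen.tip_ids, decode_sequences(mat)))
    deme_map = {tid: config.deme_labels[d] for tid, d in zip(gen.tip_ids, gen.tip_demes)}
    truth = truth_record(config)
    if out_dir is not None:
        from phylodeme import io as pio
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_fasta(out / "alignment.fasta", alignment)
        pio.write_deme_map(out / "deme_map.tsv", deme_map)
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return alignment, deme_map, truth
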