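# Methods

This note documents the models behind `phylodeme`, the choices made where
the design was genuinely open, and what the synthetic-data experiments do
and do not demonstrate.

## Scaling conventions

Time is measured in expected substitutions per site throughout.  The
scaled size of deme *i* is `theta_i = x * N_i * mu` per site, with
inheritance scalar `x` (1 for a maternally inherited haploid locus, 4
for a nuclear autosomal locus).  Operationally, *j* lineages in deme *i*
coalesce at total rate `j (j-1) / theta_i` per unit time (so a pair in
isolation coalesces after `theta/2` on average), and a lineage in deme
*i* jumps backward in time to deme *j* at rate `M[i, j]` per unit time.
A forward-time colonization edge `X>Y` (gene flow from X into Y)
corresponds to the free backward rate `M[Y, X]`; every other
off-diagonal entry of a constrained scenario is pinned to zero.  These
conventions are shared by the simulator, the likelihood machinery and
the skyline sampler; nothing else in the package depends on absolute
population sizes or calendar time except the strict-clock conversion at
reporting.

## The candidate colonization models

For three demes (France F, Sardinia S, Algeria A) each origin X yields
one independent-colonization hypothesis (`X>Y, X>Z`) and two sequential
ones (`X>Y>Z`, `X>Z>Y`): nine constrained models, each with k = 5 free
parameters (three deme sizes + two backward rates), plus the
unconstrained full model with k = 9.  The full model takes part in
fitting and is reported in the tables, but is excluded from the
best-versus-runner-up ΔAIC comparison, which is defined over the nine
biogeographic hypotheses only; with the published numbers the full
model would otherwise displace the runner-up while adding no
biogeographic content.

## Synthetic data

`simulate_genealogy` draws structured-coalescent genealogies with
explicit migration histories by competing exponential clocks, with a
windowed thinning scheme for time-varying population size (windows are
chosen so the size factor varies at most two-fold, which keeps the
rejection rate bounded even for severe founder-style expansions).
Before simulating, the deme configuration is checked for
coalescibility: every occupied deme must be absorbed, backward in time,
into one and the same closed communicating class of the positive-rate
digraph.  Reaching a *common deme* alone is not sufficient — a deme
that can reach two closed classes can strand lineages apart forever —
so the check is phrased in terms of closed classes.

Mutations are applied by a site-wise continuous-time Markov chain
(JC69, HKY85 or GTR, optionally with discrete-Gamma rate classes and a
proportion of invariant sites; category rates are bin means of the
Gamma, rescaled to mixture mean 1).  The root sequence is drawn from
the stationary frequencies.  The simulator is cross-checked in the test
suite against msprime run at matched parameters (pairwise diversity,
site-frequency spectrum, between-deme divergence under asymmetric
migration).

### Default study conditions

The default configuration emulates the shape of the mitochondrial
dataset the package is designed around: 3 demes with 34/52/52 sequences
(138 total), a 604 bp haploid maternal locus, sequential `S>A>F`
colonization, and shallow, singleton-dominated diversity (about 13
haplotypes and about 17 variable sites).  Reproducing the
singleton-dominated site pattern requires a near-star genealogy inside
the expansion epoch, which fixes the defaults at `theta = 0.5` per deme
(a modern population large enough that drift since founding is
negligible), backward rates of 500 on the free edges, and a two-epoch
linear expansion of ratio 5000 beginning 1.5e-4 substitution units
before present (about 3,500 years at the default clock, inside the
credible window the skyline analysis of the real data reports).  A
single-onset three-deme model cannot simultaneously reproduce the
per-deme haplotype-diversity gradient (0.16/0.14/0.07) and the
site-class counts; the defaults favour the site-class counts, and the
per-deme haplotype diversities come out around 0.3.  The nuclear preset
(`hsp70_like`) uses 38 diploid individuals emitted pre-phased (76
records), a 219 bp locus, `theta` four-fold larger (autosomal scalar)
and a milder effective expansion, reproducing the per-site diversity
(~0.004) and the cross-deme haplotype sharing expected of a nuclear
marker; it, too, is a compromise (about 8 haplotypes rather than 10).

Randomness: one root seed per dataset; `SeedSequence(seed).spawn(2)`
yields the genealogy and mutation streams, recorded in the truth
record.  Identical configuration and seed give byte-identical output
files.

## Haplotype statistics and networks

Haplotypes are exact sequence identities after uppercasing; IUPAC
heterozygote codes are rejected (nuclear data must arrive phased), and
alignment columns containing gaps or N are excluded from distances and
site statistics with a logged count.  Diversity is Nei's unbiased
`h = n/(n-1) (1 - sum p_i^2)`; nucleotide diversity is the mean
pairwise difference per clean site over all pairs without replacement.
A variable column is parsimony-informative iff at least two bases each
occur in at least two sequences; otherwise every base carried by
exactly one sequence counts as one singleton mutation.

The probability that a j-step connection between two haplotypes is
parsimonious is computed under a uniform-sites model: j mutation events
on an L-site sequence are parsimoniously reconstructable iff no site is
hit twice (a repeated hit always shortens the observable path, either
as a back mutation or as a two-step change at one site), giving
`P(j, L) = prod_{i=1}^{j-1} (1 - i/L)`.  The connection limit is the
largest j with `P >= 0.95` (8 steps at 604 bp), capped at L.  The test
suite validates the limit against a Monte-Carlo oracle that simulates
the mutation process directly.

Networks connect haplotype pairs in order of increasing Hamming
distance (ties broken by summed frequency, then lexicographic id); a
pair at distance d is joined through d-1 inferred intermediates only if
the current network does not already realize a path of at most d steps,
so equal-length alternatives between sampled haplotypes survive as
loops.  On up to six haplotypes the construction is checked
exhaustively against the minimal-connection networks found by subset
search.

## Migration-rate inference

The likelihood of a scenario is the probability of the alignment
integrated over genealogies-with-migration-histories under the
structured coalescent.  The machinery:

* **Felsenstein pruning** over compressed site patterns with
  per-pattern rescaling evaluates `P(D | G)` exactly for any timed
  genealogy; transition matrices come from the eigendecomposition of
  the reversible rate matrix and are built inside the numba kernel.
* **Metropolis-Hastings over histories** uses three moves whose
  proposal densities cancel exactly against the structured-coalescent
  prior at the driving parameters, so acceptance is the (tempered)
  sequence-likelihood ratio alone: single-lineage regraft (the
  structured-coalescent density factorizes exactly into the remaining
  forest's density times the resimulation measure of the detached
  lineage), regrow-above-tau (erase and resimulate everything above a
  uniformly drawn time), and a whole-history depth scaling with the
  usual Jacobian correction.  The moves are validated against direct
  prior simulation at beta = 0.
* **Importance-ratio maximization**: histories sampled at driving
  values are reweighted by the ratio of prior densities (a function of
  per-deme coalescence counts, lineage-time integrals and per-edge
  event counts), and the ratio estimate is maximized over the free
  parameters in log space; driving values start at F_ST-style moment
  estimates and the procedure is iterated.
* **Stepping-stone sampling** provides the absolute `ln P(D | params)`
  at the fitted optimum: a single chain is equilibrated at the
  posterior and annealed *down* a Beta(0.3, 1)-spaced power ladder with
  extra rungs near beta = 1 (where the variance contribution
  concentrates).

LnL values from separate Monte-Carlo runs share a large common error
component; all ten models are therefore fitted with the identical
budget, ladder and seed, so that this component cancels from the AIC
differences that drive the ranking.  Reported per-fit standard errors
reflect within-ladder variance only and understate the absolute
uncertainty of a single LnL; differences between same-seed fits are far
more precise than the individual values.  Residual Monte-Carlo noise in
the ranking is a few log units, which is also the order of the
between-scenario signal at the recovery experiment's settings.  In
consequence, the replicate-summed AIC (which averages the residual
noise over datasets) reliably identifies the generating scenario, while
the per-replicate minimum-AIC winner is recovered in only a minority of
replicates at budgets that run in minutes: the true scenario typically
sits within a few AIC units of the top of the table rather than at its
head.  A colonization signal carried purely by equilibrium directional
migration is weak at sixty sequences of 600 bp; the published analyses
of real data drew their much larger ΔAIC margins from more sequences
and stronger asymmetry.  LnL values are not expected to match any published
numbers (different estimator, different data); only the AIC arithmetic
and the ranking semantics carry over.

## Skyline dating

The demographic model is a single-deme coalescent with scaled size
`phi(t)` piecewise linear between K change points: pairwise coalescence
rate `2/phi(t)`, `phi = x * Ne * referenceـrate`.  Priors: K truncated
Poisson(2) on {0..4}; change times uniform on a window of 1.5 initial
(UPGMA) tree heights; knot sizes exponential (truncated to the bounds)
around a population mean whose prior is uniform on [1e4, 1e12] with
initial value 1e6.  The hierarchical size prior matters: a flat prior
spanning eight decades would penalize every additional change point by
about 10.7 nats (a Lindley-Bartlett effect) and freeze the
change-point count at zero regardless of signal.

K is sampled by reversible-jump birth/death moves rather than by
per-count marginalization — one chain replaces five and yields the same
posterior.  Genealogy updates reuse the regraft/regrow machinery with
the time-varying size factor.  The expansion onset ("beginning of
population growth") is operationalized, for posterior trajectories
whose modern size is at least twice the ancestral size, as the most
recent time at which the trajectory is still within two-fold of its
ancestral size, by linear interpolation; summaries (median, 95%
interval) are over the samples where the statistic is defined.
Reading off the most recent change-point *time* instead is not a
consistent estimator of the onset: with a Poisson(2) prior on the
change-point count, trajectories usually carry an extra prior-noise
knot between the true onset and the present, and that knot — not the
growth — would define the statistic.

The population-size prior is mapped once, at prior construction, to the
coalescent scale using a reference rate (default 4.28e-8
substitutions/site/year).  The sampled chain is therefore independent
of the clock rate, which enters only as the final division of
substitution-time summaries by the rate — making reported times exactly
inversely proportional to the clock, as the time-rescaling tests
assert.  The strict-clock default of 4.28e-8 is the lineage-specific
mitochondrial rate the package's study system uses.

Marginal likelihoods for the skyline-versus-constant comparison use
stepping-stone sampling along the same kind of ladder (thermodynamic
integration over the identical rung samples is available as a
cross-check).  At test-sized data the skyline-minus-constant log Bayes
factor is small relative to its Monte-Carlo error even for genuine
ten-fold expansions; the package reports it with its error rather than
claiming detection power it does not have at those sizes.

## Problem sizes used in tests and the acceptance script

The test suite runs every stochastic experiment at deliberately modest
sizes chosen to keep the full suite in the tens of minutes on one core:
scenario recovery uses 3 x 20 sequences of 600 bp at theta = 0.01 with
backward rate 30 on the colonization edges; skyline coverage uses 30
sequences of 600 bp with a 10-fold expansion and 20,000-step chains
(the onset posterior is bimodal — an unidentifiable very-recent size
regime trades off against unresolved near-present coalescence times —
and shorter chains under-explore the growth mode); oracle comparisons
use two-sequence or few-deme configurations where closed forms or
quadrature are available.  The acceptance script re-runs the same
experiments with reduced replicate counts (8 recovery datasets, 6
coverage replicates).  Passing these experiments shows the estimators
are calibrated at these sizes under the generator's assumptions
(no recombination, no selection, panmictic demes, a single locus); it
does not demonstrate power on real data, where rate variation,
sampling structure and model misspecification add error the generator
does not emulate.

## Known limitations

* The fitting model assumes constant deme sizes; data simulated (or
  collected) under strong expansion is fitted under that
  misspecification, exactly as the tool chain it re-implements did.
* Monte-Carlo noise of a single absolute LnL is several log units at
  default budgets; rankings rely on common-random-number cancellation.
* The synthetic generator has no population-split events (a spec
  non-goal); colonization is encoded purely as directional migration,
  which carries a weaker direction signal than a founder split would.
* Statistical-parsimony probability uses the uniform-sites no-repeat
  model; rate heterogeneity across sites would lower true parsimony
  probabilities slightly.
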