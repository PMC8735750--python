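# Methods

`refugia` implements joint-SFS demographic model selection and
introgression-aware coalescent analysis for a three-population system
(a desert lineage DST, a southern lineage STH and a plains lineage PLN,
with an outgroup — the lineage structure of the Texas horned lizard
across the southwestern and central United States).  This note records
the models,
the estimators, the numerical choices, and what the synthetic-data
experiments do and do not demonstrate.

## Units and parameterisations

Two conventions coexist deliberately, one per sub-literature:

* **Model-comparison demographies** (the ten-model registry) use
  diffusion-style relative units: population sizes `nu` in units of a
  reference size N_ref, epoch durations `T` in units of 2·N_ref
  generations, and scaled migration rates `M = 2·N_ref·m`, where `m` is
  the per-generation probability that a lineage's parent is a migrant.
  Migration rates are stored in the backward (lineage-movement)
  convention: `m12` is the rate at which DST lineages trace into STH.
* **The introgression (MSci) model** uses mutation-scaled units
  throughout: node ages `tau` and population sizes `theta = 4·N·mu` are
  both expected substitutions per site.

`coal_time_to_subs` / `subs_to_coal_time` convert between the systems
given a reference theta.  The simulators express either system in
msprime's absolute units through an arbitrary internal constant
(N_ref = 10,000; per-generation rate 1e-7) that cancels from every
observable; haploid samples are drawn on a diploid timescale so that
within-population diversity equals theta.

## The ten-model registry

The fixed topology is ((STH, PLN), DST): an ancestral population splits
into DST and an eastern ancestor, which later splits into STH and PLN.
Gene flow, where a model allows it, is restricted to the adjacent pairs
DST–STH and STH–PLN ("all" variants add DST–PLN).  The `split_*` family
activates migration from each split onward; the `refugia_*` family is
divergence in isolation followed by a secondary-contact epoch.  The two
headline models are `refugia_adj_2`
(isolation after the first split, adjacent gene flow after the second)
and its nested `refugia_barrier` variant (the same history with the
DST–STH rate pinned to zero — the riverine-barrier hypothesis).  The
other eight structures are reconstructions from their community-
conventional names; they live in one declarative registry so a
structure can be corrected without touching solver code.  The contact
onset for `refugia_adj_1` (between the splits) and `refugia_adj_3`
(terminal sub-epoch only), and the single-epoch ancestral contact in
the `split_*` family, are the registry's documented readings.  `k` per
model is the count of registry free parameters; nesting relations used
by the LRT machinery are tabulated explicitly.

## Expected spectra: branch-length Monte Carlo

The expected joint SFS of a model is computed by simulating
genealogies under the structured coalescent of its epoch plan and
accumulating, for every branch, its length into the joint
leaf-count cell it subtends (branch length is the Rao-Blackwellised
sufficient statistic for Poisson mutations, so no mutation noise enters).
The engine draws all randomness from a pre-generated uniform tensor
consumed in a fixed pattern — inverse-CDF waiting times, cumulative-rate
event selection — so for a fixed (seed, n_reps) the map from parameters
to spectrum is deterministic and nearly continuous, which is what makes
simplex optimisation over it feasible.  Replicates that exceed the
uniform budget (possible only under extreme migration) fall back to an
inline counter-based stream with migration frozen, the correct
strong-migration limit.  Validation: the single-population spectrum
matches the neutral E[xi_i] ∝ 1/i law to <3% at 10,000 replicates, and
spectra built from msprime-simulated SNPs converge to the engine's
expectation (the two implementations are independent).

## Composite likelihood and the staged fit

The likelihood is multinomial over unmasked folded cells with the
parameter-free coefficient omitted; observed mass on a
Monte-Carlo-empty cell is floored (1e-300), and inside the optimiser a
uniform pseudo-probability alpha = 1e-6 regularises those empty cells
(negligible wherever the expectation is resolved).  Optimisation
follows the staged community schedule — four rounds of
replicates = (10, 20, 30, 40) restarts, each a log-space Nelder–Mead
capped at maxiter = (3, 5, 10, 15), starts log-uniformly perturbed up
to a factor 2^fold with fold = (3, 2, 2, 1) around the incumbent — and
then, because those short caps make the staged phase a stochastic
search rather than a convergent one, a terminal polish: Nelder–Mead
restarts with shrinking initial-simplex spreads (0.4, 0.15, 0.05 in log
units) at 4× the replicate count, alternated with a line search along
the time-rescaling ridge.  That ridge is the direction
(nu, T) → c·(nu, T), M → M/c, which rescales genealogical time and
leaves the normalised spectrum invariant except through the pinned
ancestral size; it is the weakly identified direction of every
multinomial SFS fit, and the dedicated line search is what lets the
optimiser traverse it.  Search bounds are [1e-3, 1e3] for sizes and
times and [1e-4, 1e2] for migration rates (the event-driven engine's
cost grows with the migration rate, and rates at the cap are already
effectively panmictic).  Reported lnL is the exact (unsmoothed)
likelihood at the polish fidelity; AIC = 2k − 2 lnL with k the number
of parameters actually searched.

## Ranking and adjusted likelihood-ratio tests

Akaike machinery is standard: dAIC, relL = exp(−dAIC/2), weights
normalised to one, and the 95% confidence set as the smallest
cumulative-weight prefix.  Because the likelihood is composite
(projection and within-locus linkage), likelihood-ratio statistics are
rescaled by the Godambe sandwich factor df / tr(J·H⁻¹), with J the
covariance of bootstrap score vectors (resampling unit: the locus,
which coincides with the SNP under the one-SNP-per-locus design) and H
the observed curvature, both estimated by one-sided finite differences
of step 0.01 in the tested directions at the nested optimum (one-sided
because the tested rates sit at the zero boundary; H uses per-direction
second differences — cross terms are second-order for the one- and
two-parameter tests used here).  A migration rate fixed at zero lies on
the boundary of the parameter space, so p-values default to the 50:50
mixture of a point mass at zero and chi-square(df) (switchable to the
plain chi-square); a non-positive adjusted statistic yields p = 1.

## Minimum-divergence estimators and the bias experiments

Between-population per-locus distances behave like a shifted
exponential: location 2·tau (sequences cannot coalesce below the node
age) plus an exponential-scale coalescent excess.  With noise-free
distances the MLE of the location is the sample minimum
(`fit_shifted_exponential`).  With finite loci each distance carries
Poisson mutation noise of sd sqrt(d/L), and the minimum over thousands
of pairs is pinned at or near zero by that noise alone, so the
location-bearing statistic is the per-locus closest cross pair — the
same construction as the t_min coalescent bound, which is what a single
introgressed or hybrid lineage collapses — fitted by the exact marginal
likelihood of K ~ Poisson(L·(2·tau + e)), e ~ Exp(theta)
(`fit_poisson_shifted_exponential`, an incomplete-gamma form).  The
ancestral scale is the moment complement mean(d) − 2·tau_hat.  The
excess is not exactly exponential (deep root branches fatten its tail),
which leaves a residual ~5–10% downward tilt in the root-contrast
location at the experiment scales; the phi = 0 control quantifies it.

The bias experiment simulates under the introgression model (posterior-
mean parameter scale), estimates with the no-gene-flow estimators, and
compares against the no-gene-flow reading of the network (root contrast
resolves at tau_S, inner contrast at tau_T).  With phi_C = 0.25 the
inner time collapses by ~95% and the inferred ancestral size inflates
several-fold — the characteristic underestimate-times/overestimate-
sizes signature of ignoring gene flow — while the phi = 0 control arm
shows no systematic shift beyond the documented tilt.  The hybrid
experiment appends one individual whose loci descend from a donor
population with probability `mixing_prob` but is labelled as its host
population; its donor-derived loci carry within-population-scale
distances, collapsing both the raw minimum divergence and the root time
estimate, as the minimum-divergence argument predicts.

Experiment scales: 2 haploid samples per ingroup population, 250–300
loci of 10–15 kb.  Long loci are required here because the
minimum-divergence statistics must rise above mutation noise
(sd/2tau = 1/sqrt(2·tau·L) ≈ 0.07 at tau = 0.006, L = 15 kb); the
data-simulator default of 100 bp loci reflects the short loci of real
GBS data sets, and the locus length is a free configuration knob.

## Label-swap unidentifiability

For a bidirectional-introgression pair (X, Y), `label_swap` maps
phi → 1 − phi on both sides and exchanges theta_X and theta_Y.  The
twin generates an identical data distribution exactly when the two
parental paths above the pair are exchangeable — for the A↔B pair this
is the near-trichotomy regime (tau_S = tau_T) that the empirical
posterior occupies; away from it, and for the C↔D pair (whose parental
paths are structurally asymmetric), the twin is only approximately
equivalent and enough data can separate the peaks.  The equivalence
battery therefore tests the A↔B swap at the trichotomous vector, where
KS tests on per-locus divergences reject at the nominal rate only.

## Calibration

All conversions are exact arithmetic: age in My = tau / mu with
mu = 0.0008 substitutions/site/My; Ne = theta / (4·u) with the
per-generation rate u = mu·1e-6·(generation time 2 yr); the empirical
rate from an external calibration is mu = tau / T (T = 20 My to the
outgroup).  Printed values use half-up decimal rounding, guarded
against binary float representation.

## Synthetic-data generator: scope

The generator emulates the structure of the target data sets — three populations plus
outgroup, hundreds of unlinked loci, infinite-sites mutation, one
retained SNP per locus, a folded 3D JSFS, an optional single recently
admixed individual — with independent genealogies per locus and no
recombination within loci, no sequencing error, no missing-data
process, and no reference-bias or allele-dropout artefacts of real GBS
data.  Passing tests therefore demonstrate the correctness of the
estimators and the direction/magnitude of the modelled biases under the
stated coalescent assumptions, not robustness to wet-lab artefacts.
Loci are simulated in seeded chunks of 256 msprime replicates with
per-locus mutation seeds; a locus is reproducible by replaying at most
one chunk, and a whole data set is bit-reproducible from (seed,
configuration).  One SNP per locus is an unbiased draw from the branch
proportions only when the per-locus mutation rate is low (the retained
SNP of a high-theta locus over-represents short-tree loci); the
recovery experiment therefore uses many low-theta loci
(theta_locus = 0.2), matching the GBS regime.

## Experiment design choices

* Recovery: split_nomig at nu = (1, 1, 1), T1 = 0.5, T2 = 0.2, folded
  JSFS from one SNP in each of 26,000 low-theta loci (≥5,000 retained
  SNPs), ancestral size held at the reference in the refit (the sizes
  the experiment varies are the three terminal populations'), engine at
  1,500–2,000 replicates with 4× polish.
* Null LRT calibration: barrier truth, 600 loci per replicate, the
  barrier hypothesis fitted as the full model with the DST contact rate
  pinned, 20–25 bootstrap spectra, and a symmetrising cross-refit (each
  arm restarted from the other's optimum) so that a basin found by one
  arm cannot masquerade as evidence for gene flow.
* KS batteries: 500–1,000 loci per simulation, 10–20 seeds, alpha 0.01.

## Known limitations

* The expected-SFS engine is Monte Carlo: likelihood surfaces carry a
  seed-fixed jitter (common random numbers make it a deterministic
  roughness, not noise), bounded by the replicate count; reported lnL
  values are comparable only at the same (seed, n_reps).
* The eight name-only model structures are conventional
  reconstructions; the registry is the single place to amend them.
* Per-parameter uncertainty is limited to the Godambe machinery needed
  for adjusted LRTs; no per-parameter standard deviations are reported.
* The minimum-divergence estimators assume exchangeable loci of equal
  length and an exponential excess; heavy ancestral tails tilt the root
  location slightly downward, and rate variation across loci would add
  bias the model does not capture.
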