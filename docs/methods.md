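# Methods

This note documents the models implemented in `asmpipe`, the defaults
and why they were chosen, and what the synthetic-data tests do and do
not demonstrate.

## The stepwise assembly model

A local community of richness *S* is treated as the endpoint of
*S*\_pool − *S* sequential removals from the regional pool (the union of
species observed across all transects, with their standardized traits
and occupancy counts). The three removal operators:

* **Stochastic.** Species *i* is removed with probability proportional
  to 1/*f*<sub>i</sub>, *f*<sub>i</sub> being its occupancy (number of
  transects where it occurs). "Negatively related to pool frequency"
  admits several kernels; inverse proportionality keeps all
  probabilities positive and makes widespread species nearly immortal,
  which is the intended behaviour. A linear-complement kernel
  (`kernel="complement"`, p ∝ 1 − f/(max f + 1)) is available for
  sensitivity analysis.
* **Filtering.** Deterministic removal of the species with the largest
  Euclidean distance, in the full standardized trait space, to the
  habitat optimum. When fitting observed data the optimum is the
  *observed* community trait mean, held fixed over the removal
  sequence. Distance ties break to the lexicographically smaller
  species id.
* **Limiting similarity.** Find the globally closest pair; remove the
  member whose second-nearest neighbour (excluding the partner) is
  closer — it is the more redundant of the two. Ties break to the
  smaller id. With fewer than three species left the step falls back
  to a stochastic removal (logged).

Step order within a simulation is a uniformly shuffled permutation of
the step multiset (`order_policy="shuffled"`); a fixed
stochastic→filter→limiting order is available. Nothing in the data
identifies the order, and shuffling avoids artifacts from always
filtering first.

## Summary statistics

Four statistics summarize a community in trait space: FRic (convex-hull
volume), FEve (minimum-spanning-tree evenness), FDiv (dispersion of
distances to the hull-vertex centroid) and the vector of community
trait means (CTM, unweighted arithmetic means — the assembly model is
presence-based, so no abundance weighting anywhere).

Hull-based indices (FRic, FDiv) are computed on the first *m* principal
coordinates of the pooled standardized trait matrix, *m* = 3 by default:
a 6-D hull requires at least seven affinely independent species and is
numerically fragile at realistic community sizes, and dimensionality
reduction is the standard remedy in the functional-diversity
literature. FEve has no such constraint and is computed on full-space
distances, where the niche signatures (clustering under filtering,
overdispersion under limiting similarity) are undiluted. CTMs always
use the original standardized traits. Degenerate geometries cascade:
coincident points give FRic 0; lower-rank point sets are projected onto
their own principal axes (a 1-D "volume" is the range); a degenerate
hull in FDiv falls back to the all-species centroid; FEve/FDiv are
undefined below three species and are then dropped from the ABC
distance (logged).

## ABC-SMC

* **Prior**: uniform on the discrete composition simplex
  {(n_r, n_f, n_l) : sum = total}; nothing in the problem privileges
  any composition a priori on the reported (percentage) scale.
* **Move kernel**: move one step from a uniformly chosen nonempty
  category to a uniformly chosen other category. Symmetric in the
  simplex interior, not on the boundary.
* **Weights**: standard sequential importance weights (uniform prior ⇒
  w ∝ 1 / kernel mixture density over the previous population).
  An early unweighted variant — justified by the near-symmetry of the
  kernel — measurably collapsed the population onto low-variance
  regions of the simplex: filtering-heavy compositions produce almost
  deterministic communities, dominate acceptance at intermediate
  tolerances, and then monopolize resampling. The importance weights
  counteract exactly this clustering, and recovery experiments on
  self-consistent synthetic data improved accordingly.
* **Distance**: Euclidean over (FRic, FEve, FDiv, CTM…), each component
  divided by its scale. Scales are the per-statistic standard
  deviations over 1,000 prior-predictive simulations per transect
  (computed once per transect and shared across replicate runs). The
  CTM components additionally carry a √k factor (k = number of traits)
  so the CTM *vector* has the weight of one statistic among four:
  because the filtering optimum *is* the observed CTM, filter-heavy
  compositions reproduce every CTM component by construction, and a
  distance dominated by k CTM terms is structurally biased toward
  filtering regardless of the truth. `ctm_block_weight=False` restores
  plain per-component scaling.
* **Tolerance schedule**: ε_g is the `shrink_quantile` quantile
  (default 0.2) of the previous generation's accepted distances. The
  aggressive default shortens the passage through intermediate
  tolerances where the low-variance filtering attractor operates;
  quantiles up to 0.5 behave similarly but cost more simulations.
* **Stopping**: a generation is abandoned — the previous one is the
  posterior — when its attempts-per-acceptance ratio exceeds
  1/`stop_acceptance_rate` (default 20,000, i.e. a final acceptance
  rate of 1 in 20,000; the reported runs in this package's tests use
  1 in 2,000). Two convergence guards can stop earlier: ε improving by
  less than `min_eps_improvement` (default 2%) per generation — the
  distance noise floor — and an optional `max_generations`.
* **Estimates**: weighted posterior-mean percentages, averaged over
  `n_replicates` (default 3) runs seeded seed, seed+1, seed+2.
* **Performance**: proposal, forward simulation, FEve and CTM terms run
  in compiled (numba) code; the hull-based terms are evaluated only
  when the partial distance has not already exceeded the tolerance
  (a lower-bound rejection that cannot change which candidates are
  accepted). A transect fit at test scale (200 particles, stop 1/2,000,
  pool 30) takes seconds to tens of seconds on one core.

### Known estimator behaviour

Parameter-recovery experiments (see `tests/test_acceptance.py`) show
that interior mixes are recovered without systematic bias at survey
level, while extreme mixes (pure stochastic, pure filtering) are pulled
toward the simplex interior by 20–30 percentage points at the reduced
test settings. Two mechanisms, both intrinsic to the method rather than
to this implementation: (i) the filtering optimum equals the observed
CTM, so moderate filtering admixtures can mimic any single observed
community ("chasing the realization"); (ii) at a finite final
acceptance rate the posterior retains mass on compositions adjacent to
a corner, and the posterior mean of a boundary-concentrated
distribution is necessarily interior. Users comparing surveys should
rely on relative differences in the estimates rather than their
absolute distance from 0% or 100%.

## Null ensembles and the observed-vs-null contrasts

Fully stochastic ensembles ((total, 0, 0) compositions) and best-fit
ensembles (compositions drawn from the posterior particles, communities
kept only if their distance is at most the fit's final tolerance) are
simulated n_rep = 100 times per transect. Ensemble occurrence
frequencies (0…1) serve as relative abundances for dissimilarity
analyses. Trait–environment models are refit to each replicate's trait
means *with the observed data's final model formula* — no re-selection —
and coefficients/R² averaged, so the ensemble columns answer "what
would this exact model show without niche processes", not "what model
would have been selected".

## Mixed models

CTM ~ depth + sand + complexity with a sampling-cluster random
intercept, REML, both sides z-scored (sample sd). Backward elimination
drops the least significant fixed effect (Wald t, df = n − k − 1; the
small-sample correction matters at n = 36) until all retained p ≤ α =
0.05, ties broken alphabetically for determinism. Conditional and
marginal R² follow the variance-partition form: R²_cond = (σ²_fixed +
σ²_intercept)/(σ²_fixed + σ²_intercept + σ²_residual) with σ²_fixed the
variance of the fixed-effect linear predictor. Non-converging or
singular mixed fits fall back to OLS (random-intercept variance 0),
flagged on the result. No multiple-testing correction across traits is
applied by default, mirroring the analysis this package reproduces.

## Dissimilarity analyses

Bray–Curtis on raw counts by default (a `relative` flag normalizes
rows); the environmental distance normalizes each variable's pairwise
absolute differences by their maximum — scores lie in [0, 1], so the
total Euclidean combination lies in [0, √3]. (The source analysis
describes the normalized scores as lying "between −1 and 1"; absolute
differences cannot be negative, and this is treated as a wording slip.)
The Mantel test is one-sided (positive association), permuting transect
labels jointly in rows and columns; when the full permutation group is
no larger than the requested permutation count the test enumerates it
exactly (n ≤ 7 at the default test sizes), otherwise Monte-Carlo with
the add-one correction. The observed-vs-null slope contrast stacks
pair-level records and fits dissimilarity ~ distance × group by OLS;
pair records share transects and are not independent — the interaction
p-value inherits this (classical distance-decay ANCOVA caveat), and a
one-pair-per-transect subsample refit is provided as a diagnostic.

## Synthetic data generator

Emulates the survey structure the analyses assume: ~49-species pool
with multivariate-normal traits (exchangeable correlation,
default 0), 36 transects in 12 clusters of 3, depth with a
cluster-level component (cluster sd 3 m, within-cluster sd 0.5 m around
a 7 m mean), sand cover uniform on [0.05, 0.95], complexity 1 + Gamma(2,
0.25); the three variables are independent by construction. Communities
assemble through the forward model itself with a configurable step mix;
the trait optimum is a linear function of the z-scored environment
(default: depth shifts trait 1 with slope 1). Richness is uniform on
15–30 (mean ≈ 22). Abundance counts follow a geometric rank-abundance
profile (ratio 0.75, giving a few dominant species) scaled so a
transect's expected total is 274 × (1 − sand) ≈ 137 individuals at
mid-range sand — benign (rocky) transects hold more individuals.

Because the stochastic kernel needs occupancies that only exist once
communities exist, generation iterates: latent lognormal "commonness"
weights (sd 1) seed a first pass; a second pass re-assembles every
community using the first pass's realized occupancies. Species never
observed in any transect are trimmed from the realized dataset; the
ground-truth record therefore stores, per transect, both the nominal
step composition and the *effective* composition (steps whose removed
species survive trimming) — the latter is the quantity the fitted
model, whose pool is the union of observed species, can recover.

What the generator does not emulate: observation error (diver counts,
photographic sand estimation), within-species trait variation,
spatial autocorrelation beyond the cluster intercept, and temporal
turnover. Passing recovery tests therefore demonstrate internal
consistency of model + inference, not robustness to these field
realities.

## Numerical conventions

Standardization uses the sample standard deviation (ddof = 1)
throughout. All tie-breaks (argmax/argmin, MST edges, pair choice,
backward elimination) resolve by species-id / name order so every
stage is bit-reproducible under a fixed seed; replicate r of transect t
derives its stream from (seed + r, t). Sand given as percentages is
auto-detected (values > 1) and rescaled. Step-count targets derived from
percentage mixes use largest-remainder rounding so counts always sum to
the step total.
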