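# Methods

## Relationship complexes from co-membership logs

For each expedition (the *current* one) we consider every strictly earlier
expedition — "previous" always means a smaller `time_index`, and ties are
disallowed by validation, so no expedition is ever its own history. Each
history roster is intersected with the current roster; a subset *s* of the
current roster (|*s*| ≥ 2) has support equal to the number of history
expeditions whose intersection contains *s*, and enters the complex at
threshold τ when support ≥ τ, with weight = support.

Two interpretation choices matter and are deliberate:

- **Containment counting.** A previous expedition of size *m* supports
  *every* subset of its roster-intersection, not only the exact
  intersection. This makes support monotone non-increasing under
  supersets, so the complex is closed under inclusion by construction,
  thresholding preserves closure automatically, and large simplices are
  naturally less persistent than their faces — the qualitative behaviour
  the style analysis relies on. It is also consistent with the worked
  example of a thrice-met trio carrying weight on its edges and vertices.
- **Threshold comparison is ≥ τ**, so τ = 1 reproduces the unthresholded
  complex exactly.

Relationships are counted on *any* peak; analyses that want to restrict to
one mountain filter expeditions before building complexes, not inside the
construction.

Vertices (0-simplices) are always present — their "weight" (the number of
history expeditions shared with at least one roster member) is reported
but never thresholded, so influence ζ = 0 is well defined at every τ.

Internally a complex stores only the multiset of roster intersections;
simplices are enumerated lazily from subsets of those intersections, and
τ = 1 queries (influence, maximal simplices, max dimension) short-circuit
through the intersections themselves. Equivalence with exhaustive subset
enumeration is asserted in the tests for rosters up to 8 and histories up
to 10, at τ = 1 and τ = 2.

## Influence, co-influence, and the rank test

ζ<sub>i</sub> is the dimension of the largest simplex containing climber
*i*; co-influence is the roster mean. The success/no-summit comparison
within an experience bin uses a two-sided Mann-Whitney U: U counts pairs
with a success-group value above a no-summit value, ties worth one half.
For pooled sizes ≤ 20 the p-value is exact, by full enumeration of label
assignments over the pooled average ranks; above that, a normal
approximation with tie-corrected variance and a 0.5 continuity correction.
The two routes agree within 0.02 around the cutover on tie-free data;
heavy ties coarsen the U lattice and can roughly double that gap, which is
a property of the normal approximation rather than of either
implementation, and is bounded in the tests.

Experience bins are half-open intervals of the climber's strictly-prior
logged climbs ({5–10, 10–15, 15–20, 20–25} by default). Only climbers in
a simplex of dimension ≥ 1 enter the comparison; deaths are summarized but
never tested (the category is far too small for rank statistics). The
significance level α = 0.1 is reported alongside each p-value and no
multiple-testing correction is applied — the analysis is descriptive, and
the per-bin tests are strongly dependent anyway. Influence histograms are
normalized per outcome category (each category sums to one).

## Repeated-partner failure ratios

A record is *flagged* when at least one co-roster member shares a strictly
earlier joint expedition with the climber. Within each experience bin and
failure category the ratio is the pooled (record-weighted) failure rate
among flagged records over the pooled rate among all records in the bin.
Pooling, rather than averaging per-climber ratios, keeps every cell well
defined; a cell with flagged records but no failures is an honest 0, an
empty cell is missing (never a division error). Experience is counted
prior-to-record, not lifetime: the flag and the bin must condition on the
same information set.

The pooled-denominator design implies a dilution bias away from the
planted multiplier when flagged records dominate a bin: the estimand is
κ / (fκ + 1 − f) with f the flagged share. Recovery cohorts therefore use
small expeditions in a large pool (f ≈ 0.1), where the bias is under
0.03; null cohorts (κ = 1) are unbiased at any f and use denser pools for
statistical power.

## Expedition style

Per expedition and τ: the maximal simplicial dimension, the mean dimension
of *maximal* simplices (faces would mechanically deflate the mean), the
outsider success rate, and the expedition success rate. Under ties the
"largest simplex" is the union of all simplices attaining the maximal
dimension — the conservative outsider definition. Expeditions with no
simplex of dimension ≥ 1 at a τ are excluded at that τ. The per-τ Pearson
correlation relates success rate to mean maximal dimension; it needs ≥ 3
expeditions and nonzero variance, and records a reason when undefined.
The outsider-success-versus-dimension profile uses unit-width dimension
bins with standard errors of the mean; a least-squares slope over
per-expedition points summarizes it for regime tests.

## Features and factors

Six binary personal features: age below the cohort median, male sex,
membership in the cohort's modal nationality block, any experience above
8000 m, oxygen on ascent, oxygen on descent. The median age and modal
nationality are computed from the analyzed cohort (only expeditions with
≥ 12 members are analyzed; in synthetic cohorts the modal block is the
hired/Sherpa identity, which doubles as the nationality axis). Each
expedition contributes two incidence matrices (successful and
unsuccessful climbers); centralities are computed per expedition and then
averaged with standard errors — the comparison is a distribution over
expeditions, not a single pooled graph.

The projection I = PᵀP has its diagonal zeroed before centrality: feature
self-counts are prevalences, and leaving them in lets a common feature
dominate the spectrum regardless of co-expression structure. Eigenvector
centrality is power iteration from the uniform positive vector, tolerance
1e-10, capped at 1e5 iterations, run on I + s·Id with s the maximum row
sum. The shift leaves eigenvectors untouched but makes the dominant
eigenvalue strictly largest in magnitude, so bipartite-like graphs (e.g. a
star, whose extreme eigenvalues are ±√k) converge to the Perron vector
instead of oscillating. A zero matrix returns the uniform vector with a
degenerate flag.

Expedition-wide factors — days to summit, camps above base camp, roster
size including hired personnel, and the paying-members-to-hired ratio
(undefined without hired personnel) — are correlated with expedition
success rate (summit fraction of the roster) via the same Pearson kernel.

## The synthetic cohort generator

The generator emulates exactly the structural features the analyses
consume; it does not attempt to match any real database's marginals, nor
weather, route, or season effects.

- **Persistent subgroups.** Expeditions are built in time order; with
  probability ρ (`group_persistence`, default 0.6) a new roster seeds
  itself with a block (2–5 members) copied from a uniformly chosen earlier
  expedition, the remainder drawn uniformly. Chains of copies create
  simplices of weight ≥ 2, so the τ filtration has content.
- **Outcome model.** Member success probability is
  logistic(β₀ + β_ζ·ζ + regime term + feature effects), with ζ recomputed
  incrementally from the history generated so far using the analysis-side
  definition — planted and measured influence share one scale by
  construction (asserted cross-module in the tests). Defaults β₀ = −0.4,
  β_ζ = 0.8.
- **Regimes.** The *core* of an expedition is the set of members attaining
  the maximal ζ (equivalently, the union of maximal-dimension simplices at
  τ = 1). In cooperative expeditions non-core members gain γ·(max
  dimension) log-odds (default γ = 0.5): the spillover scales with the
  size of the core subgroup, which is what makes outsider success rise
  with maximal dimension. In polarized expeditions non-core members lose a
  flat δ (default 1.0), producing the flat-to-depressed outsider profile.
  `mixed` flips a fair coin per expedition.
- **Partner effect.** After computing success probability, the failure
  probability of a record with at least one repeated partner is multiplied
  by κ ∈ (0, 1]. Failure causes are drawn from a 4-vector of category
  weights; deaths (probability 0.03 given failure) are recorded as
  accident-related, matching a taxonomy whose accident category covers
  death and injury.
- **Climbers.** Six feature prevalences give (young, male, hired/modal
  block, prior-8000 m veteran, oxygen ascent, oxygen descent). Ages are a
  discretized normal (mean 38, sd 9, truncated to [18, 75]), with the
  young flag selecting the below/above-38 half so the age prevalence is
  exact; ages advance one year per 40 time-index steps. Only the
  above/below-median split matters downstream. An optional 6-vector of
  log-odds feature effects supports planted-feature recovery tests.
- **Randomness.** One root seed is split into per-expedition substreams
  (`numpy.random.SeedSequence.spawn`), so cohorts are bit-reproducible and
  climber attributes are independent of expedition count.

`experience_8000m` is emitted as (pre-cohort veteran flag) + strictly
prior in-cohort ascents of ≥ 8000 m peaks; the validation helper recomputes
the increments from history and trusts only each climber's first record as
the unobservable baseline.

What passing tests on these cohorts do *not* show: robustness to the
messiness of real expedition logs — missing demographics, ambiguous
identities across records, seasonal clustering of expeditions (the
generator's total order has no ties), or correlated feature prevalences
beyond the hired/nationality link. Conclusions about real data need the
real tables run through the same pipeline.

## Problem sizes and numerical choices

Study cohorts are 150 climbers over 400 expeditions (rosters 8–12) for
influence analyses, 120 over 300 (rosters 6–10) per regime for style, and
2000 over 10000 small rosters (3–5) for partner-effect recovery, where the
dilution bias analysis above dictates the shape; null calibrations use 40
(influence) and 20 (partners, style) seeded replicates. These sizes put
every Monte-Carlo band in the tests at three-plus standard errors.
Brute-force oracles cap rosters at 8 (subset enumeration) and pooled rank
samples at 20 (permutation enumeration). Determinism contracts: identical
config and seed give byte-identical pipeline outputs (sorted rows, fixed
float format, hashed inputs in the manifest).

## Known limitations

- Complex enumeration is exponential in the size of a single
  roster-intersection; fine for rosters of tens, wrong tool for hundreds.
- The exact Mann-Whitney route enumerates C(n, n1) assignments and is
  capped at pooled size 20 by default.
- Betti numbers, homology and persistence diagrams are out of scope: the
  analyses use weight filtration of simplices only.
- The generator's regime term conditions on the τ = 1 core; regimes
  defined at higher thresholds would need a different planting scheme.
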