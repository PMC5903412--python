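# Methods

This note documents the models, estimators and design choices behind
`covnet`, and what the synthetic test bed does and does not establish about
real data.

## The analysis model

**Structural covariance.** For each group g, the connectivity proxy is the
inter-regional Pearson correlation matrix `R_g` of regional morphometry
(cortical thickness, mm) across the group's subjects. Networks derived
from `R_g` are group-level objects: there is one network per group, not per
subject, which shapes all inference below.

**Preprocessing.** Scanner site is an additive nuisance per region; it is
removed by regressing each region's values on the site factor with all
groups pooled, keeping residuals plus the pooled region mean (equivalently:
subtract site means, add the grand mean). This is idempotent and exactly
removes the additive site offsets the generator produces. Quality
screening removes subjects whose across-region SD deviates from their
group's mean by more than 2 group-SDs (strictly; a subject at exactly 2 SD
is kept). "Variability" could also be read as variance or MAD; SD is the
simplest faithful reading and the rule is applied once, not iterated. A
consequence of the 2-SD rule worth knowing: at most ⌊(n−1)/4⌋ subjects can
ever be excluded from a group of n, so screening can never empty a group.

**Distance decay.** All unordered region pairs (i < j) are stacked as
observations `(r_ij, d_ij, group)`, where `d_ij` is the Euclidean distance
between MNI centroids. The full linear model has a separate intercept and
slope per group; slope homogeneity is tested by comparing against the
common-slope model, giving `F(G−1, G·P − 2G)` with P = N(N−1)/2 pairs.
With 308 regions and 3 groups the denominator df is 141828 — a structural
property of the design, independent of the data. Post hoc pairwise slope
t-tests use the full model's coefficient covariance. Raw correlations are
modelled (a Fisher-z option exists, off by default). Pair observations
are treated as independent, which the F-test's df assumes; correlations
sharing a region are in fact dependent, so these p-values are descriptive
rather than exact — group inference in the pipeline rests on the
permutation machinery instead.

**Network construction.** The maximum spanning tree on correlation weights
(equivalently the minimum spanning tree on 1 − r) is taken first, then the
strongest remaining correlations are added until
`round(density · N(N−1)/2)` edges. The tree guarantees connectedness at
every density. The target count includes the tree's edges by default; a
`density_excludes_mst` switch supports the additive reading (at N = 308
the two differ by at most 307 of 4728 edges). Edges are ranked by signed
correlation — a strong negative correlation is never preferred to a weaker
positive one — with `|r|` ranking available by configuration; ties are
broken lexicographically by (i, j) so construction is deterministic.

**Metrics.** Degree k is the row sum of the binary adjacency; the
cumulative distribution is `P(k) = Σ_{k'≥k} p(k')`; hub sets take the
⌈f·N⌉ highest-degree nodes (ties toward the lower region id); wiring cost
is the mean centroid distance over connected pairs (mm); morphometry-by-
degree curves average group-mean regional values over nodes with degree ≥
threshold (absolute degrees, or degree percentiles from 0 to 100%); the
rich-club coefficient `φ(k)` is the edge density of the subgraph of nodes
with degree > k, reported raw and normalised by the mean over 100
degree-preserving rewired surrogates (5E double-edge swaps each, seeded).

**Permutation inference.** For two groups, subjects are shuffled between
the groups (sizes preserved), both covariance matrices and networks are
rebuilt, and the statistic difference is recomputed per permutation.
P-values use the add-one convention `p = (1 + #{|null| ≥ |obs|})/(1 + B)`,
so the smallest attainable p is 1/(1+B). Draws on which a statistic is
undefined (e.g. a zero-variance region) are redrawn with a bounded budget.
FDR control defaults to Benjamini–Yekutieli at α = 0.025 — BY because
network-metric p-values are mutually dependent, α = 0.025 to pair with
two-tailed testing; BH is available. For vector statistics (e.g. the
cumulative degree distribution over a degree range) a max-statistic
family-wise correction is provided.

**Modular agreement.** Louvain is run `n_restarts` times (default 100)
with distinct sub-seeds; the partition with the best modularity Q wins —
"iterating" read as best-of-restarts rather than consensus (consensus is a
possible alternative, not implemented). Agreement between two partitions
is the Jaccard overlap of their co-assigned pair sets; the denominator
choice is not canonical, so a conditional-proportion variant is available,
and z-scoring against the matched null largely neutralises the choice.
Significance compares the observed agreement with agreement between
surrogate partitions matched to each group's template and uses the null's
95th quantile (one-sided), plus a z-score and add-one p. Agreement
*differences* between group pairs are referred to the differences of the
matched surrogate agreements, two-sided on |difference|, FDR-corrected.

**The constrained null.** Surrogate partitions preserve four properties of
the template: module count, module sizes, spatial contiguity and
hemispheric symmetry. Symmetry forces even module sizes; odd-sized
templates (possible from raw Louvain output) are accommodated by moving
one region between a pair of odd-sized modules (the number of odd modules
is always even). Generation grows modules by seeded random region growth
on one hemisphere's neighbour graph at half size — all but the largest
module are grown, the largest takes the remainder — rejecting and retrying
until every module is connected, then mirrors the labels to the other
hemisphere. Because the neighbour graph has no inter-hemisphere edges, a
mirrored module is two components on that graph; contiguity is therefore
defined on the neighbour graph augmented with mirror-pair edges
(equivalently, each module's restriction to each hemisphere is connected).
An independent checker (networkx connectivity, separate from the growth
code) validates all four properties on every draw.

## The synthetic cohort generator

The generator emulates the derived form of multi-site developmental
cohorts: three groups (default 87/62/69 subjects, matching a NT/autism/
ADHD design), 308 cortical parcels, thickness near 2.75 ± 0.25 mm,
additive per-site offsets, and inter-regional correlation decaying with
centroid distance at a group-specific rate.

**Geometry.** Centroids are sampled on two mirrored hemispheric shells
(radius 48 ± 2.5 mm) separated along x; the neighbour graph is a
symmetrised k-nearest-neighbour graph (k = 6) built on one hemisphere,
patched to connectivity, and mirrored. The shell radius is deliberately
more compact than a real cortex: the slope of a linear fit of
`exp(−d/L)` on d is non-monotone in L, peaking when L is near half the
maximum pairwise distance, and a 48 mm shell places the working decay
range (L ≥ 50 mm) on the monotone side — so a faster decay always fits a
steeper slope, the qualitative relation the analysis interprets. With a
cortical-scale radius this relation inverts between L = 50 and 100 mm.

**Covariance model.** Subject vectors are multivariate normal with
correlation `C = S ∘ exp(−D/L_g)` (Schur product), marginal SD
`subject_noise_sd` (default 0.25 mm) and mean `mean_ct` (default 2.75 mm)
plus site offset; optional iid measurement noise on top. S is an optional
intrinsic-coupling matrix (uniform 1s by default; a blend with a wide-
spread random correlation under `coupling_heterogeneity`). A planted
partition adds `module_boost` to within-module correlations, clipped and
repaired to positive definiteness by diagonal loading when necessary
(logged). Planted partitions are generated mirror-symmetric and spatially
contiguous by the same growth machinery as the null model.

**Why planted modules matter for wiring cost.** Under the pure decay model
the population correlation is a monotone function of distance for *every*
decay length, so the top-density edge set — hence the wiring cost — is
identical across groups in population; only sampling noise differs. Any
group difference in wiring cost requires strong covariance off the
distance ranking. The generator's planted symmetric modules provide
exactly that: a module spans both hemispheres, so its within-module
cross-hemisphere pairs are strong long-range correlations whose survival
above the density threshold depends on the decay length. The parameter-
recovery conditions therefore plant one shared 4-module structure in both
groups (boost 0.3); the decay contrast (100 vs 50 mm) then yields both a
steeper slope and a lower wiring cost in the faster-decay group, which is
the configuration the analysis is designed to detect. Without shared
long-range structure the wiring-cost comparison has essentially no signal
at realistic sample sizes.

**Planted-module recovery conditions.** For modular-agreement recovery the
background decay is set short (25 mm) with boost 0.45: a long decay length
makes baseline correlations high and spatially smooth everywhere, so
Louvain finds geometry-driven modules shared by all groups and the planted
structure is masked; a short decay keeps the background local — and local
correlation is consistent with contiguous planted modules — letting the
planted partition dominate the community structure.

## Problem sizes and reproducibility

Tests run the full stack at reduced sizes chosen as the package's standard
test conditions: 60-region parcellations for recovery and null-model
checks, 40 regions × 12 subjects/group × B = 99 × 200 replicates for
permutation calibration, exhaustive oracles at ≤ 12 nodes (spanning-tree
enumeration at N = 6, i.e. 3003 candidate trees per instance). The
acceptance script runs the study-scale configuration (308 regions,
87/62/69 subjects, B = 1000). All randomness flows from integer seeds;
the pipeline fans a master seed out to named per-stage streams (CRC-mixed
`SeedSequence`), so any stage can be re-run in isolation with identical
results and full runs are byte-reproducible.

## What the synthetic results do and do not show

Passing tests establish that the estimators are correct (oracle
equivalence), the null models are valid (constraint checking, type-I
calibration within the binomial interval of the nominal 5%), and the
pipeline recovers planted effects of realistic size. They do not
establish that real cortical thickness covariance follows an exponential
distance decay (the functional form is a modelling choice; real decay is
merely monotone), that real site effects are additive constants, that real
module structure is exactly mirror-symmetric, or anything about FreeSurfer
-level measurement error, which is not simulated. Values printed by the
acceptance script on synthetic cohorts are the same *kind* of quantity a
real study reports (F statistics, slopes, wiring costs, agreement
z-scores), with magnitudes set by the generator's parameters, not by brain
data; only structurally determined quantities (degrees of freedom, hub
counts, edge counts) are expected to match a real 308-parcel, 3-group
study exactly.

## Known limitations

- The ANCOVA's independence assumption over region pairs (shared-region
  dependence) is inherited from the standard design; its F and post hoc
  p-values should be read descriptively.
- Louvain best-of-restarts is a heuristic; different restart counts can
  change partitions on near-degenerate modularity landscapes (Q ties are
  broken by first-found).
- The constrained null generator uses rejection sampling; templates with
  many small modules on sparse neighbour graphs can need many retries, and
  pathological sizes (a size-1 module, unsatisfiable under symmetry) raise
  an error naming the offending size.
- Degree-preserving rewiring for rich-club normalisation uses double-edge
  swaps, which sample the degree-preserving graph space approximately, not
  uniformly.
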