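# Methods

## Problem and representation

`crossfeednet` classifies the interaction between a pair of microorganisms as
*cross-feeding* (one grows on metabolites the other secretes, in either or
both directions) or *competition* (both contend for the same resources),
using nothing but the organisms' genome-scale metabolic networks.

Each network is reduced to the set of its reaction identifiers.  A *reaction
pool* — the ordered universe of reaction IDs observed in at least one
organism of the collection, with reference order preserved — defines the
coordinates of a fixed-length binary profile: bit *i* is 1 iff pool reaction
*i* is present in the organism.  Reactions in an organism but absent from the
pool (exchange and sink reactions emitted by reconstruction tools, typically)
are ignored with a logged count.  The pool order is part of the data; it is
serialized with every encoded artifact together with a SHA-256 content hash,
and artifacts from different pools are refused.

A pair of organisms is the concatenation of the two profiles (length 2*P*).
Concatenation is order-sensitive, so every labelled pair enters the dataset
twice, in both orders (AB/BA augmentation).  This removes positional bias and
doubles the sample size, but it also creates near-duplicate examples: the two
orientations of a pair must never straddle a train/test split.  Both
orientations share a canonical `pair_key` (the sorted ID tuple) that all
downstream splitting is keyed on.

## Fold construction

Cross-validation folds are built at the level of unordered pairs:

1. k-means (squared Euclidean on the raw 0/1 vectors, k-means++, 10
   restarts, fixed seed) clusters the canonical orientation of each pair into
   `n_clusters` groups (default 10);
2. clusters are merged whole into `n_folds` folds (default 4) by a greedy
   balancer: largest cluster first, into the currently smallest fold, ties
   broken by index.  The procedure is deterministic given the clustering.

Clustering similar pairs into the same fold makes train and test sets as
dissimilar as possible, so the reported performance is conservative.
Orientation co-location holds by construction, and `audit_leakage`
additionally verifies it on the oriented vectors (useful for fold files of
external provenance).  `cross_validate` refuses assignments whose audit is
not clean.

## Classifiers

The in-repo baseline is a from-scratch k-nearest-neighbours classifier over
binary pair vectors.  Distances are Euclidean or cosine; votes are uniform or
inverse-distance weighted (`w = 1/(d + 1e-12)`; the epsilon guards exact
duplicates).  Ties at the k-th distance are broken by stable training-index
order, so predictions are deterministic.  The score is the (weighted)
fraction of neighbours labelled cross-feeding; the decision threshold is 0.5
and a score exactly at the threshold predicts cross-feeding, the majority
class at the prevalences this tool targets (≈3.86:1).  The reported default
is k = 3 with Euclidean distance and uniform votes; all four
metric/weighting combinations remain runnable, and `select_k` scans k = 1..30
on a single pair-level hold-out split (67% train by default, optionally on a
subsample of the data) and returns the accuracy-maximising k with ties broken
toward smaller k.

Random forest, SVMs (linear, RBF, polynomial, sigmoid kernels) and gradient
boosting are thin adapters over scikit-learn and xgboost behind one
`ClassifierSpec` contract — these solvers are commodity components and are
not re-derived here.  SVM scores are a logistic squash of the decision
function: monotone, in [0, 1], and deterministic, so ROC/PR ranking is
unaffected; thresholding the squashed score at 0.5 coincides with the SVM's
own sign rule.  An unavailable family raises a capability error rather than
silently substituting.

Inference on a new pair scores both orientations and averages, so
`predict_pair(a, b) == predict_pair(b, a)` exactly.

## Evaluation

Confusion counts are pooled over folds before metrics are computed (per-fold
macro-averaging is available via `macro_average_panels`).  With competition
(co) and cross-feeding (cf) as target classes: `P_co = TP_co/(TP_co+FN_cf)`,
`R_co = TP_co/(TP_co+FN_co)`, F1 their harmonic mean, symmetric formulas for
cf, accuracy over all examples, balanced accuracy the mean of the two
recalls.  Zero denominators yield 0 with an explicit flag, never NaN.
Display strings round to two decimals, half-up, trailing zeros trimmed
("0.9", "0.6"); full-precision values are always carried alongside.

ROC curves use a full threshold sweep and the trapezoidal area, which equals
the Mann–Whitney statistic (oracle-tested by exhaustive pairwise
enumeration).  The competition-target curve scores with the complement
`1 - score_cf`, which makes the two targets' ROC areas identical (complement
symmetry).  PR areas use the step-wise average-precision convention
`sum((R_i - R_{i-1}) * P_i)`; trapezoidal PR interpolation is known to be
optimistic and is available only behind an explicit flag.  The random
baseline for precision is the class prevalence (0.21/0.79 at 546:2106).

## Consensus with external score matrices

External methods report a real number per ordered organism pair whose sign
encodes the interaction (positive = cross-feeding, zero = none, negative =
competition).  `pcps_to_labels` applies the sign trichotomy (invariant under
positive scaling; diagonal forced to none; asymmetric matrices are logged
and unordered-pair labels read the upper-triangle cell).  The consensus
matrix is +1 where both methods say cross-feeding, −1 where both say
competition, 0 otherwise.  `score_against_reference` restricts to unordered
pairs the reference labels (discarding its "no interaction" pairs by
default), treats the reference as truth, and reuses the metric engine; a
predicted "none" on a scored pair counts against the reference class.  "No
interaction" is representable but is never a training class — the classifier
stays two-class.

## Synthetic communities

The generator produces fully in-silico study conditions at the scale of the
real training collection: a pool of 3,141 reactions, 260 organisms with a
mean of 793 reactions each, and 1,053 cross-feeding / 273 competition pairs
(each then augmented to 2,652 oriented vectors of length 6,282).

The head of the pool is partitioned into disjoint blocks standing in for
pathways.  Each of 4 *guilds* owns a producer module (synthesis/secretion of
its by-product) and a consumer module (catabolism of that by-product,
carried by the next guild in a feeding cycle); each of 2 *substrate
families* owns a resource module (uptake/catabolism); each of 10 *habitats*
owns a larger core-function module (the capabilities a niche demands).
Every organism draws a guild, a substrate family and a habitat uniformly and
independently, switches on the corresponding whole blocks (producer,
consumer of the previous guild, resource, habitat), and fills up with a
Poisson-sized uniform background draw from the non-module region so the
expected total hits the configured mean.  Defaults: module size 80, habitat
size 180, leaving a 541-reaction background region at ~0.69 occupancy.

Interactions are planted between co-occurring organisms (same habitat):

* **cross-feeding** (probability α, default 1): a pair (A in guild g, B in
  guild g+1) — A carries a producer module whose paired consumer module B
  carries; with probability 1−α the pair is uniformly random, a label the
  reaction profiles cannot explain;
* **competition** (probability β, default 1): two organisms preferring the
  same substrate (both carry the same resource module) in guilds at feeding-
  cycle distance ≥ 2 — niche overlap without a feeding relation; with
  probability 1−β uniformly random;
* recorded labels flip with probability η (default 0); the planted truth is
  returned separately.

The within-habitat constraint is relaxed to the whole community only when no
habitat offers an eligible fresh pair; at the default geometry this never
triggers, so every planted pair is intra-habitat.

This architecture was chosen deliberately.  The dominant similarity
structure among pair vectors is then the habitat signature, which carries no
label information, so fold construction clusters communities and holds them
out whole — the realistic analogue of "similar pairs go to the same fold" —
while every guild/resource pattern remains represented in the training folds
and the habitat mismatch penalty is a constant offset for all training
candidates, leaving neighbour ranking to the label-bearing modules.  Designs
in which the label-bearing patterns themselves dominate the clustering fail
under this fold procedure: k-means isolates each tight pattern into one
cluster, the balancer puts it into one fold, and all training data relevant
to those test pairs disappears.  That failure mode is intrinsic to
cluster-then-hold-out evaluation, not to any classifier.

All randomness flows from a single seed through `numpy.random.SeedSequence`
spawning, so community generation, pair planting and label noise are
independently reproducible; fixture writes are byte-identical across runs.

What the generator does *not* emulate: phylogenetic correlation between
profiles, reaction co-occurrence structure within real pathways, degree
heterogeneity of real interaction networks, flux or thermodynamic
feasibility, and annotation error in reconstructions.  Passing the planted-
recovery gates therefore shows the pipeline is correct and leakage-free and
that it can read complementarity/overlap signal out of reaction presence —
it does not certify accuracy on real genomes.

Presets: `tiny` (P=50, 12 organisms, 20 pairs) for unit tests; `paper_scale`
(defaults above); `null` (P=800, 120 organisms, 500 pairs, η=0.5), whose
labels carry no signal, for no-skill checks.

## Numerical and degenerate-input choices

* Reaction IDs are opaque strings compared exactly; no namespace
  normalization.
* Duplicate interaction records: exact duplicates are deduplicated with a
  warning; the same unordered pair under two labels is a hard error.
* Organisms with zero pooled reactions are rejected (all-zero profiles would
  make cosine distance undefined and carry no information).
* k-means clusters are merged by size only; class balance across folds is
  not optimized (observed per-fold class counts are visibly uneven in
  practice, which pooled metrics absorb).
* Pair-drawing in the generator is rejection sampling with an exhaustive
  per-tier scan, so a feasible configuration always terminates and an
  infeasible one raises a validation error.

## Problem sizes used by the test suite and acceptance script

Unit tests run on the `tiny` preset and small random instances; the
acceptance checks run the full `paper_scale` preset (2,652 vectors of length
6,282) for the planted-recovery and noise-degradation gates, 500-vector
instances for the KNN oracle, and 1,000-shuffle permutation nulls.  A full
suite completes in a few minutes on one CPU.

## Known limitations

* The tool consumes already-reconstructed networks; reconstruction itself
  (annotation, orthology mapping, gap-filling) is out of scope, as are flux
  simulations on the models.
* Two-class only: "no interaction" can be represented in consensus matrices
  but cannot be predicted.
* Predictions name no mechanism — neither the exchanged metabolites nor the
  contested resources.
* Hyperparameter search beyond k for KNN is out of scope; the other
  classifier families run at library defaults unless configured.
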