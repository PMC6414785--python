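# Methods

## The problem and the model

`coexmerge` integrates two probe-level microarray studies of CD8+ T-cell
differentiation — an "inflation" time course and an "exhaustion" time
course, measured on different platforms — into one gene × sample matrix,
and then asks a network question of the result: does the module of genes
co-expressed with a master regulator (Tbx21) behave as a single
coordinated program (one dominant hub) or as a dysregulated one (no
unique hub)? All stages are deterministic given a configuration and a
seed.

## Cross-platform merging

Probe-level log2 matrices are collapsed to one row per gene symbol by the
*max signal probe* rule: the probe with the highest mean intensity across
all samples represents its gene (ties broken by lexicographically
smallest probe id). "Highest mean" rather than per-sample maximum keeps
each gene's profile from a single physical probe. Platforms are then
intersected on exact symbol strings (no alias resolution) and
concatenated column-wise. Post-merge renormalization is optional:
`scale` (per-sample z-scoring) or classic `quantile` normalization
(each column's sorted values replaced by the cross-column mean of sorted
values; ties receive the mean of the reference slots they span — this
makes the operation idempotent). Outlier removal is an explicit,
user-supplied sample list, never automatic.

The variance filter keeps genes whose across-sample interquartile range
*strictly exceeds* a threshold (default 0.5 log2 units). Quantiles use
linear interpolation (the quartiles of `[1,2,3,4]` are 1.75 and 3.25);
the convention is stated because IQR-filter counts depend on it.

## Batch correction (parametric empirical Bayes)

The location/scale model: for gene *g* in batch *b*,
`Y = α_g + X β_g + γ_gb + δ_gb ε`. The algorithm (1) fits the pooled
model by least squares with sample-size-weighted batch means defining the
grand mean, (2) standardizes gene-wise by the pooled residual variance,
(3) estimates per-batch gene-wise locations γ̂ and scales δ̂² and shrinks
them by empirical Bayes — a normal prior on γ and an inverse-gamma prior
on δ², both hyperparameterized by method of moments across genes, solved
by the usual fixed-point iteration (tolerance 1e-4, max 100 iterations) —
and (4) removes the shrunk effects and back-transforms. No reference
batch: both platforms shrink toward the pooled standard. Covariates can
be protected during standardization, but the default run passes none
(the state design is balanced across platforms, so batch-mean removal
does not erase it). On a frozen two-batch fixture the output matches the
Bioconductor sva ComBat implementation to ~5e-12 (the reference matrix is
stored under `tests/data/`).

Two behavioural notes, verified against the reference implementation:
duplicated data relabeled as two batches is *not* returned bit-identical
(locations shrink to zero but the scale step rescales each batch's
variance toward its shrunk posterior), and gene-wise grand means move by
O(1e-2) because the shrinkage residual does not cancel exactly across
batches. Tests assert the real invariants: row means essentially
untouched (drift ≪ the removed batch shift), identical batches adjusted
identically, and batch-label permutation invariance.

## PVCA

The audit standardizes gene rows, performs a sample-space PCA, and
retains the smallest set of components reaching a cumulative-variance
threshold (default 0.6). Per component, variance components are estimated
for each design factor and each pairwise interaction by non-negative
method-of-moments one-way ANOVA estimators (an interaction's own
contribution is its combined-factor component minus its mains, truncated
at zero); the residual is the within-cell variance of the finest factor
cross. Proportions are normalized per component and averaged with
eigenvalue weights. This moment estimator replaces the mixed-model fit
used by some PVCA implementations; the contract is at the level of
proportions. Because most genes in a genome-scale matrix are noise, the
residual share is structurally large — factor comparisons ("which design
factor dominates?") therefore rank the design factors, with the residual
reported alongside.

## Co-expression network

Unsigned weighted network: `a_ij = |cor|^β` (Pearson; β default 9, with
20 as the scale-free-criterion alternative). Topological overlap uses the
standard unsigned form. Modules come from average-linkage clustering of
`1 − TOM` with a *static* cut at a fraction of the maximum merge height,
followed by pruning of branches below the minimum module size (default
30) and size-ranked colour naming (turquoise, blue, brown, ...). The
static cut is fully reproducible, unlike hybrid dynamic cutting, and its
default is 0.998 of the root height: under high soft powers the adjacency
is so compressed that every informative split sits in the top percent of
the dendrogram, and lower cuts strip the peripheral members of weakly
correlated but genuine modules (verified on planted 40-gene modules at
within-correlation 0.7). At milder powers (β ≈ 6) a slightly lower cut
(≈ 0.995) is appropriate; the parameter is exposed everywhere. Pure-noise
matrices leave ≥ 80% of genes unassigned at the default settings.

Module eigengenes are the first principal component of the
gene-standardized module submatrix (unit norm, oriented so the mean gene
correlation is non-negative); modules whose eigengene dissimilarity
`1 − cor` falls below the merge distance (default 0.25) are merged
iteratively, closest pair first. Hubs are per-module argmax of kWithin
(ties lexicographic). Edge export applies a strict weight threshold to
within-module TOM entries.

Soft-power selection bins connectivity into 10 equal-occupancy bins and
regresses log10 of the empirical *density* of k on log10 of the bin mean.
With equal-occupancy bins the raw bin proportion is constant by
construction, so a density (count divided by bin width) is the only
meaningful p(k); R² is sign-flipped when the slope is positive and the
smallest power reaching the target R² (default 0.85) is recommended. A
caution documented rather than hidden: finite-sample networks built from
i.i.d. noise can show spuriously good scale-free fits at high powers, so
the fit index should not be read as evidence of structure on its own.

## Template matching

The template is a gene's own observed profile. Each candidate's Pearson
correlation with the template is computed across all samples (ordered by
group, then timepoint, when metadata is present); matches are `R >`
threshold — signed and strict, so an anti-correlated gene never matches —
with the template itself excluded. Matching is invariant to affine
transformations with positive slope. Default threshold 0.8.

## Peak enrichment

Peaks are scored BED intervals; a gene is peak-bearing when a retained
peak's midpoint lies strictly within the distance cutoff (default
1000 bp, with 2000 bp as the published variant) of its annotated TSS on
the same chromosome — strand enters only through the TSS coordinate, and
the midpoint (not a summit) is the anchor because plain BED carries no
summit. Enrichment contrasts one module against a disjoint comparison
module in a 2×2 two-sided Fisher exact test; the odds ratio is the
unconditional sample `ad/bc` with a 0.5 continuity correction only when a
zero cell occurs (flagged in the output).

## The synthetic generator: what it emulates, and what it does not

The generator plants known structure on the standardized latent scale:
module *m* has a per-sample factor `f_m = μ_m + z`, `z ~ N(0,1)`, and a
member with target correlation ρ is `c·f_m + σ·ε` with
`c = σ·sqrt(ρ/(1−ρ))` (σ = `noise_sd`, default 0.3), giving closed-form
planted correlations. The hub gene equals its factor plus small noise
(sd 0.05), with member loadings calibrated so the hub–member correlation
equals `hub_strength` exactly. Template followers track the hub's factor
at `follower_cor` and are counted as part of the hub module's correlation
cluster in the ground truth. In the "dual" (exhaustion-like) variant the
module splits into two sub-factors correlated 0.8 through a shared
component, members alternate between them at within-half correlation
0.75, and the regulator loads only on the shared component — correlated
with everything, hub of nothing, and decoupled from the coordinated state
trajectory.

State enters as module-specific trajectory means: the hub module follows
a monotone differentiation profile (naive 0, resolving 0.35, extreme 1.0,
scaled by `state_effect`), the next module an acute-phase profile (high
only at the earliest post-infection timepoint, scale 0.7), and every
third module is design-independent. Distinct trajectories keep modules
separable in an unsigned network, where a shared trajectory would fold
all modules onto one |cor| axis. `state_effect` defaults to 10 log2
latent units, i.e. ~6 log2 shifts in strongly loaded genes between naive
and extreme — the magnitude seen between sorted naive and effector CD8
populations for strongly responsive genes, and large enough that state
clades in hierarchical clustering are clean rather than marginal.

Platform batch effects take exactly the form the EB correction assumes:
platform B adds a gene-wise offset (sd = `batch_shift`, default 1.0) and
inflates the *residual noise* (not the biology) by `batch_scale`
(default 2.0). Probes replicate each gene with a fixed descending offset
ladder (0.6 log2 per step) plus small probe noise, so the max-signal
probe is unambiguous; the truth records it. Shared genes (85% by default)
appear on both platforms and always include all planted structure.

What the generator does **not** emulate: probe-level cross-hybridization,
intensity-dependent (nonlinear) platform distortions, annotation-version
symbol drift, correlated background genes, or pathway-level realism.
Passing tests therefore demonstrate correctness of the algorithms under
the location/scale batch model and latent-factor correlation structure —
not robustness to violations of those assumptions in real GEO data.

## Numerical and design choices

- Unsigned network (the |cor| convention); a signed variant is out of
  scope.
- Pearson correlation throughout; robust variants out of scope.
- Deterministic everywhere: lexicographic tie-breaks (probe winners,
  hubs, edge ordering), fixed PCA sign convention (largest-magnitude
  loading positive), single seed feeding one generator, TSVs written with
  9 significant digits so reruns are byte-identical.
- EB fixed point: tolerance 1e-4, max 100 iterations (converges in a
  handful on all tested inputs).
- Degenerate inputs fail loudly: zero-variance genes must be filtered
  before network construction, zero-variance samples block `scale`
  renormalization by name, single-level PVCA factors are dropped with a
  warning, confounded ComBat covariates raise with the factor named.
- Default problem sizes (1000 genes, 60 samples, modules 100/60/40 with
  50 followers; 10–20 replicates in tests) keep a full test run in tens
  of seconds while leaving planted effects far from the detection
  boundary.
- The published stage parameters are the defaults: IQR 0.5, merge
  distance 0.25, β ∈ {9, 20}, template R 0.8, edge weights 0.41/0.54,
  peak distances 1/2 kbp, peak score 50.

## Known limitations

- The static tree cut, while reproducible, is less adaptive than dynamic
  cutting; very heterogeneous module tightness may need a per-dataset
  cut height.
- PVCA's moment estimator can differ from REML-based mixed-model
  estimates on strongly unbalanced designs.
- The scale-free fit index is reported but is a weak model-selection
  signal at small sample counts (see above).
- Symbols are matched as exact strings; cross-annotation alias handling
  is the caller's responsibility.
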