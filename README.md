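# coexmerge

Cross-platform transcriptome integration and co-expression network
comparison for two-condition immune time-course studies.

The motivating biology: persistent virus infections drive CD8+ T-cell
memory toward two very different fates — memory **inflation** (sustained,
functional populations, as under MCMV or adenoviral vectors) and
**exhaustion** (checkpoint-marked, dysfunctional populations, as under
chronic LCMV). Comparing the transcriptional programs behind these fates
means merging microarray studies produced on different platforms
(Illumina, Affymetrix) by different laboratories, then asking whether a
master-regulator-driven gene module (centred on the transcription factor
Tbx21, *T-bet*) keeps or loses its coordinated, hub-like structure across
the two regimes.

`coexmerge` implements that workflow as a tested, reusable library plus
CLI:

1. **Probe → gene collapse** — each gene symbol is represented by its
   highest-mean-intensity probe ("max signal probe"), per platform.
2. **Gene-universe intersection** — collapsed platforms are merged on
   their shared symbols; optional post-merge quantile/scale
   renormalization and an explicit outlier-exclusion list.
3. **Batch correction** — parametric empirical-Bayes location/scale
   adjustment (the ComBat model): gene-wise standardization against a
   pooled fit, per-batch location γ̂\_gb and scale δ̂²\_gb estimates shrunk
   toward method-of-moments normal / inverse-gamma priors, then removed.
4. **PVCA audit** — principal variance component analysis: sample-space
   PCA, non-negative method-of-moments variance components per retained
   component for each design factor and pairwise interaction, averaged
   with eigenvalue weights.
5. **Exploration** — covariance PCA of samples and Euclidean-distance
   hierarchical clustering with newick export.
6. **Co-expression network** (the WGCNA formalism) — unsigned adjacency
   `a_ij = |cor(x_i, x_j)|^β`, topological overlap
   `ω_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, average-linkage
   clustering of `1 − ω` with a static tree cut, size-ranked colour-named
   modules (turquoise = largest, blue = second), eigengene merging at a
   dissimilarity threshold, intramodular connectivity `kWithin` with
   per-module hubs, thresholded edge export and scale-free-fit soft-power
   selection.
7. **Template matching** (Pavlidis) — genes whose trajectory correlates
   with a template gene's profile above a signed Pearson threshold.
8. **Peak enrichment** — ChIP-seq peaks assigned to genes by
   peak-midpoint-to-TSS distance; module-vs-module two-sided Fisher exact
   test of peak-bearing gene counts.

A first-class **synthetic-data generator** emulates the study layout with
known ground truth: two platforms with partially overlapping gene
universes and many-to-one probe maps, a naive/resolving/extreme state
design over timepoints, planted latent-factor modules including a
hub-driven module (and an "exhaustion-like" two-factor variant with no
single hub), additive + multiplicative platform batch effects, template
followers and a peak table enriched near one module's TSSs.

## Worked example

```python
from coexmerge import RunConfig, run_pipeline
from coexmerge.workflow import compare_networks, regulator_connectivity_rank
from coexmerge import dual_factor_design

inflation = run_pipeline(RunConfig(seed=0))
exhaustion = run_pipeline(RunConfig(design=dual_factor_design(), seed=0))

print(inflation.pvca_before.round(3).to_dict())
# {'platform': 0.529, 'state': 0.301, 'platform:state': 0.002, 'residual': 0.169}
print(inflation.pvca_after.round(3).to_dict())
# {'platform': 0.0, 'state': 0.329, 'platform:state': 0.003, 'residual': 0.668}

print(inflation.assignment.sizes().to_dict())   # {1: 155, 2: 63, 3: 40}
print(compare_networks(inflation, exhaustion, "Tbx21")["a"])
# {'module': 1, 'module_size': 155, 'hub': 'Tbx21', 'regulator_rank': 1,
#  'regulator_degree': 149, 'template_matches': 149}
print(compare_networks(inflation, exhaustion, "Tbx21")["b"])
# {'module': 1, 'module_size': 99, 'hub': 'G00043', 'regulator_rank': 93,
#  'regulator_degree': 0, 'template_matches': 0}
```

Reading the output: before correction the platform factor dominates the
variance decomposition; after empirical-Bayes correction it vanishes and
the biological state factor leads. Module detection recovers the three
planted modules (the 155-gene turquoise module is the hub module plus its
template followers). In the single-hub ("inflation-like") run the
regulator Tbx21 is its module's hub — connectivity rank 1, exported-edge
degree 149, 149 template-matched genes at R > 0.8. In the two-factor
("exhaustion-like") run the same gene, though present in the homologous
module, loses the hub property: rank 93, degree 0, no template matches —
the package's quantitative restatement of coordinated vs dysregulated
co-expression.

The same pipeline runs from the shell:

```bash
coexmerge all --seed 0 --out runs/demo
```

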