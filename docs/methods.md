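# Methods

This note documents the models, conventions and design choices behind
`digestnet`, in the spirit of a statistical-methods appendix.

## Scope and data model

The pipeline starts at a validated OTU count table (samples × OTUs,
non-negative integers, unique identifiers, order preserved from input);
upstream read processing, OTU clustering and taxonomy assignment are out
of scope. Relative-abundance matrices are derived, read-only products and
are never written back into a count table. Taxonomy lineages use the five
ranks phylum…genus with explicit `unclassified` placeholders; on
aggregation, unclassified OTUs pool under `unclassified_<parent>` where
parent is the most resolved classified rank. Genus-level analyses use the
rarefied table by default (callers may pass the unrarefied table; nothing
else changes).

## Rarefaction

Subsampling is without replacement — each sample's rarefied counts follow
a multivariate hypergeometric distribution conditioned on its observed
counts (numpy's generator), so the expected rarefied count is
`depth × proportion` and identity is preserved when a sample sits exactly
at depth. Samples below depth are dropped with a logged warning, never
padded. All calls are bit-reproducible given a seed.

## Diversity

Chao1 uses the classic `S_obs + F1²/(2 F2)` with the bias-corrected
`S_obs + F1(F1−1)/2` fallback when no doubletons exist (these two agree
with the common toolchain variants; the conditional form keeps the
estimator finite for every input). Shannon entropy defaults to natural
log with the base recorded in the output (base 2 available, since older
toolchains reported bits). "Simpson diversity" is reported as Gini–Simpson
`1 − Σp²`, with the raw dominance `Σp²` exposed alongside.

Weighted UniFrac is computed by scikit-bio (one post-order traversal);
the normalized variant — division by the abundance-weighted maximum
distance — is the default, and both variants are available because the
normalization convention of legacy tools is ambiguous. Inputs are
validated so a missing OTU is reported by name rather than surfacing as a
library error. The implementation is tested against an independent
branch-walk oracle and closed-form two-leaf cases.

## Ordination and inference

* **PCoA**: eigendecomposition of the Gower-centered `−½ J D² J`.
  Coordinates are eigenvectors scaled by √eigenvalue. Negative eigenvalues
  (non-Euclidean distances) are reported, never clipped silently;
  proportions explained are taken over positive eigenvalues only.
* **PerMANOVA**: Anderson's pseudo-F computed directly from the distance
  matrix. (A desktop-tool convention computes it on PCoA scores instead;
  the two agree exactly on Euclidean inputs and the score-based variant is
  available behind `use_pcoa_scores=True`.) Permutation p-values use the
  (count+1)/(n+1) estimator so p is never 0, with a seeded generator and
  an exhaustive mode that enumerates all n! relabelings for small n.
* **Partial Mantel**: upper triangles of the community and focal matrices
  are residualized on the control triangles (matrix-regression
  convention); r is the Pearson correlation of residuals, with a
  rank-transform (Spearman) option used for the module–environment
  tables. The permutation unit is whole samples — the focal matrix's rows
  and columns are permuted jointly, preserving its internal structure —
  and the projection onto the control space is built once since it is
  permutation-invariant. Singular control sets (duplicate or constant
  controls) are rejected. Default 9999 permutations.
* **Variance partitioning**: RDA R² (share of total response variance
  captured by the linear fit) for every union of predictor sets, adjusted
  by Ezekiel's formula, then decomposed into Venn-region fractions by
  inclusion–exclusion. The fractions sum to the total adjusted R² as an
  algebraic identity (tested to 1e-10); negative adjusted fractions are
  legitimate small-sample artifacts and are flagged, not clipped. Raw-R²
  values are also reported for comparison with unadjusted conventions.
* **Jackknifed UPGMA**: the reported dendrogram is average-linkage on the
  full-table weighted UniFrac matrix; each replicate re-rarefies to
  ⌊fraction × depth⌋ (default 0.75, 100 replicates — both recorded in the
  result since legacy defaults are undocumented) and a node's support is
  the fraction of replicate trees containing the same sample cluster.
* Per-taxon environment correlations (Pearson/Spearman, two-sided
  t-approximation) are reported without multiplicity correction by
  default, mirroring common practice of reporting raw significance; a
  Benjamini–Hochberg switch appends q-values.

## Core-population classification

All prevalence rules are strict inequalities on exact fractions, never on
rounded sample counts. Worked arithmetic: with 43 samples, core (> 0.9)
requires presence in ≥ 39 samples (39/43 = 0.907); with 16, ≥ 15; with
27, ≥ 25. Cosmopolitan (> 0.5) requires ≥ 22 of 43. Presence means
count ≥ 1 in the supplied table (min-count override available); the
rarefied table is the intended input. Sub-core sets exclude global core
members by construction; "specific" OTUs are cluster-exclusive. Pooled
summaries satisfy `mean_pooled = (n_I m_I + n_II m_II)/(n_I + n_II)`
exactly, which is the identity behind Table-1-style all-sample columns.

## C-score and the fixed-fixed null

The checkerboard statistic is the Stone–Roberts pairwise mean
`(rᵢ − Sᵢⱼ)(rⱼ − Sᵢⱼ)`. The null model preserves all row and column sums
via 2×2 checkerboard swaps. One Markov step is one *attempted* swap
(failures stay put): counting attempts rather than acceptances makes the
chain's stationary distribution exactly uniform over the fixed-margin
matrix class (thinning by acceptances would weight each matrix by its
number of available swaps). Defaults: 30,000-step burn-in, 1,000-step
thinning, 10,000 null draws — conventional values, all recorded in the
result object. Unswappable (frozen) matrices return a flagged degenerate
result instead of raising so batch runs survive. The swap kernel is a
numba-compiled loop; uniformity is tested against exhaustive enumeration
of small fixed-margin classes, and margin preservation is asserted on
every draw in test mode.

## Networks, modules, baselines

Spearman correlations use mid-ranks with two-sided t-approximation
p-values (an exact-permutation mode exists for n ≤ 10 and serves as the
small-n oracle). Edges require ρ > 0.6 AND p < 0.01 (both strict), with no
multiplicity correction by default to mirror the field convention the
thresholds come from; strong negative pairs are kept in a ledger and are
never edges or module inputs. Module detection is Louvain on the
positive-edge graph with ρ weights, seeded and therefore deterministic,
with module ids ordered by decreasing size. Topology metrics are
unweighted: average local clustering (degree < 2 counts 0) and average
shortest path on the largest connected component, with the component
coverage fraction logged. Erdős–Rényi baselines are exact-G(n, m) draws
(uniform over simple edge sets, sampled as m distinct index pairs);
per-graph metrics (multilevel modularity, clustering, LCC path length,
computed with igraph for both the empirical network and the ensemble so
the comparison is like-for-like) are streamed without retaining graphs.
"Higher than random" verdicts use the ensemble's 0.95 quantile.
Module–environment association is a partial Mantel of Bray–Curtis
distances on each module's member sub-table against each covariate's
Euclidean distance, controlling the other three covariates (the distance
choice for module communities is undocumented in legacy workflows;
a weighted-UniFrac variant can be obtained by passing that matrix
directly to `partial_mantel`).

## Synthetic communities

The generator emulates the statistical structure of a two-cluster,
43-digester survey; it does not simulate reads, chemistry dynamics or
mechanistic ammonia inhibition. Per-sample log-intensities are

```
η = baseline(role) ± separation·Δ(cluster) + λ·f_module + Σ_k β_k z_k + ε
```

softmaxed into compositions and drawn Dirichlet-multinomial at uniform
depth (default 2230; concentration 500 gives mild overdispersion versus a
plain multinomial). OTU roles: 10 core OTUs (high shared baseline, the
first four with a Cluster-I surplus, labelled with *Clostridium*-group
genera, which plants the lower Cluster-I Shannon diversity); 6 modules of
15 OTUs sharing one standard-normal latent factor per sample with loading
1.5 (strong co-variation plus occupancy dropout: cosmopolitan but not
core); Cluster-II and Cluster-I-specific blocks (Spirochaetes /
Bacteroidales / methanogen analogues vs Clostridiales analogues); and a
rare log-normal tail capped so no tail OTU can drift into the core
stratum. Covariates NH₄⁺-N, pH, COD, phosphate are log-normal/clipped
Gaussian with a planted NH₄⁺-N–phosphate correlation (r ≈ 0.75 on the
latent scale) and linear loadings on designated blocks (ammonium
suppresses the methanogen analogues). The phylogeny is a Kingman
coalescent over all OTUs; module members are deliberately not clades.

Structural constants were fixed once so the default survey meets its
planted contracts — every core OTU strictly above 90 % prevalence, every
non-core OTU at or below it, module OTUs cosmopolitan, within-module
Spearman above the 0.6 edge threshold — verified by a bounded
resample-until-valid loop (the prevalence check needs survey-sized n:
at 16 samples the > 90 % line leaves no gap, so reduced fixtures may set
`enforce_prevalence=False`). All randomness flows from one seed through a
single generator; equal seeds give bit-identical output.

What passing recovery tests on these communities does **not** show:
robustness to compositional artifacts beyond the softmax coupling,
to uneven sequencing depth, to taxonomic misassignment, or to module
structure weaker than the planted loading; real surveys can fail any of
those.

## Problem sizes used in validation

Recovery and calibration checks run at the survey's native scale
(43 samples × 300 OTUs; 50 generator seeds for module recovery, 100
segregation replicates, 1000 calibration simulations at 99 permutations,
10,000-draw null chains and 10,000-graph ensembles), chosen to keep
Monte-Carlo error well inside the asserted bands.

## Known limitations

* Spearman p-values rely on the t-approximation; at very small n the
  exact mode should be preferred.
* Louvain is greedy; module counts on real data depend on resolution and
  tie-breaking (seeded here), so module *counts* are not comparable
  across tools.
* The C-score chain's mixing time is matrix-dependent; the defaults are
  generous for survey-sized matrices but no convergence diagnostic is
  computed.
* VPA assumes linear responses on the supplied scale; transform
  abundances (e.g., log or Hellinger) before calling if curvature is
  expected.
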