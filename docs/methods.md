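# Methods

`ipfnet` re-implements, as a tested and reusable pipeline, an integrative
analysis workflow for multi-dataset case/control lung transcriptome
compendia: harmonisation, consensus differential expression, gene-set and
cell-marker scoring, disease-module construction on a protein
interactome, unsupervised molecular subtyping, key-driver identification
and diffusion-based drug-target prioritisation. This note documents the
models, the parameters that matter, the synthetic data the test suite
uses as ground truth, and the numerical choices made where the design was
genuinely open.

## Harmonisation

**Quantile normalization.** The reference distribution is the row-wise
mean of the column-sorted matrix; each sample's values are replaced by
the reference values at their within-column ranks. Tied values receive
the mean of the reference values across the tied rank span, which makes
the transform well defined and idempotent. Applying it forces every
sample's marginal distribution onto the common reference, removing
sample-level location/scale and shape differences while preserving
within-sample rank order.

**Empirical-Bayes batch adjustment.** Residual dataset effects are
modelled per gene g, batch b as an additive location shift γ_gb and a
multiplicative error scale δ_gb (the classic parametric location/scale
batch model). The condition (case/control) enters the gene-wise linear
model as a covariate whenever it is estimable, so genuine disease effects
are not absorbed into the batch terms; if any batch contains only one
condition the covariate is dropped globally with a warning (fitting
different designs per batch would make the shared standardisation step
ill-defined). Data are standardised against the batch-free fit, batch
parameters are estimated per gene, shrunk toward batch-level parametric
priors — normal for γ, inverse-gamma for δ² — with hyper-parameters by
method of moments and the standard iterative EB solution, then removed,
and grand mean plus covariate effects restored. Only the parametric
variant is implemented. A consequence worth knowing: the EB shrinkage
deliberately leaves the *shrunken sampling noise* of per-batch means in
place, so with a small number of genes and homogeneous batch effects the
per-gene residual batch gap is of order (1−w)·σ/√n_b rather than 0; with
gene-specific batch effects (large across-gene prior variance, the
situation the model is built for) the shrinkage weight w→1 and residual
gaps vanish.

**PCA quality control.** PCA on the gene-standardised matrix, with a
batch-separation statistic defined as the between-batch over total
variance (η²) of the PC1 scores — ≈0 when batches are mixed, →1 when PC1
is a pure batch axis. On the synthetic compendium with batch sd 1 this
drops from >0.99 to <10⁻⁵ after adjustment.

## Consensus differential expression

Three independent per-gene two-group statistics are intersected; a gene
is a consensus DEG only if all three are significant *and* the fold
change passes |log2FC| > log2(1.5) ≈ 0.585 (log2FC = difference of group
means on the log2 scale). Requiring concordance minimises the realised
FDR of the final list.

1. **Moderated t** — gene-wise residual variances s²_g on d_g df are
   shrunk toward a prior: s²_post = (d₀s₀² + d_g s²_g)/(d₀+d_g), with
   (d₀, s₀²) estimated by method of moments on log s²_g through the
   digamma/trigamma identities for the log of a scaled χ². The moderated
   t = log2FC/(s_post·√(1/n₁+1/n₂)) is referred to a t distribution on
   d₀+d_g df; BH adjustment across genes, significance at adjusted
   p < 0.01. With homoscedastic genes the estimated d₀ is infinite
   (complete shrinkage, the correct limit); `prior_df=0` recovers the
   ordinary pooled t exactly.
2. **SAM-type regularised d** — d_g = (mean₁−mean₂)/(s_g+s₀) with s_g the
   pooled sd and the fudge constant s₀ set to the median of the s_g (a
   simplification of the original quantile search; configurable). The
   null comes from condition-label permutations *stratified by batch* so
   the compendium structure is respected; when fewer distinct stratified
   permutations exist than requested, all of them are enumerated. The
   q-value is the median permutation tail count over the observed tail
   count at |d_g|, monotonised (running minimum from the top of the
   ranking) and capped at 1; significance at q < 0.01. Note a known
   small-sample property of the median estimator: the single top-ranked
   null gene receives q = 0 whenever more than half of the permutations
   produce no exceedance, so the SAM arm alone is slightly anticonservative
   at the very top of the list — the three-way intersection is what
   controls the consensus FDR, and does (empirical FDR ≤ 0.05 on planted
   truth).
3. **Artificial between-condition component** — ψ2_g =
   (mean₁−mean₂)·√(n₁n₂/n)/s_g, the scaled second artificial component of
   a multivariate inferential analysis, reduced here to the single
   statistic used as a third independent filter. Single-step permutation
   FDR(t) = mean permutation tail count over observed tail count at
   t=|ψ2_g|, monotonised; significance at FDR < 0.01.

Permutation count defaults to 1000 (the suite uses 200–300, which is
ample for the 0.01 thresholds given the count-ratio construction).

## Gene-set and cell-marker scoring

* **ORA** — one-sided Fisher exact test of a query list against each set
  over the measured universe; odds ratio with Haldane 0.5 correction when
  a margin cell is 0; BH across sets; significant at adjusted p < 0.05.
* **GSEA** — genes ranked by signal-to-noise (difference of group means
  over sum of group sds; the classic default) for phenotype-based runs;
  running sum rises by |r|^p (p = 1) normalised over hits and falls by
  1/(N−N_h) at misses; ES is the signed extremum. Nominal p and NES are
  computed against sign-matched permutation ES (NES = ES/mean|ES*| of
  matching sign); the collection-level FDR follows the positive/negative
  tail pooled-NES procedure; significance screened at FDR < 0.25.
  Phenotype permutation is used with ≥7 samples per group, gene-label
  permutation otherwise. For a single set the FDR degenerates to the
  permutation-NES tail fraction.
* **ssGSEA** — per sample, genes ordered by decreasing expression (ties
  broken by gene order); score = Σ over positions of weighted in-set ECDF
  (weights = expression rank^α, α = 0.25) minus uniform out-of-set ECDF;
  no final range-normalisation (a documented dialect choice). Rank-based,
  hence invariant to sample-wise monotone transforms.
* **Eigengene** — first principal component of the standardised member
  sub-matrix, unit variance, sign anchored so the mean correlation with
  member genes is ≥ 0. The cited literature does not restate the exact
  recipe; first-PC with sign anchoring is the standard reading.
* **Cell scores** — ssGSEA per marker set, z-standardised across samples,
  reported as *relative* enrichment per cell type. This deliberately
  replaces full digital deconvolution: no constrained regression, no
  proportion estimates — only rank-based relative enrichment.
* **Enrichment map** — nodes are significant sets; edges connect sets
  whose Jaccard similarity strictly exceeds 0.10.

## Disease module, hubs, key drivers, diffusion

The consensus up-regulated DEGs are projected onto the interactome as an
induced subgraph (isolated nodes retained and counted); the largest
connected component (ties broken by the component containing the
lexicographically smallest node) is the disease module. Centralities on
it: degree; closeness with within-component normalisation (n_c−1)/Σd
(total on disconnected inputs, 0 for singletons); betweenness by Brandes'
exact algorithm, unnormalised, endpoints excluded — ranks, the only thing
consumed downstream, are normalisation-invariant. Hubs are the
intersection of the ⌈0.10·n⌉ top-ranked nodes of all three measures, with
name-ascending tie-breaks for determinism.

**Key driver analysis** tests *every* network node (a driver need not be
a module gene): for node v with depth-d neighbourhood N_d(v) (d = 1 by
default, configurable), the statistic is the fold enrichment
(|N_d(v)∩module|/|N_d(v)|)/(|module|/|nodes|); the null permutes
module-membership labels over nodes (10,000 permutations by default), p
uses the add-one estimator so it is never 0, BH across tested nodes, and
key drivers are called at FDR < 0.01. Nodes with fewer than 3 neighbours
are not tested (degenerate statistics). This is deliberately *not* a
Bayesian-network reconstruction: causal network inference needs data
(e.g., genetics of expression) that a transcriptome compendium does not
provide, so neighbourhood enrichment on the supplied interactome is the
module's central, documented simplification. Depth-1 label permutation
induces an exact hypergeometric overlap law, which the test suite uses as
an oracle; note the null is discrete, so the realised type-I rate at
p < 0.05 on sparse graphs is conservative (~0.02), never inflated.

**Diffusion scoring** uses the regularized-Laplacian kernel
K = (I+L)⁻¹ on the interactome's largest connected component (heat kernel
exp(−tL), t=1, available as an alternative), with the binary seed
indicator y of disease-module genes: f = K·y. The Monte-Carlo
normalisation permutes the seed indicator uniformly over nodes preserving
the seed count (1000 draws by default) and reports
z_i = (f_i − mean_i)/sd_i; a node with degenerate permutation sd is
flagged and assigned z = 0. Drugs are scored by the z of their mapped
targets; per-target scores are primary, with the mean (and max) over
mapped targets as a convenience aggregate; unmapped targets are reported
explicitly.

## Subtyping and clinical statistics

Cases only are clustered — the features are the consensus up-regulated
DEGs (the full DEG set is available behind a flag), standardised to mean
0/sd 1 per feature — by Ward agglomeration on Euclidean distances. The
number of clusters is chosen as the silhouette maximum over k = 2..6
(silhouette is undefined at k = 1; SSE is still reported from k = 1), with
the SSE elbow (maximum second difference) reported for corroboration.
Group comparisons use the Welch (unequal-variance) t-test — a safer
default than the pooled t when only "unpaired t-test" is specified —
and Fisher's exact test for 2×2 tables (sample odds ratio with Haldane
correction; p = 1 for a zero margin). Clinical correlations are Pearson r
with t-distribution p and Bonferroni adjustment (adjusted p = min(1,
p·m)); pairs with missing covariates are dropped per pair, constant
vectors are reported as missing with a note.

## Synthetic data: what it emulates and what it does not

The generator produces the *study conditions* for every recovery test.
Per gene g and sample i in batch b:

    x_gi = μ_g + δ_g·case_i + sub_g(i) + sev_g(i) + o_gb + s_gb·ε_gi

with baseline μ_g ~ N(7,1) on the log2 scale; planted effects
δ_g = ±1.0 log2 units for 60 up / 40 down genes (defaults); gene-specific
batch offsets o_gb ~ N(0, 1.0) and noise scales s_gb ~ LogNormal(0, 0.1)
multiplying ε ~ N(0, 0.5) — exactly the location/scale structure the
batch adjustment assumes, making preprocessing recovery a fair test. The
default compendium is 3 batches × (20 cases + 20 controls), 1000 genes.
Cases split into two subgroups (alternating within batch, so batches stay
balanced), each over-expressing its own 40-gene pathway by 1.5 log2
units; subgroup pathways are disjoint from the planted DE sets so DEG
recovery and subtype recovery remain independent tests — note that
subgroup genes still carry a real case-control shift of half the subgroup
effect, which is why DEG-calibration runs switch the subgroup effect off.
A 30-gene severity pathway gets a continuous per-case activity
a_i ~ N(0,1); FVC and DLCO percent-predicted are linear in the severity
pathway's mean expression with negative slopes (−5 and −4, Gaussian noise
sd 5 and 6, intercepts 80 and 70) and exist for cases only, as in real
compendia. The realised activity–FVC correlation is recorded in the truth
object, giving correlation-recovery tests a target sign and magnitude
(≈ −0.6 to −0.7 at the defaults).

The interactome generator grows a Barabási–Albert preferential-attachment
graph (500 nodes, 2 edges per new node by default) over the compendium's
gene names and promotes low-degree non-module nodes to key drivers by
wiring each to sampled module genes up to degree 20, so ≥80% (by
construction ~90%) of a driver's neighbours are module members. Gene-set
decoys are uniform random draws (they therefore overlap planted DE genes
at the hypergeometric expectation — decoys are null for *structure*, not
for phenotype association); drug tables pair driver-targeting drugs with
random-target decoys.

What the generator does **not** emulate: probe-level microarray noise,
count-based RNA-seq sampling, gene–gene correlation beyond the planted
block structure, missing values, annotation mismatch between matrix and
interactome, or confounding between batch and condition. Passing the
recovery suite therefore demonstrates correctness of the algorithms under
the stated generative model, not performance on any real compendium.

## Numerical and reproducibility choices

* One global seed per run; every stochastic stage derives a substream as
  (seed·1000003 + crc32(stage)) mod 2³¹, so stages are independently
  reproducible and any derived seed stays below 2³¹.
* All result tables are written with a fixed float format (%.6g) and rows
  sorted by gene/set/sample name; two runs with the same config are
  byte-identical, and every stage writes a JSON provenance record
  (parameters, derived seed, sha256 input hashes, output row count).
* Permutation p-values use the add-one estimator (never 0); BH via a
  single shared implementation; ceilings (⌈·⌉) and name-ascending
  tie-breaks wherever a top-fraction or ranking is taken.
* Ties in expression ranks (ssGSEA/GSEA orderings) are broken by gene
  order/name, deterministically.
* Degenerate inputs are contracts, not crashes: zero-variance genes get
  t=0/p=1 with a log note; singleton graph components get closeness 0;
  degenerate permutation sds get flagged z=0; a drug with no mapped
  target gets a missing aggregate and a flag.
* Test-suite problem sizes (1000-gene compendia, 500-node graphs, 200–300
  permutations for the DEG arms, 10,000 for KDA) were chosen as the
  smallest sizes at which the planted effects are comfortably in the
  asymptotic regime the methods assume.

## Known limitations

* The batch model assumes no batch×condition confounding; a fully
  confounded batch degrades to an adjustment without condition protection
  (with a warning) and genuine disease signal may then be attenuated.
* KDA on the supplied interactome finds *topological* regulators of the
  module, not causal ones; directionality is out of reach without
  perturbational or genetic data.
* The GSEA FDR follows the conventional pooled-NES procedure, whose
  accuracy degrades for very small collections; with one set it reduces
  to a permutation-NES tail.
* Quantile normalization assumes most genes are not differentially
  expressed; with very large planted fractions it attenuates effects.
* The cell scores are relative enrichment values and must not be read as
  cell-type proportions.
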