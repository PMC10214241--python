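# Methods

## Scope and model

The pipeline reconstructs, as reusable library code, a coexpression-network
analysis of matched head-and-neck tumor cohorts: genes are grouped into
modules by weighted correlation network analysis, modules are annotated
against ferroptosis/inflammation/tumor-inflammation/EMT/ISG signature sets
and GO/KEGG-style collections, signature-related subnetworks are extracted
from a trimmed network, and each subnetwork is tested for a gradual
increase of tumor/normal expression from the inner tumor core over the
invasive front to metastases.  Companion stages score and stratify
single-cell/spot columns by signature expression and intersect up-regulated
gene lists across platforms.

Alignment, quantification, batch correction, embedding and cell clustering
are out of scope; cluster/region labels are consumed as input.

## Network construction

- **Correlation.** Pearson on log2(TPM + 1) values (Spearman available via
  config).  At least 3 samples; zero-variance genes are removed upstream
  with a warning.  Genes with ≥ 90% zero abundance are excluded first
  (inclusive cut — the conservative reading of the 90% rule).
- **Soft threshold.** Candidates β = 1..20.  For each β, unsigned adjacency
  `|cor|^β` (signed variant `((1+cor)/2)^β` available), connectivity
  `k_i = Σ_j a_ij` with `a_ii = 0`, and the signed scale-free fit index:
  nodes binned into 10 equal-width bins of k, log10(frequency) regressed on
  log10(mean k) over non-empty bins, R² signed by the slope.  Selected β is
  the smallest candidate with fit ≥ 0.7; if none qualifies, the β of
  maximal fit is used with a warning.  The scan is fully deterministic.
- **TOM.** `TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with unit
  diagonal; an exactly zero denominator (isolated pair) yields 0.  Memory
  is O(n²) — about 2.7 GB of doubles at 18k genes; block-wise decomposition
  is not implemented (documented limitation).
- **Clustering.** Average linkage (UPGMA) on `1 − TOM` via
  scipy.cluster.hierarchy; merge heights are invariant to leaf permutation.
  scipy's nearest-neighbour-chain implementation is deterministic for a
  given input, which we treat as sufficient tie handling rather than
  imposing a bespoke lexicographic rule.

## Dynamic tree cut

`cutreeDynamic`-style module detection is authored here (no reference
implementation of the hybrid cut is available in this environment) as a
bottom-up branch finalization over the merge sequence:

- Walking merges in height order, a cluster is finalized as a module at the
  moment it is absorbed, if it (i) has ≥ `minModuleSize` members, (ii) is
  *separated* — the absorbing height clears the cluster's own top merge by
  ≥ `gap_frac` of the headroom to the dendrogram's maximum height
  (`gap_frac` = 0.55/0.40/0.30/0.20/0.10 for deepSplit 0..4), and (iii) is
  *coherent* — its mean within-cluster TOM similarity exceeds a noise
  floor.  A PAM-like stage then assigns unlabeled leaves to the nearest
  module when they clear the same floor; labels are renumbered by
  decreasing module size.  A plain static cut (`tree` variant) is provided
  for comparison.
- **Noise floor.** Judging branch coherence on the raw dissimilarity scale
  is not portable across data sets: after power-thresholding, a weak but
  real module in structured data can be *less* tight in absolute terms
  than chance clusters of an unstructured data set at a lower power.  The
  pipeline therefore calibrates the floor per data set: each gene's sample
  values are independently permuted (fixed internal seed, so the whole
  chain stays deterministic), the permuted data is pushed through the same
  adjacency/TOM computation, and the floor is set to twice the
  99.9th percentile of the null similarities.  Chance-tight clusters in
  structure-free data sit at the null scale and are rejected (simulated
  pure-noise matrices label ≥ 95% of genes unassigned), while planted
  modules with within-correlation 0.64 sit orders of magnitude above it.
- Degenerate inputs: fewer leaves than `minModuleSize` (or n ≤ 1) yield
  all-unassigned labels with a warning; dissimilarities are expected in
  [0, 1].

## Annotation, trimming, subnetworks

- **Hypergeometric enrichment** is computed in log space (gammaln) as the
  upper tail `p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n)`; the background N is
  the gene universe that entered network construction (post-sparsity
  filter), not the whole genome, because modules are drawn from that
  universe.  Sets are intersected with the background before counting; a
  set entirely outside it is skipped with a warning.
- **BH adjustment** is the step-up `q_(i) = min_{j≥i} p_(j)·m/j`, applied
  separately within each annotation category (the five-signature
  collection is one family; each GO/KEGG-style collection is its own).
- **Representative terms**: per category, unique terms ranked by best q
  (ties by p, then name), truncated to the top 20, filtered to q ≤ 0.05.
- **Trimming**: nodes are the union of representative-term members; a
  candidate edge needs weight > 0.01 *and* positive Pearson correlation.
  "Weight" refers to the TOM similarity by default — the reading that
  honours both the 0.01 floor and the positive-association rule — with
  adjacency or raw correlation available as config switches.  Each node
  ranks its candidate edges by descending weight (ties by lexicographic
  pair) and keeps its top 50; an edge survives if *either* endpoint keeps
  it (the most inclusive consistent reading of "top 50 edges for each
  source and target node").  Trimming is deterministic and idempotent.
- **Signature subnetworks**: seed modules have signature q ≤ 0.05 and at
  least one signature gene among their in-network members; the subnetwork
  is the seed modules' genes plus all direct neighbours.  The node set is
  monotone non-decreasing in the q cut.

## Gradient analysis

- Per patient, gene and tumor site: `log2((TPM_T + 1)/(TPM_N + 1))` against
  the same patient's normal (normals averaged on the log scale if a
  patient has several; multiple tumor samples at one site are averaged per
  patient).  Site summaries take the median across patients by default;
  pooling all samples is available by flag, since the original analysis
  does not state which was used.
- **Wilcoxon signed-rank** (authored): zeros dropped, midranks for ties,
  W = sum of positive-difference ranks.  For n ≤ 25 remaining pairs the
  two-sided p is exact: the full 2^n sign-assignment null distribution is
  built by convolution over doubled midranks (identical to literal
  enumeration, in polynomial time), and p = 2·min(P(W' ≥ W), P(W' ≤ W))
  capped at 1.  Above n = 25 a normal approximation with tie variance
  correction `Σ(t³−t)/48` and a 0.5 continuity correction is used; its
  exact type-I rate at n = 40 and α = 0.05 is 0.048.  All differences zero
  yields (W, p) = (0, 1).
- **Verdict**: gradual increase = strictly increasing medians IC < IF < M
  (strict, as printed) *and* p ≤ 0.05 for IC vs IF *and* for IC vs M,
  pairing by gene.  No multiplicity adjustment is applied across
  subnetworks (none is applied in the source analysis).  Because the test
  treats genes as exchangeable units, strong within-module correlation
  makes the p-values anti-conservative in absolute terms; the verdict is
  used as a descriptive pattern label, as in the original analysis.

## Scoring, stratification, cross-platform intersection

- Score = unweighted mean of log2(x+1) expression over the signature genes
  present (sum mode by flag); the mean keeps the printed 5/3 high/low cuts
  size-free.  Stratification is strict above (score > 5 high) and
  inclusive below (score ≤ 3 low); intermediates are excluded downstream.
- Group DE: two-sided Mann–Whitney per gene (scipy; exact for tie-free
  groups of ≤ 8 columns, decided per gene, tie-corrected asymptotic with
  continuity otherwise), log2 FC = mean(high) − mean(low) on the log2p1
  scale, BH over all genes tested.  Strata need ≥ 2 columns each.
- Epithelial calling: per cluster, the mean epithelial score of member
  columns; tumor iff mean > cut.  No universal threshold exists, so the
  cut is a required explicit parameter on real data (tests derive it from
  the planted score modes).
- Top-N up-regulated genes are ranked by descending fold change (ties by
  p, then name; p-ranking by flag), fold-change filtering uses
  `(mean_T + 1)/(mean_C + 1) ≥ 1.5` (inclusive), and the platform
  intersection is a sorted set intersection with rank provenance.

## Synthetic data

- **Cohort** (per gene g in module m, patient p, site s, log2 scale):
  `x = baseline_g + u_p + noise_sd·(λ_m f_{m,p,s} + √(1−λ_m²) ε) + δ_{m,s}`
  with λ_m = √r, so the module term's within-module correlation is exactly
  r; `u_p ~ N(0, 0.3)` is a patient effect shared across a patient's
  samples (a realistic inter-patient baseline, contributing ~0.08
  background correlation); the site factor f is redrawn per site within a
  patient so T/N contrasts are driven by the planted shifts δ, not shared
  factors.  Matrices are emitted as TPM = 2^x − 1 clipped at 0
  (baseline mean 5, sd 2 log2 units, so low-baseline genes produce zeros
  and exercise the sparsity filter).
- **Defaults** (the study conditions for all tests): 15 patients × 4 sites
  (60 samples), 1200 genes, five modules of sizes 120/100/90/80/60 at
  r = 0.64 carrying the five signatures; ferroptosis and inflammation have
  coupled increasing shifts δ = (0.5, 1.5, 2.5) and (0.4, 1.2, 2.0);
  tumor_inflammation is flat (0.5), EMT null, ISG decreasing.  Per-step
  shifts of ~1 log2 unit keep the planted pattern clear of the sampling
  noise of a 15-patient median (sd ≈ 0.37 per site due to the shared site
  factor), which a real cohort of this size would equally need.  Signature
  sets take 40 genes from their module plus 20 background genes.
- **Spots**: negative-binomial counts (gamma–Poisson, dispersion 0.5,
  library size 20 000 over 1000 genes); 50 signature genes get an 8× base
  abundance and a 2^1.5-fold increase in front spots; front spots occupy
  the lattice perimeter.  Ground truth (module map, signature map, shifts,
  regions, planted DE genes) is emitted alongside every matrix.
- Generators are pure functions of (spec, seed); the on-disk fixture
  regenerates byte-identically from its seed and is therefore written at
  test time rather than committed.

### What the generator does and does not emulate

It reproduces the *statistical* structure the pipeline relies on — matched
sites per patient, correlated modules enriched for named signatures,
monotone per-site shifts, overdispersed spot counts with regional effects —
but not real gene identities, realistic pathway topology, uneven site
coverage, HPV status, compositional library-size artefacts or spatial
autocorrelation beyond the region split.  Passing tests therefore
demonstrate that the implementation recovers planted structure under the
model's assumptions, not that the biological claims transfer to any given
real cohort.

## Known limitations

- Module eigengenes, eigengene-based module merging and block-wise network
  decomposition are not implemented.
- The full-scale network statistics of the motivating study (a trimmed
  network of 1447 nodes and 12 037 edges at power 17; subnetworks of
  42/63/132/116/66 genes; 539 fold-change-filtered genes) derive from
  patient data deposited under controlled access (GEO GSE178537, GSE181300,
  GSE185965, GSE196947) and cannot be recomputed here; the synthetic
  cohort is a statistical stand-in, not a reproduction of those numbers.
  Likewise the two platform gene lists behind the published 42-gene
  intersection live in supplementary tables not redistributable with this
  package; `platform_gene_lists` generates a synthetic pair with the
  published sizes (1500, 539, overlap 42) so the intersection operation is
  exercised end to end.
- When the soft-threshold scan settles on a low power (a possibility on
  cohorts whose connectivity is far from scale-free), modules whose
  planted shift patterns are correlated can merge, and subnetwork
  neighbours can couple a flat module to a gradient one; the pipeline
  reports what it measures in that regime rather than guarding against it.
- The coherence floor assumes the permutation null is a fair model of
  "no coexpression"; strong technical covariates shared across all genes
  (e.g., severe batch structure) would inflate both the data and the null,
  which is the intended behaviour but should be kept in mind.
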