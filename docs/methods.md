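# Methods

## Model and procedure

The pipeline joins two evidence channels on one gene ranking.

**TWAS.** The gene-trait association statistic is
Z = wᵀz / √(wᵀLw), where w is the gene's cis-eQTL weight vector, z the GWAS
SNP Z-scores and L the SNP LD correlation matrix, all restricted to the
shared SNP frame. Under z ~ MVN(0, L), Z is exactly standard normal, so
two-sided normal p-values are valid without any genomic-control step. The
denominator carries the square root: wᵀLw is the variance of the predicted
expression score wᵀz, and dividing by the variance rather than the standard
deviation would not yield a pivotal statistic. FDR control is
Benjamini–Hochberg, computed twice — within each tissue (per-tissue
discovery lists) and pooled across tissues (headline significance) — since
both conventions are in use and they answer different questions; output
tables carry both columns.

Harmonization aligns the weight panel to the GWAS allele orientation: a
weight whose (ref, alt) pair is swapped relative to the GWAS record flips
sign; a pair matching neither orientation is dropped and counted. No strand
flipping is attempted — panels and summary statistics are assumed
co-stranded, which holds within a simulation or any harmonized release, and
avoids silently corrupting strand-ambiguous (A/T, C/G) SNPs. Coordinates
are 1-based inclusive; the cis window is TSS ± 1 Mb, closed.

Redundant predicted-expression features are grouped by the correlation
r = wᵢᵀLwⱼ / √((wᵢᵀLwᵢ)(wⱼᵀLwⱼ)) on a zero-padded shared frame: the
transitive closure of |r| > 0.9 merges features, |r| < 0.008 marks
independence, and anything between is labeled a joint group without
refitting — the labels are reported, and conditional modeling of joint
features is out of scope. Genes are also annotated with a 100 kb segment id
(TSS ÷ 100,000) as positional metadata only. Representative selection and
every other tie is broken lexicographically so outputs are deterministic.

**CGSEA.** Gene scores default to the signed TWAS Z of the tissue with the
smallest p per gene (a `max_abs` rule is available). The weighted KS
running sum over the descending ranking uses hit increments |score|^p
(p = 1 by default) normalized by the hit total, and miss decrements
1/(N − N_hits); the ES is the running-sum value of maximal absolute
deviation, with the leading edge taken at-or-before the peak (positive ES)
or at-or-after it (negative ES). The null permutes gene labels — at this
stage only gene-level scores exist, so phenotype permutation is not
available — reassigning membership uniformly at the observed set size.
p = (1 + #{|ES_perm| ≥ |ES_obs|}) / (n_perm + 1), never exactly zero.
NES = ES_obs / mean(|ES_perm| of the observed sign); when no permutation
shares the sign, NES is reported missing and flagged. Significance requires
all three of P < 0.05, BH-FDR < 0.05 and |NES| > 1. Set-size bounds default
to [5, 500] after restriction to the score universe (the intersection of
scored genes and set members; its size is logged). NES values under this
convention are O(1); enrichment reports from other normalizations can be
orders of magnitude larger and are not comparable.

**Differential expression.** Per-gene Welch (unequal-variance) t-test on
the log2 matrix, case minus control means as log2FC, BH across genes. The
moderated-statistic approach of limma/GEO2R is deliberately not emulated:
its exact settings in any given archived analysis are unrecoverable, while
the Welch test is assumption-light and well-defined. DEG calls use strict
inequalities (adj. P < 0.05 AND |log2FC| > 0.5): a gene exactly at either
boundary is not called. Input is assumed log2-transformed; no
normalization is applied.

**Network analysis.** Edges at combined score ≥ 0.4 (inclusive) form a
simple undirected unweighted graph; sub-threshold endpoints remain as
isolated nodes. MCC(v) = Σ (|C| − 1)! over maximal cliques C containing v
(isolated nodes score 0). EPC removes each edge independently with
probability 0.5 per iteration and averages the count of other nodes left in
v's component; the default 1,000 iterations (classical descriptions use
5,000) keeps desk-scale runtime with a CLI override, and all comparisons of
EPC values are tolerance-based. MCODE follows the three-stage scheme:
vertex weight = k × density of the highest k-core of the closed
neighborhood (0 below the degree cutoff); complexes grow breadth-first from
the highest-weighted unvisited seed, admitting neighbors with weight >
seed_weight × (1 − node_score_cutoff) up to the depth cap; a haircut pass
iteratively strips degree-1 members, complexes without a 2-core are
discarded, and score = density × size. Fluff is off by default. ORA uses
the exact hypergeometric upper tail P(X ≥ k) with BH across terms; the
universe defaults to all genes scored by the calling stage and is always
explicit.

**Integration arithmetic.** Overlap percentages are
round-half-even(100 × numerator/denominator, 2). The overlap universe uses
per-tissue nominal P < 0.05 while headline gene lists use FDR < 0.05; the
two thresholds are separate config keys because they serve different
roles (breadth for intersection, stringency for discovery).

## Synthetic data

The generator emulates the statistical skeleton each stage consumes:

- **LD**: block-diagonal AR(1) within blocks, corr(i,j) = ρ^|i−j|
  (ρ = 0.6 default, typical of dense cis regions). Stored per block — the
  dense matrix is never materialized at scale.
- **Weights**: each gene draws `snps_per_gene` SNPs from one block,
  standard-normal weights rescaled so wᵀLw = 1. Tissue 0 carries the base
  weights; other tissues add Gaussian jitter (sd 0.25) before
  renormalization, emulating shared-but-not-identical cis architecture so
  a strong gene is discoverable in every tissue.
- **GWAS Z**: per block, MVN with covariance L and mean
  Σ_g α_g·(Lw_g)/√(w_gᵀLw_g) over causal genes (tissue-0 weights), so a
  causal gene's own tissue-0 TWAS Z has expectation exactly α. α is defined
  on the standardized gene-statistic scale — the simplest scale on which
  recovery is directly checkable.
- **Chemical sets**: active chemicals draw round(fraction × size) members
  from causal genes, the rest uniformly from non-causal; inactive sets are
  uniform. Set sizes are uniform on the configured range, clamped to the
  universe.
- **Expression**: gene baseline ~ N(6, 1) plus planted log2FC in cases plus
  N(0, 0.3²) noise, Gaussian on the log2 scale by design to match the Welch
  test (no count model).
- **PPI**: disjoint planted Erdős–Rényi modules over consecutive genes plus
  background edges (p = 0.02), scores uniform on [0.4, 1].

Sub-seeds derive by hashing (generator name, master seed), so adding a
generator never perturbs another's stream, and every generator is a pure
function of its config. Defaults: 10 samples per expression group, noise
sd 0.3, two planted modules of sizes 6 and 4 at within-probability 0.9.

What the generator does **not** emulate: realistic allele frequencies or
empirical LD maps, imputation quality, count-based RNA-seq noise,
library-size or batch effects, scale-free PPI degree distributions, or
correlated chemical sets. Passing tests therefore demonstrate correctness
of the statistics and recovery under the stated generative model, not
robustness to the full messiness of real cohort data.

## Numerical choices

- Degenerate predictor variance wᵀLw ≤ 1e−12 is an error, not a zero
  division. ES values are clipped to [−1, 1] against last-ulp spill of the
  cumulative sum; at a magnitude tie between the positive and negative
  running-sum peaks, the reported sign follows the first extreme index,
  which floating-point noise can select — all oracle comparisons are on
  |ES| with sign checked only away from ties.
- p-values are floored at the smallest positive double before BH (BH
  requires p ∈ (0, 1]).
- Two-group tests with zero variance in both groups return p = 1 at equal
  means by convention.
- TSVs are written with repr/17-significant-digit floats and read with
  round-trip parsing, making rerun outputs byte-identical.
- All orderings (ranking ties, seeds, representatives, module members) are
  broken lexicographically.
- CGSEA permutation streams are seeded per chemical by hashing
  (chemical id, seed): results are independent of iteration order.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen to keep
Monte-Carlo error well inside the asserted tolerances: null calibration at
500 one-gene blocks of 50 SNPs; TWAS recovery over 20 seeds × 100 genes
(5 causal, α = 6); CGSEA recovery with 100 chemicals (5 active at fraction
0.8 over 20 causal genes in a 300-gene universe) at 1,000 permutations;
module recovery over 10 seeds. The CGSEA scenario keeps causal genes sparse
in the universe deliberately: under a gene-label permutation null, a dense
causal background inflates null ES for every set and masks planted
enrichment — the sparse design mirrors the CTD situation where
disease-associated genes are a small fraction of all annotated genes.

## Known limitations

- No weight training (BSLMM/elastic net): weight panels are inputs.
- Joint features are labeled, not conditionally refit; no colocalization.
- The best-tissue gene-score rule discards cross-tissue sign conflicts
  beyond the best-p tissue.
- The Welch test is anti-conservative versus moderated statistics at very
  small sample sizes.
- EPC and any Monte-Carlo score carry O(1/√n_iter) noise; ranks of
  near-tied nodes can swap between seeds.
- MCODE's grown complexes depend on the seed ordering of equal-weight
  vertices; determinism is guaranteed, optimality is not.
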