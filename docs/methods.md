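# Methods

## Scope and data model

`exopair` analyses matched tumor / adjacent-tissue exomes at the level of
*per-site paired read counts*: each candidate single-base variant carries
the tumor and normal alt/ref supporting-read counts plus the caller's site
metrics (MQ0, DP, QUAL, QD). Read alignment, duplicate removal,
realignment and recalibration are upstream concerns; the package consumes
their output (VCF with two samples and AD/DP FORMAT fields, or an
equivalent TSV dialect). Indels and multi-allelic sites are out of scope;
multi-allelic records are rejected at load with their record number.

Coordinates are 1-based inclusive on variants (VCF convention); chromosome
arms and CDS intervals are half-open internally and converted at I/O.

## Filtering cascade

Stages run in a fixed order (quality → exonic/depth → Fisher specificity →
shared/germline → window mask → known SNPs); every stage is contractive and
idempotent, and each surviving site records the stages it passed in an
audit trail. Threshold defaults (`PipelineThresholds`): MQ0 ≥ 4 **and**
MQ0/DP > 0.1 (the ratio guard treats DP = 0 with MQ0 > 0 as failing);
DP < 5; QUAL < 50.0; QD < 1.5; exonic floor of 10 reads satisfied by
*either* tissue (the requirement is read as per-tissue coverage of the
site, and demanding both tissues would conflate the exonic gate with the
specificity test); Fisher α = 0.01; germline rule alt ≥ 5 in *both*
tissues; window of 1,000 bp with > 10 variants.

**Specificity test.** The 2×2 table is alt vs ref reads per tissue — the
only table the paired counts support. The test is two-sided; the direction
(tumor vs non-tumor) comes from the sample odds ratio, Haldane-corrected
(+0.5 on all cells) *only* when a marginal cell is zero, never for the
P-value itself. Sites not significant in either direction stay
unclassified and leave the analysis at this stage.

**Window mask.** Windows slide per chromosome over one patient's pooled
(both specificity classes) variants; a window anchored at each variant
position suffices, since any overfull window can be shifted right to the
first variant it contains without losing members. All variants inside any
overfull window are removed. Tiled windows would miss straddling clusters.
The masked sites feed a kataegis diagnostic: a one-sided binomial test of
their C:G>T:A fraction against the patient-wide fraction — true kataegis
is C>T-enriched, mis-alignment clusters are not.

**Consequence calls.** Reference and alternate codons are translated with
the standard genetic code (Biopython), reverse-complementing minus-strand
transcripts; stop gain and stop loss are reported as the single `stop`
class, matching the three-way nonsynonymous / synonymous / stop summary
used for cohort tables.

## Arm enrichment

Rates are reported as mutations per 10 Mb per arm. The per-arm Fisher test
compares in-arm vs out-of-arm counts between the pooled tumor-specific and
non-tumor-specific sets (two-sided). The per-patient enrichment score

ES_ij = [(Nt_ij + c)/(Nt_−ij + c)] / [(Nn_ij + c)/(Nn_−ij + c)]

is a ratio of odds ratios with a symmetric Haldane–Anscombe pseudocount
c = 0.5 guarding empty arms. The score's verbal definition fixes the
numerator/denominator roles (tumor enrichment normalized by the patient's
background enrichment) but not the pseudocount; c = 0.5 is this package's
reconstruction. Truncation of scores below 1 to 0 applies only to the
display matrix; all statistics (subgroup rank-sum comparisons) run on raw
scores, since truncation would destroy ranks. Subgroup comparisons use the
exact rank-sum null for group sizes ≤ 12 when the scores are tie-free, and
the tie-corrected normal approximation with continuity correction
otherwise; ES values computed from small integer counts do tie.

A caveat established by simulation (and enforced honestly by the test
suite rather than hidden): with ~50 tumor and ~30 background variants per
patient spread over 20 arms, per-arm background counts are Poisson with
mean ≈ 1.5, so single-patient ES values are heavy-tailed and the arm with
the top advanced-vs-early mean-ES contrast identifies a factor-3 planted
excess in roughly 70% of cohorts, not near-certainty; reliable recovery at
cohort size 12 needs pooling (the pooled multi-cohort Fisher test
recovers the planted arm decisively). Users should treat single-cohort
per-arm ES rankings as descriptive.

## Spectrum

The 12 ordered base substitutions collapse over strand into six classes;
`classify_substitution` is strand-symmetric by construction. Group
comparisons are rank-sum tests on per-patient class *fractions* (pooled
counts would let high-burden patients dominate); patients with no variants
in a group carry no fraction and are dropped, and a group left empty skips
the test with a flag. The flanking-sequence matrix reports empirical base
frequencies at offsets −k..+k around variant loci on the strand as stored
(optionally collapsed to pyrimidine reference); loci within k of a contig
end are skipped and counted.

## Expression integration

Normalization follows the microarray convention: log2, quantile
normalization (each sample's sorted values replaced by the cross-sample
means of sorted values; ties receive the mean of their tied quantiles),
then per-sample mean-centering. Quantile normalization is idempotent on
tie-free data; with ties the rank-averaging rule is not a strict fixed
point, which is inherent to the tie convention.

**Directional KS enrichment.** For one sample profile, set-member values
are compared against non-member values with one-sided two-sample KS tests
in both directions (D+: members stochastically larger; D−: smaller). The
exact small-sample null distribution is used while n·m ≤ 10⁴, the
asymptotic formula beyond; P is floored at 1e-300. The signed score is
−log10 of the more significant side's P, positive when the up-side wins,
0 on exact ties or degenerate sets (empty intersection, set = whole
profile). Member-vs-non-member comparison within each sample was chosen
over a statistic-null formulation because it needs no resampling and keeps
per-patient scores comparable across sets.

**EASE.** The conservative enrichment P is the one-sided Fisher exact
P-value after decrementing the overlap cell by one; overlaps of 0 or 1
give P = 1 by construction. The background defaults to the number of genes
on the expression platform and is overridable. Raw P-values are reported
(Benjamini–Hochberg offered as an optional column, off by default).

**Subgroup-differential selection.** The gene-set universe is restricted
to sets with > 10 genes that contain at least one mutated gene, where
"mutated" is the union over patients of tumor-specific variant genes. Per
set, a two-sample Student t-test compares per-patient signed scores
between grade groups, and a fold criterion compares group mean score
*magnitudes* offset by +1 (zero guard), in either direction; selection
requires P < 0.05 and fold > 2. The subgroup test is not pinned down by the method's
verbal description; Student's t on per-patient scores is this package's
reconstruction, and a sign-aware alternative (absolute difference of
signed group means) is exposed as `fold_mode="signed_diff"`. The MT-vs-WT
comparison pools, per patient, the expression of that patient's mutated
genes against all other genes in the same sample and applies a two-tailed
two-sample t-test.

**Hubs.** Interaction degrees are counted on the undirected induced
subgraph of a user-supplied edge list (self-loops dropped with a warning,
duplicate edges collapsed), ranked by degree with lexicographic
tie-breaks. Network inference itself is out of scope.

## Synthetic cohort generator

The generator emulates the study conditions end-to-end; defaults: 6 early
+ 6 advanced patients; 10 chromosomes of two equal 10-Mb arms; 25
non-overlapping single-exon genes per arm with CDS lengths 300–2,400 bp
(multiples of 3); Poisson(50) tumor-specific and Poisson(30) background
variants per patient placed uniformly over CDS with arm probabilities
proportional to arm length; arm "1q" multiplied by 3 for advanced
patients' tumor variants. Read counts: per-tissue depth
negative-binomial(mean 30, dispersion 8); alt reads Binomial(depth, VAF)
with VAF 0.3 for somatic sites in their own tissue and a 0.5% error alt
rate in the other; germline sites use VAF 0.5 in both tissues with ≥ 5 alt
reads and depth ≥ 10 enforced. Site metrics are drawn so that each quality
gate independently fails with probability 5%. Substitution classes are
drawn from per-tissue six-class weights (C:G>T:A-dominant; T:A>A:T weight
0 in normal tissue, making that class tumor-exclusive); for free
placements the class is drawn first and the site placed on a compatible
reference base, so pooled fractions reproduce the configured weights.
Hypermutable foci plant 15 sites inside a 1,000-bp CDS window at VAF 0.5
(mis-alignment mismatches most reads), so that more than ten typically
survive the upstream gates and the window mask removes the cluster. A
global known-SNP position pool is generated first; `snp`-labelled sites
(tumor-like counts, listed positions) exercise the SNP-removal stage, and
no other site is placed on a pool position. Expression is
Normal(0, noise_sd) per gene × patient, with each patient's mutated genes
shifted by −2 and configured gene-set shifts (+2 on three sets in the
advanced group and two in the early group by default) added to member
genes. Ground-truth labels (somatic_tumor / somatic_normal / germline /
cluster / snp, plus quality-failure flags) are written to a sidecar table
that analysis code never reads.

What the generator does *not* emulate: subclonal tumor heterogeneity and
purity gradients, indels, GC- or mappability-dependent coverage,
correlated expression structure, and GO-term overlap topology (sets are
sampled independently). Passing recovery tests therefore demonstrates the
statistical machinery under the stated read-count model, not robustness to
those real-data complications.

Determinism: every stage derives its RNG from (seed, stage index); equal
configs give byte-identical cohorts, genomes and expression.

## Numerical and testing choices

- Tumor VAF 0.3 at depth ~30 puts the Fisher specificity test in a
  moderate-power regime: detection probability of a planted somatic site
  is ≈ 0.66 (two-sided P < 0.01 needs roughly 8 alt reads at depth 30).
  The recovery test asserts agreement with an independent Monte Carlo of
  the count model rather than an arbitrary recovery target; germline
  leakage into the tumor-specific set is bounded at 1%.
- Exact conditional tests (Fisher, rank-sum) have discrete, conservative
  null P-value distributions; they are *super-uniform*, not uniform, so
  two-sided uniformity checks reject them by construction. The continuous
  t-test calibrations are uniform and tested as such.
- Oracle comparisons in the suite use hand-written hypergeometric tail
  sums, exhaustive rank-assignment enumeration (KS, rank-sum) and an
  O(n²) all-window scan, kept independent of the implementation paths.
  Fisher agreement is enumerated exhaustively for margins ≤ 15 and on
  2,000 random tables with margins ≤ 60 — sizes chosen to keep the full
  suite fast while covering the count regime the pipeline actually sees.
- Simulation-based tests fix their seeds and state their problem sizes
  (e.g. 200-seed recovery runs, 500-simulation calibrations) explicitly in
  the test bodies.

## Known limitations

- The ES pseudocount and the exact arrangement of the score are
  reconstructions (see above); other conventions would shift raw scores
  but not the rank-based subgroup comparisons.
- EASE background choice materially affects P-values; the platform gene
  count is a convention, not a universal truth.
- The window mask removes whole windows; sparse true mutations inside an
  artifact cluster are lost with it (accepted, matching the stringent
  design goal of minimizing false positives at the cost of sensitivity).
- P-values are reported raw throughout (matching the small-cohort,
  hypothesis-generating design); multiple-testing control is optional and
  off by default.
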