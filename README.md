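# exopair

Paired tumor/non-tumor exome variant-specificity analysis with expression
integration, for small matched cancer cohorts (the motivating setting is
hepatitis-B-related hepatocellular carcinoma profiled as ~12 tumor /
adjacent-liver pairs at ~30× exome coverage, split into early and advanced
histological grade groups).

Deep but error-prone exome sequencing of small tissue samples produces many
false variant calls, so the package implements a deliberately stringent
cascade that turns per-site paired read counts into *tumor-specific* and
*non-tumor-specific* (background) variant sets, then asks where those
variants sit in the genome and what they do to expression:

1. **Quality gate** — drop sites that are hard to validate
   (MQ0 ≥ 4 and MQ0/DP > 0.1), low coverage (DP < 5), low quality
   (QUAL < 50), or low quality-by-depth (QD < 1.5).
2. **Exonic depth** — keep CDS sites with ≥ 10 supporting reads in at
   least one tissue.
3. **Specificity** — two-sided Fisher exact test on the 2×2 table
   [[tumor_alt, tumor_ref], [normal_alt, normal_ref]]; a site is
   tumor-specific when *P* < 0.01 with odds ratio > 1, non-tumor-specific
   in the symmetric case.
4. **Germline** — sites with ≥ 5 variant-supporting reads in *both*
   tissues are constitutional (or non-specific calls) and removed.
5. **Hypermutable windows** — any 1,000-bp window holding > 10 variants is
   masked entirely (local mis-alignment artifacts; a binomial C>T
   diagnostic confirms the masked clusters are not kataegis).
6. **Known SNPs** — listed positions are removed.

Downstream analyses: the six-class strand-collapsed substitution spectrum
(C:G>T:A, C:G>A:T, C:G>G:C, T:A>C:G, T:A>A:T, T:A>G:C) with rank-sum
comparisons between the variant sets; per-arm mutation rates per 10 Mb and
Fisher arm-enrichment tests; the per-patient, per-arm **enrichment score**

    ES_ij = [(Nt_ij + c)/(Nt_-ij + c)] / [(Nn_ij + c)/(Nn_-ij + c)],  c = 0.5

which normalizes the tumor in-arm/out-of-arm odds by the patient's own
background odds (scores < 1 truncated to 0 for display only); EASE-score
(jackknifed one-sided Fisher) functional enrichment of mutated gene lists;
per-patient directional Kolmogorov–Smirnov enrichment of gene-set
expression, signed −log10(*P*); a pooled mutated-vs-wild-type expression
t-test; selection of gene sets whose per-patient scores differ between
grade subgroups (*P* < 0.05, > 2-fold); and an interaction-degree hub
summary over a user-supplied edge list.

Because cohorts like this are rarely depositable, the package ships a
first-class synthetic-data generator (`exopair.synthetic`) that reproduces
the statistical structure the analysis assumes — patient-variable burden,
a designated arm with a rate excess in the advanced subgroup, a
C:G>T:A-dominant spectrum with tumor-exclusive T:A>A:T, germline-shared
sites, hypermutable clusters, known-SNP contaminants, and expression with
down-shifted mutated genes — with ground truth in a sidecar the analysis
never reads.

## Worked example

```python
from exopair import SyntheticConfig, generate_all
from exopair.pipeline import run_pipeline
from exopair.arms import es_matrix, subgroup_es_comparison

bundle = generate_all(SyntheticConfig(seed=1))
result = run_pipeline(bundle.cohort.patients, bundle.genome,
                      bundle.cohort.snp_positions)
print(result.stage_counts["total"])
mats = es_matrix(result.tumor_specific, result.non_tumor_specific,
                 bundle.genome.arms)
comp = subgroup_es_comparison(mats.raw, bundle.cohort.grades)
print(comp.loc["1q"])
```

prints the per-stage site counts of the cascade

```
input           1376
quality         1142
exonic_depth    1142
fisher           721
germline         721
window           630
snp              601
```

(1,376 candidate sites fall to 601 classified variants: the quality gate
removes forced metric failures, the Fisher stage keeps only sites with
significant one-tissue excess, and the window mask absorbs the planted
clusters) and the designated arm's subgroup comparison

```
statistic        32.000000
pvalue            0.025974
mean_advanced     3.461639
mean_early        0.557808
contrast          2.903831
```

i.e. the factor-3 mutation-rate excess planted on arm 1q of the advanced
patients surfaces as a higher advanced-group enrichment score (rank-sum
*P* ≈ 0.026).

The same pipeline runs from the shell:

```sh
exopair run-all --seed 1 --out ws/       # simulate + every stage + summary.json
exopair simulate --seed 1 --out ws2/     # or stage by stage:
exopair filter --workspace ws2/
exopair spectrum --workspace ws2/
exopair arms --workspace ws2/
exopair enrich --workspace ws2/
```

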