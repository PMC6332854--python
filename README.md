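# hapgwas

Sliding-window haplotype GWAS for quantitative traits in livestock, built
around the analysis of Warner-Bratzler shear force (WBSF, kg — a mechanical
measure of beef tenderness) in genotyped cattle.

Single-SNP association tests only see variants typed on the array.  When the
causal variant is untyped, a *haplotype* of `w` consecutive SNPs can be in
much stronger linkage disequilibrium (LD) with it than any single SNP, so the
package scans the genome with overlapping sliding windows of `w ∈ {1, 3, 5,
7, 9, 11}` SNPs (step 1 SNP; `w = 1` is ordinary single-SNP GWAS), treating
every distinct haplotype string observed in the phased sample as an allele,
dosage-coded 0/1/2 per individual.

## Model and statistics

Phenotypes are pre-adjusted for contemporary-group fixed effects and a linear
age-at-slaughter covariate under an animal model, then each predictor is
tested with the linear mixed model

    y = 1μ + xβ + u + e,   u ~ MVN(0, G·V_g),   e ~ MVN(0, I·V_e)

where **G** is the genomic relationship matrix from standardized genotypes
(`G = WW'/m`, column `j` of `W` centered by `2p_j` and scaled by
`1/sqrt(2 p_j (1−p_j))`).  A single eigendecomposition of `G` turns REML into
a one-dimensional profile over `λ = V_g/V_e` and every window test into a
weighted least-squares fit (per-predictor variance ratios are reused from the
null model by default, re-estimated exactly on request).

The additive genetic variance of a locus is

* biallelic SNP: `σ² = 2p(1−p)a²`
* haplotype locus with k alleles: `σ² = Σ_{i<l} (a_i − a_l)² p_i p_l`,
  the frequency-weighted variance of the allele effects.

Genome-wide, the per-locus variances of one analysis are modelled as a
Gamma(shape α, rate β) sample.  Parameters come from the moment
(Newton-Raphson) approximation `α = (3 − s + sqrt((3−s)² + 24s))/(12s)` with
`s = ln(mean σ²) − mean(ln σ²)` and `β = α/mean σ²`; for haplotype loci they
are estimated per allele-count class and smoothed over the allele count
(cubic polynomial for α, Brody growth curve `A(1 − Be^{−κt})` for β).  A
locus is called significant when its variance reaches the gamma quantile at
probability `1 − 0.05/n_tests` (Bonferroni over the analysis's loci).
Significant windows from all analyses are merged by bp-span overlap into QTL
regions, classified by mean pairwise r² (S > 0.6, M > 0.2, W > 0.1, else N).

A founder-copying simulator (`hapgwas.sim`) generates phased panels with
tunable LD decay and phenotypes with the full fixed/random structure plus
planted QTL — including *untyped* causal variants tagged only by multi-SNP
haplotypes — so the whole pipeline is testable offline.

## Worked example

```python
from hapgwas.sim import headline_config, simulate_study
from hapgwas.pipeline import RunConfig, run_pipeline

geno, phen, truth = simulate_study(headline_config(6))
res = run_pipeline(geno, phen, RunConfig(window_sizes=(1, 3, 5)), qc=False)
print(res.regions_table.round(3).to_string(index=False))
```

prints (seed 6: 500 bulls, 2,000 SNPs, one untyped QTL at chr1:5,000,000):

```
chrom      first_id       last_id  start_bp  end_bp  span_bp  mean_r2 ld  SNP   SW3   SW5
    1 snp_1_4866554 snp_1_4977840   4866554 4977840   111286    0.273  M  NaN 0.298 0.291
```

One QTL region is called, spanning 111 kb around the planted causal position.
The `SW3`/`SW5` columns give the best additive variance (kg²) among the
region's significant 3- and 5-SNP windows; the `NaN` under `SNP` records that
no single SNP reached its threshold — the causal variant is not on the map,
and no typed SNP tags it well enough.  `ld = M` classifies the region's mean
pairwise r² (0.273) as moderate.

The same stages are available from a shell:

```
hapgwas simulate --seed 1 --out sim/
hapgwas run-all sim/genotypes.vcf sim/phenotypes.tsv --out results/
hapgwas verify-tables
```

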