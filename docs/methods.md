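# Methods

This note records the models, numerical choices and known limitations of
`hapgwas`.  It is written for users who want to know what the package
computes, what its synthetic data do and do not emulate, and where the
genuinely open design choices were resolved.

## Haplotype loci

Windows of `w` consecutive SNPs advance one SNP at a time and never span
chromosomes, so a chromosome with `n` SNPs yields `n − w + 1` windows.  A
window's alleles are the distinct haplotype strings observed in the phased
sample — exact string identity, no clustering — sorted by descending
frequency with lexicographic tie-break, and each individual's diplotype is
coded 0/1/2 per allele.  `w = 1` reproduces standard genotype coding exactly,
which unifies the single-SNP and haplotype analyses in one engine.

Rare-allele pooling: the pipeline's default (`RunConfig.pool_rare = True`)
merges alleles observed on fewer than 2 haplotype copies into one `"other"`
class before testing.  A near-private allele contributes effect-estimation
noise of order `V_P/(2n)` times a 1-df chi-square to the locus variance; at
n = 500 these heavy-tailed components measurably break the family-wise
calibration of the gamma thresholds (see below), and pooling them restores
it for the single-SNP and 5-SNP analyses.  The low-level
`enumerate_locus` keeps `pool_rare = False` so the unpooled statistic, with
its variance summed over *all* observed alleles, remains available;
calibration-sensitive work should leave pooling on.

## Mixed model

Pre-adjustment fits trait = intercept + contemporary-group classes + linear
age (centered) by REML/GLS under the animal model with the standardized-
genotype GRM as covariance; the adjusted trait is the raw trait minus the
fitted fixed part.  Contemporary groups need at least three records; constant
age degrades to mean-only adjustment; an age covariate collinear with the
groups is rejected with a diagnostic.

REML is a one-dimensional profile over `log λ`, `λ = V_g/V_e`, on
eigen-rotated data: a 49-point grid on [−12, 12] followed by bounded Brent
refinement.  A flat profile (e.g. `G = I`, where `V_g` and `V_e` are not
separately identifiable) or an optimum within one grid step of the bounds is
flagged as a boundary fit.  Small negative GRM eigenvalues from roundoff are
clipped at zero; the polygenic simulation adds 1e-6 jitter before Cholesky.

Per-predictor tests reuse the null-model λ (the population-parameters-
previously-determined approximation); `exact_lmm = True` re-estimates λ per
predictor.  Each haplotype allele is tested one-vs-rest.  The k dosage
columns of a locus sum to the constant 2, so a joint fit with an intercept is
singular — one-vs-rest is the estimable parametrization that yields an
effect for every allele, which the variance formula needs.  Multi-allelic
joint coding (k−1 columns) would need effects re-expressed against a
reference and is not the default.

## Variance and thresholds

The biallelic formula `2p(1−p)a²` and the pairwise haplotype formula
`Σ_{i<l}(a_i−a_l)² p_i p_l` are implemented as printed, including their known
inconsistency: at k = 2 the pairwise form equals *half* the biallelic form
applied to (p, a₁−a₂).  `variance_scale = "snp_consistent"` doubles the
pairwise form for users who want the two to coincide; the default
(`"as_printed"`) does not, and the thresholding is scale-invariant either
way because cutoffs are fitted to the same statistics.

The moment approximation for the gamma shape is
`α = (3 − s + sqrt((3−s)² + 24s))/(12s)`.  (The widely circulated variant
lacking the `+` before the square root is negative for typical `s` and
cannot be a shape parameter; the form used here is the standard
Newton-Raphson-derived approximation.)

Class fits and smoothing: haplotype-locus variances are grouped by allele
count k across *all* window sizes jointly (the class distribution depends on
k, not on which window size produced the locus); classes need ≥ 30 positive,
non-constant variances.  With ≥ 5 classes, α(k) is smoothed by a cubic
(ordinary least squares) and β(k) by the Brody curve `A(1 − Be^{−κt})`
(nonlinear least squares; start values A = max observed β,
B = 1 − β(k_min)/A, κ ∈ {0.1, 0.05, 0.5, 1.0} with restarts).  Allele counts
outside the fitted class range use the smoothed prediction clamped to the
range.  The single-SNP analysis uses one direct moment fit, no smoothing.
Zero variances (effect exactly 0) are excluded from fitting with a logged
count.  Cutoffs are inverse gamma CDFs at `1 − 0.05/n_tests` with `n_tests`
the genome-wide number of tested loci of that analysis; a locus is flagged
when `σ² ≥ cutoff` (boundary inclusive).

Calibration at small n: on no-genetics null simulations (500 individuals,
2,000 SNPs) the realized family-wise false-flag rate is nominal for the
single-SNP and SW5 analyses but runs above nominal for SW3 (about 4 runs in
20 instead of 1).  The cause is heterogeneity the class model cannot see:
within one allele-count class, windows with balanced allele frequencies
carry roughly twice the class-average noise scale, so a single per-class
gamma underestimates the extreme tail by ~10-15% in scale.  This is a
property of the class-wise gamma machinery itself, amplified at small n
where per-allele noise `V_P/(2n)` is several times larger than in a
~3,000-animal study; users applying the thresholds at small sample sizes
should treat borderline 3-SNP-window flags with caution.

## LD and regions

r² comes directly from phased haplotype frequencies,
`(p_AB − p_A p_B)²/(p_A(1−p_A)p_B(1−p_B))` — no genotype-EM estimator is
needed on phased data.  Decay curves bin all intra-chromosomal pairs within
`max_dist` (default 1 Mb, 10 kb bins), with seeded pair subsampling for
large panels; empty bins report a null mean.

Flagged windows merge transitively when their bp spans overlap or abut on
one chromosome; a flagged single SNP joins the region containing it or forms
a singleton region (span 0).  Region LD classes use the boundary convention
that r² = 0.6/0.2/0.1 fall to the weaker class, since the published class
intervals are open on both ends.  Detection summaries report both truncated
and rounded percentages: the published tallies for the same table mix the
two conventions (19/33 printed as 57 is truncation; 20/33 printed as 61 is
rounding), so neither alone reproduces all printed values.

## Synthetic cohort

The generator emulates the study population's structure: trait mean 5.9 kg,
SD 1.80 kg; slaughter age 691 ± 102 days (truncated at ±3 SD) with a linear
effect (default 0.002 kg/day); contemporary groups of ≥ 3 animals with
N(0, 0.5²) kg effects; a polygenic background drawn with covariance
proportional to the realized GRM at h² = 0.12 (WBSF heritability in indicine
cattle is low, ~0.1); and planted QTL.  The residual is scaled so trait
variance net of group structure is ≈ (1.80 kg)².

Haplotypes come from a founder-copying process: each sample haplotype copies
segments from 50 founder templates, switching templates between adjacent
SNPs with probability `1 − exp(−switch_rate·gap)`.  Founders are *mutually
correlated* — each founder carries a latent ancestry coordinate shared along
the chromosome, the allele at a site of target frequency q is an exact
rank-threshold (round(qK) carriers), and 1% per-site mutation noise is
added.  Independent founder sites would cap r² near 1/K at all distances;
the gradient construction instead gives short-range mean r² ≈ 0.25-0.4
decaying below 0.15 beyond 100 kb with `switch_rate = 5e-6`/bp (frozen after
tuning once against that target).  Typed-site target frequencies are drawn
U(0.2, 0.8), mimicking array ascertainment of common variants.

Causal QTL sites are *clade* alleles: carried by an interior interval of the
ancestry order (a younger mutation on an internal branch), placed inside the
array-visible frequency range.  A single threshold-like array SNP cannot
represent an interval indicator, but the intersection of two flanking
threshold SNPs — i.e. a local haplotype — can.  This is the concrete
mechanism by which `untyped_tagged` QTL (whose causal column is simulated,
used for the phenotype, then dropped from the emitted map) are recoverable
by sliding-window haplotypes yet nearly invisible to single-SNP tests.

`headline_config` plants one untyped QTL of ≈ 0.29 kg² (effect 1.1 kg,
frequency ≈ 0.15).  The gamma cutoff scales like `k·V_P/(2n)`, so at n = 500
it sits ~6× higher on the variance scale (≈ 0.17 kg²) than in a
~3,000-animal cohort (≈ 0.03 kg²); the headline QTL therefore preserves the
full-scale study's signal-to-threshold ratio (≈ 2×) rather than its absolute
variance, which no analysis could flag at this sample size.  The default
panel (`default_qtl_panel`) instead keeps per-QTL variances in the 0.03-0.10
kg² range typical of reported tenderness QTL.

What the simulator does *not* emulate: genotyping and imputation error,
pedigree/family structure beyond the founder mosaic, multi-generation
selection, dominance or epistasis, variable recombination (the switch rate
is uniform per bp), and a realistic site-frequency spectrum for untyped
variation.  Passing tests on this cohort show the pipeline's statistics
behave as designed under a known truth, not that the power or calibration
figures transfer to any particular real population.

On a desk-scale genome (2 × 10 Mb), a GRM-consistent polygenic background
has few effective dimensions and genuinely concentrates ~0.1-0.2 kg² of
additive variance on single loci; calibration checks therefore use h² = 0
traits, where "no flag" is the correct answer everywhere.

## Problem sizes

Simulated studies default to 500 individuals and 2 × 1,000 SNPs over 10 Mb
chromosomes; power and calibration properties are assessed over 20 seeded
replicates, and heritability recovery uses 500 individuals × 5,000 markers.
These sizes keep a full multi-window scan to a few seconds per replicate
while leaving every stage's statistical behavior measurable.
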