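"""End-to-end sliding-window haplotype GWAS pipeline.

Stages: QC -> GRM -> phenotype pre-adjustment -> per-window-size association
(single SNPs are the w = 1 case of the same engine) -> per-locus additive
variance -> gamma thresholds (Bonferroni over the loci of each analysis) ->
significant-locus flags -> QTL-region merging with LD classification ->
LD-decay summary.  The same GRM is used for the single-SNP and all
haplotype analyses.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hapgwas.genotypes import PhasedGenotypes, apply_qc, QCReport
from hapgwas.ld import DecayCurve, QTLRegion, decay_curve, merge_regions, regions_bed, regions_frame
from hapgwas.mixed_model import GRM, NullModelFit, compute_grm, fit_null, preadjust_phenotype, test_predictors
from hapgwas.variance import (
    GammaClassFit,
    SmoothedParams,
    fit_gamma_classes,
    fit_gamma_mom,
    gamma_threshold,
    haplotype_variance,
    smooth_params,
    snp_variance,
)
from hapgwas.windows import build_windows, iter_loci

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Pipeline options; loadable from a YAML mapping."""

    window_sizes: tuple[int, ...] = (1, 3, 5, 7, 9, 11)
    sample_cr: float = 0.90
    marker_cr: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 1e-5
    exact_lmm: bool = False          # per-predictor REML instead of null-model lambda
    variance_scale: str = "as_printed"  # or "snp_consistent"
    pool_rare: bool = True           # pool haplotype alleles seen on < 2 copies
    family_alpha: float = 0.05
    min_loci_per_class: int = 30
    smooth_gamma: bool = True        # smooth (alpha, beta) over allele-count classes
    ld_max_dist: int = 1_000_000
    ld_bin_width: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 1 or w % 2 == 0 for w in self.window_sizes):
            raise ValueError("window sizes must be odd and >= 1")
        if not 0.0 < self.family_alpha < 1.0:
            raise ValueError("family_alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "window_sizes" in raw:
            raw["window_sizes"] = tuple(raw["window_sizes"])
        return cls(**raw)


def analysis_label(w: int) -> str:
    return "SNP" if w == 1 else f"SW{w}"


def association_scan(geno: PhasedGenotypes, null: NullModelFit, w: int,
                     variance_scale: str = "as_printed", exact: bool = False,
                     pool_rare: bool = False,
                     chunk: int = 4096) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every window of size ``w``: per-allele effects and per-locus variance.

    Returns (locus table, allele table).  Each haplotype allele is tested as
    its own 0/1/2 one-vs-rest dosage predictor; the locus variance combines
    the k per-allele effects and frequencies.  For w = 1 the biallelic SNP
    formula is applied to the alt allele.  Monomorphic loci (k = 1) are
    reported with variance 0 and no test.
    """
    windows = build_windows(geno, w)
    loci = list(iter_loci(geno, windows, pool_rare=pool_rare))

    cols: list[np.ndarray] = []
    owner: list[tuple[int, int]] = []  # (locus index, allele index)
    for li, locus in enumerate(loci):
        if locus.k == 1:
            continue
        if w == 1:
            ai = locus.alleles.index("1")
            cols.append(locus.dosage[:, ai])
            owner.append((li, ai))
        else:
            for ai in range(locus.k):
                cols.append(locus.dosage[:, ai])
                owner.append((li, ai))

    eff = np.full(len(cols), np.nan)
    se = np.full(len(cols), np.nan)
    pv = np.full(len(cols), np.nan)
    for lo in range(0, len(cols), chunk):
        hi = min(lo + chunk, len(cols))
        X = np.column_stack(cols[lo:hi]).astype(float)
        e, s, p = test_predictors(X, null, exact=exact)
        eff[lo:hi], se[lo:hi], pv[lo:hi] = e, s, p

    allele_rows = []
    per_locus_eff: dict[int, dict[int, float]] = {}
    for (li, ai), e, s, p in zip(owner, eff, se, pv):
        locus = loci[li]
        wd = locus.window
        allele_rows.append((wd.chrom, li, wd.first_id, wd.last_id, wd.start_bp, wd.end_bp,
                            locus.k, locus.alleles[ai], locus.freqs[ai], e, s, p))
        per_locus_eff.setdefault(li, {})[ai] = e

    locus_rows = []
    for li, locus in enumerate(loci):
        wd = locus.window
        if locus.k == 1:
            sigma2 = 0.0
        elif w == 1:
            ai = locus.alleles.index("1")
            e = per_locus_eff[li][ai]
            sigma2 = np.nan if np.isnan(e) else snp_variance(locus.freqs[ai], e)
        else:
            effs = np.array([per_locus_eff[li][ai] for ai in range(locus.k)])
            if np.isnan(effs).any():
                sigma2 = np.nan
            else:
                sigma2 = haplotype_variance(locus.freqs, effs, scale=variance_scale)
        locus_rows.append((wd.chrom, li, wd.first_id, wd.last_id, wd.start_bp, wd.end_bp,
                           locus.k, sigma2))

    locus_df = pd.DataFrame(locus_rows, columns=["chrom", "window", "first_id", "last_id",
                                                 "start_bp", "end_bp", "k", "sigma2"])
    allele_df = pd.DataFrame(allele_rows, columns=["chrom", "window", "first_id", "last_id",
                                                   "start_bp", "end_bp", "k", "allele", "freq",
                                                   "effect", "se", "pvalue"])
    return locus_df, allele_df


def snp_thresholds(locus_df: pd.DataFrame, family_alpha: float = 0.05) -> pd.DataFrame:
    """Single-cutoff threshold table for the single-SNP analysis.

    Bonferroni n_tests is the genome-wide number of tested (polymorphic,
    finite-variance) SNPs; the gamma fit uses the direct moment
    approximation with no allele-count smoothing.
    """
    ok = locus_df["sigma2"].notna() & (locus_df["sigma2"] > 0)
    n_tests = int(ok.sum())
    if n_tests == 0:
        raise ValueError("no testable loci: cannot set thresholds")
    fit = fit_gamma_mom(locus_df.loc[ok, "sigma2"].to_numpy(), k=2)
    cut = gamma_threshold(fit.alpha, fit.beta, n_tests, family_alpha)
    return pd.DataFrame([("SNP", 2, fit.alpha, fit.beta, cut)],
                        columns=["analysis", "k", "alpha", "beta", "cutoff"])


def hap_thresholds(locus_dfs: dict[int, pd.DataFrame], family_alpha: float = 0.05,
                   min_loci: int = 30, smooth: bool = True) -> pd.DataFrame:
    """Per-allele-count cutoffs for the haplotype analyses.

    Gamma class parameters are estimated per allele count k on the loci of
    ALL window sizes pooled (the class distribution depends on k, not on
    the window size that produced the locus), then smoothed over k — cubic
    for the shape, Brody for the rate — when enough classes exist.  The
    Bonferroni n_tests is per analysis: the genome-wide number of tested
    loci of that window size.  Allele counts outside the fitted class range
    use the smoothed prediction clamped to the range (or the nearest fitted
    class when smoothing is unavailable).
    """
    pooled_sig = np.concatenate([
        df.loc[df["sigma2"].notna() & (df["sigma2"] > 0), "sigma2"].to_numpy()
        for df in locus_dfs.values()
    ])
    pooled_k = np.concatenate([
        df.loc[df["sigma2"].notna() & (df["sigma2"] > 0), "k"].to_numpy()
        for df in locus_dfs.values()
    ])
    if pooled_sig.size == 0:
        raise ValueError("no testable haplotype loci: cannot set thresholds")
    fits = fit_gamma_classes(pooled_sig, pooled_k, min_loci=min_loci)
    if not fits:
        raise ValueError("no allele-count class has enough loci for a gamma fit")
    sm: SmoothedParams | None = None
    if smooth and len(fits) >= 5:
        sm = smooth_params(fits)
    fitted_ks = np.array(sorted(fits))
    rows = []
    for w, df in locus_dfs.items():
        ok = df["sigma2"].notna() & (df["sigma2"] > 0)
        n_tests = int(ok.sum())
        for k in sorted(df.loc[df["sigma2"].notna(), "k"].unique()):
            if k < 2:
                continue
            if sm is not None:
                kk = float(np.clip(k, *sm.k_range))
                a, b = float(sm.alpha(kk)), float(sm.beta(kk))
            elif k in fits:
                a, b = fits[k].alpha, fits[k].beta
            else:
                f = fits[int(fitted_ks[np.argmin(np.abs(fitted_ks - k))])]
                a, b = f.alpha, f.beta
            rows.append((analysis_label(w), k, a, b,
                         gamma_threshold(a, b, n_tests, family_alpha)))
    return pd.DataFrame(rows, columns=["analysis", "k", "alpha", "beta", "cutoff"])


@dataclasses.dataclass
class PipelineResult:
    qc_report: QCReport | None
    grm: GRM
    null: NullModelFit
    locus_tables: dict[str, pd.DataFrame]    # per analysis, with cutoff + flagged
    allele_tables: dict[str, pd.DataFrame]
    thresholds: pd.DataFrame
    regions: list[QTLRegion]
    regions_table: pd.DataFrame
    decay: DecayCurve


def run_pipeline(geno: PhasedGenotypes, phenotypes: pd.DataFrame, config: RunConfig,
                 outdir: str | Path | None = None, qc: bool = True) -> PipelineResult:
    """Run every stage on a phased panel and phenotype table.

    ``phenotypes`` needs columns ``id, wbsf_kg, cg, age_days`` (ids matching
    the panel's samples).  With ``outdir`` set, every stage's output is
    written as TSV.
    """
    report = None
    if qc:
        geno, report = apply_qc(geno, config.sample_cr, config.marker_cr,
                                config.maf_min, config.hwe_p_min)
    phen = phenotypes.set_index("id").loc[geno.samples].reset_index()

    logger.info("stage grm: %d samples x %d markers", geno.n_samples, geno.n_variants)
    grm = compute_grm(geno)
    y_adj, fixed = preadjust_phenotype(phen["wbsf_kg"].to_numpy(), phen["cg"].to_numpy(),
                                       phen["age_days"].to_numpy(), grm)
    null = fit_null(y_adj, grm)
    logger.info("null fit: Vg=%.4f Ve=%.4f lambda=%.4f", null.vg, null.ve, null.lam)

    locus_tables: dict[str, pd.DataFrame] = {}
    allele_tables: dict[str, pd.DataFrame] = {}
    hap_locus_by_w: dict[int, pd.DataFrame] = {}
    for w in config.window_sizes:
        label = analysis_label(w)
        locus_df, allele_df = association_scan(geno, null, w, config.variance_scale,
                                               exact=config.exact_lmm,
                                               pool_rare=config.pool_rare)
        locus_tables[label] = locus_df
        allele_tables[label] = allele_df
        if w > 1:
            hap_locus_by_w[w] = locus_df

    thr_frames = []
    if 1 in config.window_sizes:
        thr_frames.append(snp_thresholds(locus_tables["SNP"], config.family_alpha))
    if hap_locus_by_w:
        thr_frames.append(hap_thresholds(hap_locus_by_w, config.family_alpha,
                                         config.min_loci_per_class, config.smooth_gamma))
    thresholds = pd.concat(thr_frames, ignore_index=True)

    flagged_frames = []
    for w in config.window_sizes:
        label = analysis_label(w)
        locus_df = locus_tables[label]
        cut = thresholds[thresholds["analysis"] == label].set_index("k")["cutoff"]
        locus_df["cutoff"] = locus_df["k"].map(cut)
        locus_df["flagged"] = locus_df["sigma2"] >= locus_df["cutoff"]
        fl = locus_df[locus_df["flagged"] == True].copy()  # noqa: E712
        fl["analysis"] = label
        flagged_frames.append(fl[["chrom", "start_bp", "end_bp", "first_id", "last_id",
                                  "analysis", "sigma2"]])
        logger.info("analysis %s: %d loci, %d flagged", label, len(locus_df), len(fl))
    flagged = pd.concat(flagged_frames, ignore_index=True)
    regions = merge_regions(flagged, geno=geno)
    analyses = [analysis_label(w) for w in config.window_sizes]
    regions_table = regions_frame(regions, analyses)
    decay = decay_curve(geno, config.ld_max_dist, config.ld_bin_width, seed=config.seed)

    result = PipelineResult(report, grm, null, locus_tables, allele_tables,
                            thresholds, regions, regions_table, decay)
    if outdir is not None:
        _persist(result, geno, Path(outdir))
    return result


def _persist(result: PipelineResult, geno: PhasedGenotypes, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if result.qc_report is not None:
        result.qc_report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    np.savetxt(outdir / "grm.txt", result.grm.matrix, fmt="%.8g")
    (outdir / "grm_samples.txt").write_text("\n".join(result.grm.samples) + "\n")
    for label, df in result.locus_tables.items():
        df.to_csv(outdir / f"assoc_{label}.tsv", sep="\t", index=False)
    for label, df in result.allele_tables.items():
        df.to_csv(outdir / f"alleles_{label}.tsv", sep="\t", index=False)
    result.thresholds.to_csv(outdir / "thresholds.tsv", sep="\t", index=False)
    result.regions_table.to_csv(outdir / "regions.tsv", sep="\t", index=False)
    regions_bed(result.regions).to_csv(outdir / "regions.bed", sep="\t", index=False, header=False)
    result.decay.to_frame().to_csv(outdir / "ld_decay.tsv", sep="\t", index=False)
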