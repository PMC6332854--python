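"""Phased genotype container, phased-VCF I/O, and SNP-array style QC.

Genotypes are stored as a haplotype matrix of 0/1 allele codes (missing = -1)
with two rows per sample: haplotype rows ``2i`` and ``2i+1`` belong to sample
``i``.  Input is assumed to be phased, imputed, autosomal and biallelic, as
produced by array genotyping followed by imputation/phasing.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = -1

#: Chromosome labels accepted as autosomes by default: plain integers,
#: optionally "chr"-prefixed (cattle autosomes are 1..29, but the container
#: is not species-specific).
def _is_autosome_label(chrom: str) -> bool:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return c.isdigit()


@dataclasses.dataclass
class PhasedGenotypes:
    """Sample-indexed phased haplotype matrix with a variant map.

    Attributes
    ----------
    samples : list of str
        Ordered sample ids.
    variants : pandas.DataFrame
        One row per variant with columns ``chrom, pos, id, ref, alt``;
        ``pos`` is 1-based and strictly increasing within a chromosome.
    hap : numpy.ndarray of int8, shape (2 * n_samples, n_variants)
        Allele codes 0/1 with -1 for missing.
    """

    samples: list[str]
    variants: pd.DataFrame
    hap: np.ndarray

    def __post_init__(self) -> None:
        self.hap = np.asarray(self.hap, dtype=np.int8)
        if self.hap.shape != (2 * len(self.samples), len(self.variants)):
            raise ValueError(
                f"haplotype matrix shape {self.hap.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.hap, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele codes must be 0, 1 or -1 (missing)")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def genotype_matrix(self) -> np.ndarray:
        """0/1/2 alt-allele dosage per sample (float; NaN where missing)."""
        a = self.hap[0::2].astype(float)
        b = self.hap[1::2].astype(float)
        a[a == MISSING] = np.nan
        b[b == MISSING] = np.nan
        return a + b

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant, missing alleles excluded."""
        ok = self.hap != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(ok, self.hap, 0).sum(axis=0) / ok.sum(axis=0)

    def take_samples(self, idx: np.ndarray) -> "PhasedGenotypes":
        idx = np.asarray(idx)
        hap_rows = np.empty(2 * len(idx), dtype=int)
        hap_rows[0::2] = 2 * idx
        hap_rows[1::2] = 2 * idx + 1
        return PhasedGenotypes(
            [self.samples[i] for i in idx], self.variants.reset_index(drop=True), self.hap[hap_rows]
        )

    def take_variants(self, idx: np.ndarray) -> "PhasedGenotypes":
        idx = np.asarray(idx)
        return PhasedGenotypes(
            list(self.samples), self.variants.iloc[idx].reset_index(drop=True), self.hap[:, idx]
        )


@dataclasses.dataclass
class QCReport:
    """Per-filter removal counts, in application order."""

    n_samples_in: int
    n_markers_in: int
    samples_removed_call_rate: int
    markers_removed_nonautosomal: int
    markers_removed_call_rate: int
    markers_removed_maf: int
    markers_removed_hwe: int
    thresholds: dict

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.samples_removed_call_rate

    @property
    def n_markers_out(self) -> int:
        return self.n_markers_in - (
            self.markers_removed_nonautosomal
            + self.markers_removed_call_rate
            + self.markers_removed_maf
            + self.markers_removed_hwe
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("samples_in", self.n_samples_in),
            ("samples_removed_call_rate", self.samples_removed_call_rate),
            ("samples_out", self.n_samples_out),
            ("markers_in", self.n_markers_in),
            ("markers_removed_nonautosomal", self.markers_removed_nonautosomal),
            ("markers_removed_call_rate", self.markers_removed_call_rate),
            ("markers_removed_maf", self.markers_removed_maf),
            ("markers_removed_hwe", self.markers_removed_hwe),
            ("markers_out", self.n_markers_out),
        ]
        return pd.DataFrame(rows, columns=["item", "count"])


def read_phased_vcf(path: str | Path) -> PhasedGenotypes:
    """Read a phased VCF into a :class:`PhasedGenotypes`.

    Every non-missing GT must be phased (``|`` separator); an unphased
    genotype raises with the offending sample and position.  Only biallelic
    SNP records are supported.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    haps = []
    errors = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS} — only biallelic SNPs supported"
            )
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise ValueError(f"non-SNP alleles at {var.CHROM}:{var.POS} ({var.REF}>{var.ALT[0]})")
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, (a, b, phased) in enumerate(g[:3] for g in var.genotypes):
            if a >= 0 and b >= 0 and not phased:
                errors.append(f"sample {samples[i]} at {var.CHROM}:{var.POS}")
            col[2 * i] = a if a >= 0 else MISSING
            col[2 * i + 1] = b if b >= 0 else MISSING
        haps.append(col)
        rows.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}", var.REF, var.ALT[0]))
    if errors:
        shown = "; ".join(errors[:10])
        raise ValueError(f"unphased genotypes in {path} ({len(errors)} records): {shown}")
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    hap = np.column_stack(haps) if haps else np.empty((2 * len(samples), 0), dtype=np.int8)
    return PhasedGenotypes(samples, variants, hap)


def write_phased_vcf(geno: PhasedGenotypes, path: str | Path) -> None:
    """Write a minimal phased VCFv4.2 (GT field only)."""
    sym = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hapgwas\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in geno.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.samples) + "\n")
        a = geno.hap[0::2]
        b = geno.hap[1::2]
        for j, v in enumerate(geno.variants.itertuples(index=False)):
            gts = "\t".join(f"{sym[int(a[i, j])]}|{sym[int(b[i, j])]}" for i in range(geno.n_samples))
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def hwe_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """1-df chi-square Hardy-Weinberg test from genotype counts."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def apply_qc(
    geno: PhasedGenotypes,
    sample_cr: float = 0.90,
    marker_cr: float = 0.95,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-5,
    autosomes_only: bool = True,
) -> tuple[PhasedGenotypes, QCReport]:
    """Apply array-QC filters in the standard order.

    Samples with genotype call rate below ``sample_cr`` are removed first.
    Marker statistics (call rate, minor allele frequency, Hardy-Weinberg)
    are then computed on the retained samples; markers are removed when
    call rate < ``marker_cr``, MAF < ``maf_min`` (strict: a marker at the
    boundary is kept) or HWE p-value < ``hwe_p_min``.  With
    ``autosomes_only``, markers whose chromosome label is not an autosome
    are removed before the marker-statistic filters.
    """
    if geno.n_variants == 0 or geno.n_samples == 0:
        raise ValueError("empty genotype matrix")
    thresholds = dict(
        sample_cr=sample_cr, marker_cr=marker_cr, maf_min=maf_min, hwe_p_min=hwe_p_min,
        autosomes_only=autosomes_only,
    )

    gt = geno.genotype_matrix()  # NaN = missing genotype
    sample_call = 1.0 - np.isnan(gt).mean(axis=1)
    keep_s = np.flatnonzero(sample_call >= sample_cr)
    n_s_removed = geno.n_samples - len(keep_s)
    if len(keep_s) == 0:
        raise ValueError("all samples removed by call-rate filter")
    g = geno.take_samples(keep_s)

    chrom_ok = g.variants["chrom"].astype(str).map(_is_autosome_label).to_numpy()
    if not autosomes_only:
        chrom_ok = np.ones(g.n_variants, dtype=bool)
    n_nonauto = int((~chrom_ok).sum())

    gt = g.genotype_matrix()
    marker_call = 1.0 - np.isnan(gt).mean(axis=0)
    freq = g.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = np.ones(g.n_variants)
    for j in range(g.n_variants):
        col = gt[:, j]
        col = col[~np.isnan(col)]
        hwe_p[j] = hwe_pvalue(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))

    fail_cr = chrom_ok & (marker_call < marker_cr)
    fail_maf = chrom_ok & ~fail_cr & (maf < maf_min)
    fail_hwe = chrom_ok & ~fail_cr & ~fail_maf & (hwe_p < hwe_p_min)
    keep_m = chrom_ok & ~fail_cr & ~fail_maf & ~fail_hwe
    if not keep_m.any():
        raise ValueError("all markers removed by QC filters")

    out = g.take_variants(np.flatnonzero(keep_m))
    report = QCReport(
        n_samples_in=geno.n_samples,
        n_markers_in=geno.n_variants,
        samples_removed_call_rate=n_s_removed,
        markers_removed_nonautosomal=n_nonauto,
        markers_removed_call_rate=int(fail_cr.sum()),
        markers_removed_maf=int(fail_maf.sum()),
        markers_removed_hwe=int(fail_hwe.sum()),
        thresholds=thresholds,
    )
    logger.info(
        "QC: %d/%d samples, %d/%d markers retained",
        report.n_samples_out, report.n_samples_in, report.n_markers_out, report.n_markers_in,
    )
    return out, report
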