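"""Overlapping sliding windows of consecutive SNPs and haplotype-allele dosage coding.

A window of ``w`` consecutive SNPs on one chromosome defines a haplotype
locus: the distinct haplotype strings observed in the sample are its alleles,
and each individual's diplotype is dosage-coded 0/1/2 per allele (0 = no
copies, 1 = one copy, 2 = two copies).  Windows advance one SNP at a time, so
a chromosome with n SNPs yields n - w + 1 windows; ``w = 1`` degenerates to
single-SNP analysis with standard 0/1/2 genotype coding.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterator

import numpy as np
import pandas as pd

from hapgwas.genotypes import MISSING, PhasedGenotypes

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class Window:
    chrom: str
    first: int  # column index into the variant map, inclusive
    last: int   # inclusive
    start_bp: int
    end_bp: int
    first_id: str
    last_id: str

    @property
    def w(self) -> int:
        return self.last - self.first + 1


@dataclasses.dataclass
class WindowSet:
    """All sliding windows of one size, never spanning chromosomes."""

    w: int
    windows: list[Window]

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[Window]:
        return iter(self.windows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(wd.chrom, wd.first, wd.last, wd.start_bp, wd.end_bp, wd.first_id, wd.last_id)
             for wd in self.windows],
            columns=["chrom", "first", "last", "start_bp", "end_bp", "first_id", "last_id"],
        )


@dataclasses.dataclass
class HaplotypeLocus:
    """One haplotype locus: distinct alleles, frequencies and dosage codes.

    ``alleles`` are haplotype strings over {0,1}^w sorted by descending
    frequency (ties broken lexicographically); ``dosage`` is an
    (n_samples, k) integer matrix whose rows sum to 2.
    """

    window: Window
    alleles: list[str]
    freqs: np.ndarray
    dosage: np.ndarray

    @property
    def k(self) -> int:
        return len(self.alleles)


def build_windows(geno: PhasedGenotypes, w: int) -> WindowSet:
    """Enumerate all windows of ``w`` consecutive SNPs per chromosome, step 1."""
    if w < 1:
        raise ValueError(f"window size must be >= 1, got {w}")
    windows: list[Window] = []
    var = geno.variants
    pos = var["pos"].to_numpy()
    ids = var["id"].to_numpy()
    for chrom, grp in var.groupby("chrom", sort=False):
        lo, hi = grp.index[0], grp.index[-1]
        n = hi - lo + 1
        if n < w:
            logger.warning("chromosome %s has %d SNPs < window size %d: no windows", chrom, n, w)
            continue
        for i in range(lo, hi - w + 2):
            j = i + w - 1
            windows.append(Window(str(chrom), i, j, int(pos[i]), int(pos[j]), str(ids[i]), str(ids[j])))
    return WindowSet(w=w, windows=windows)


def _pack_window(hap: np.ndarray) -> np.ndarray:
    """Pack a (2n, w) 0/1 slice into integer codes; missing alleles raise upstream."""
    w = hap.shape[1]
    weights = (1 << np.arange(w - 1, -1, -1)).astype(np.int64)
    return hap.astype(np.int64) @ weights


def enumerate_locus(geno: PhasedGenotypes, window: Window,
                    pool_rare: bool = False, min_copies: int = 2) -> HaplotypeLocus:
    """Enumerate the haplotype alleles of one window and dosage-code diplotypes.

    Requires complete (post-imputation) phased data inside the window;
    a missing allele raises, naming the sample and window.  With
    ``pool_rare``, alleles observed on fewer than ``min_copies`` haplotype
    copies are merged into a single ``"other"`` class (their dosages and
    frequencies add); without it every distinct haplotype string is its own
    allele.  Pooling bounds the estimation noise that near-private alleles
    feed into the locus variance.
    """
    slab = geno.hap[:, window.first : window.last + 1]
    miss = np.flatnonzero((slab == MISSING).any(axis=1))
    if miss.size:
        sample = geno.samples[miss[0] // 2]
        raise ValueError(
            f"missing allele for sample {sample} in window "
            f"{window.chrom}:{window.start_bp}-{window.end_bp}"
        )
    w = window.w
    codes = _pack_window(slab)
    uniq, inv, counts = np.unique(codes, return_inverse=True, return_counts=True)
    strings = np.array([format(int(c), f"0{w}b") for c in uniq], dtype=object)
    if pool_rare and (counts < min_copies).any() and (counts < min_copies).sum() > 1:
        rare = counts < min_copies
        keep_idx = np.flatnonzero(~rare)
        remap = np.full(len(uniq), len(keep_idx))
        remap[keep_idx] = np.arange(len(keep_idx))
        inv = remap[inv]
        counts = np.append(counts[keep_idx], counts[rare].sum())
        strings = np.append(strings[keep_idx], "other")
    freqs = counts / codes.size
    # descending frequency, ties lexicographic on the haplotype string
    order = np.lexsort((strings.astype(str), -freqs))
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    k = len(counts)
    n = geno.n_samples
    dosage = np.zeros((n, k), dtype=np.int16)
    alle = rank[inv]  # allele rank per haplotype row
    np.add.at(dosage, (np.repeat(np.arange(n), 2), alle.reshape(n, 2).ravel()), 1)
    return HaplotypeLocus(
        window=window,
        alleles=[str(s) for s in strings[order]],
        freqs=freqs[order],
        dosage=dosage,
    )


def iter_loci(geno: PhasedGenotypes, windows: WindowSet,
              pool_rare: bool = False) -> Iterator[HaplotypeLocus]:
    """Lazily enumerate every window's haplotype locus."""
    for wd in windows:
        yield enumerate_locus(geno, wd, pool_rare=pool_rare)


def locus_table(geno: PhasedGenotypes, windows: WindowSet) -> pd.DataFrame:
    """Flat per-allele table for all loci (one row per haplotype allele)."""
    rows = []
    for idx, locus in enumerate(iter_loci(geno, windows)):
        wd = locus.window
        for allele, p in zip(locus.alleles, locus.freqs):
            rows.append((wd.chrom, idx, wd.first_id, wd.last_id, wd.start_bp, wd.end_bp,
                         locus.k, allele, p))
    return pd.DataFrame(
        rows,
        columns=["chrom", "window", "first_id", "last_id", "start_bp", "end_bp", "k", "allele", "freq"],
    )
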