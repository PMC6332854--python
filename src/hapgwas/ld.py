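"""Pairwise LD (r^2), decay-by-distance summaries, and QTL-region calling.

r^2 is computed directly from phased haplotype frequencies:

    r^2 = (p_AB - p_A p_B)^2 / (p_A (1 - p_A) p_B (1 - p_B))

Significant windows from all analyses are merged transitively by bp-span
overlap into QTL regions, and each region is classified by the mean pairwise
r^2 of its markers: S (strong) for r^2 > 0.6, M (moderate) for
0.2 < r^2 <= 0.6, W (weak) for 0.1 < r^2 <= 0.2, N otherwise — boundary
values go to the weaker class.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from hapgwas.genotypes import PhasedGenotypes


def ld_class(r2: float) -> str:
    """S/M/W/N label for a mean pairwise r^2; boundaries to the weaker class."""
    if not np.isfinite(r2):
        return "N"
    if r2 > 0.6:
        return "S"
    if r2 > 0.2:
        return "M"
    if r2 > 0.1:
        return "W"
    return "N"


def _r2_from_cols(a: np.ndarray, b: np.ndarray) -> float:
    pa = a.mean()
    pb = b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic marker: r^2 undefined")
    pab = (a * b).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def pairwise_r2(geno: PhasedGenotypes, i: int, j: int) -> float:
    """r^2 between markers ``i`` and ``j`` from phased haplotype counts."""
    a = geno.hap[:, i].astype(float)
    b = geno.hap[:, j].astype(float)
    return _r2_from_cols(a, b)


def mean_pairwise_r2(geno: PhasedGenotypes, idx: np.ndarray) -> float:
    """Mean r^2 over all marker pairs in ``idx`` (NaN for < 2 markers)."""
    idx = np.asarray(idx)
    if idx.size < 2:
        return float("nan")
    H = geno.hap[:, idx].astype(float)
    vals = [_r2_from_cols(H[:, a], H[:, b]) for a, b in itertools.combinations(range(idx.size), 2)]
    return float(np.mean(vals))


@dataclasses.dataclass
class DecayCurve:
    """Binned mean r^2 by pairwise distance."""

    bin_start: np.ndarray  # bp, inclusive
    bin_end: np.ndarray    # bp, exclusive
    mean_r2: np.ndarray    # NaN where a bin holds no pairs
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": self.bin_start, "bin_end": self.bin_end,
            "mean_r2": self.mean_r2, "n_pairs": self.n_pairs,
        })


def decay_curve(geno: PhasedGenotypes, max_dist: int = 1_000_000, bin_width: int = 10_000,
                max_pairs_per_chrom: int | None = None, seed: int = 0) -> DecayCurve:
    """Mean r^2 per distance bin over all intra-chromosomal pairs within max_dist.

    For large panels ``max_pairs_per_chrom`` subsamples pairs (seeded).
    """
    edges = np.arange(0, max_dist + bin_width, bin_width)
    nb = len(edges) - 1
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=int)
    rng = np.random.default_rng(seed)
    H = geno.hap.astype(float)
    pos_all = geno.variants["pos"].to_numpy()
    for _, grp in geno.variants.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        if cols.size < 2:
            continue
        pos = pos_all[cols]
        ii, jj = [], []
        for a in range(cols.size - 1):
            upper = np.searchsorted(pos, pos[a] + max_dist, side="right")
            for b in range(a + 1, upper):
                ii.append(a)
                jj.append(b)
        ii = np.array(ii)
        jj = np.array(jj)
        if max_pairs_per_chrom is not None and ii.size > max_pairs_per_chrom:
            pick = rng.choice(ii.size, size=max_pairs_per_chrom, replace=False)
            ii, jj = ii[pick], jj[pick]
        sub = H[:, cols]
        p = sub.mean(axis=0)
        keep = (p[ii] > 0) & (p[ii] < 1) & (p[jj] > 0) & (p[jj] < 1)
        ii, jj = ii[keep], jj[keep]
        pab = np.einsum("ki,ki->i", sub[:, ii], sub[:, jj]) / sub.shape[0]
        d = pab - p[ii] * p[jj]
        r2 = d**2 / (p[ii] * (1 - p[ii]) * p[jj] * (1 - p[jj]))
        dist = pos[jj] - pos[ii]
        which = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, nb - 1)
        np.add.at(sums, which, r2)
        np.add.at(counts, which, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DecayCurve(bin_start=edges[:-1], bin_end=edges[1:], mean_r2=mean, n_pairs=counts)


@dataclasses.dataclass
class QTLRegion:
    """A merged run of significant windows on one chromosome.

    Coordinates are 1-based inclusive; ``span`` is end - start (bp), zero for
    a singleton single-SNP region.  ``best_sigma2`` maps analysis label to
    the best (maximum) variance among member windows of that analysis.
    """

    chrom: str
    start: int
    end: int
    first_id: str
    last_id: str
    best_sigma2: dict[str, float]
    mean_r2: float = float("nan")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def ld(self) -> str:
        return ld_class(self.mean_r2)


def merge_regions(flagged: pd.DataFrame, geno: PhasedGenotypes | None = None) -> list[QTLRegion]:
    """Merge flagged windows (any analysis) into QTL regions.

    ``flagged`` needs columns ``chrom, start_bp, end_bp, first_id, last_id,
    analysis, sigma2``; single-SNP hits are windows with start == end.
    Windows whose spans overlap or abut on one chromosome merge transitively;
    a single-SNP hit joins the region it falls inside, otherwise it forms a
    singleton region.  With ``geno`` given, each region's mean pairwise r^2
    over the markers it contains is computed for LD classification.
    Deterministic regardless of input order.
    """
    regions: list[QTLRegion] = []
    if len(flagged) == 0:
        return regions
    flagged = flagged.sort_values(["chrom", "start_bp", "end_bp"], kind="stable")
    for chrom, grp in flagged.groupby("chrom", sort=True):
        cur: list[pd.Series] = []
        for _, row in grp.iterrows():
            if cur and row["start_bp"] <= cur[-1]["_end"] + 1:
                row = row.copy()
                row["_end"] = max(cur[-1]["_end"], row["end_bp"])
                cur.append(row)
            else:
                if cur:
                    regions.append(_finalize(chrom, cur, geno))
                row = row.copy()
                row["_end"] = row["end_bp"]
                cur = [row]
        if cur:
            regions.append(_finalize(chrom, cur, geno))
    return regions


def _finalize(chrom: str, members: list[pd.Series], geno: PhasedGenotypes | None) -> QTLRegion:
    start = int(min(m["start_bp"] for m in members))
    end = int(max(m["end_bp"] for m in members))
    firsts = sorted(members, key=lambda m: (m["start_bp"], str(m["first_id"])))
    lasts = sorted(members, key=lambda m: (-m["end_bp"], str(m["last_id"])))
    best: dict[str, float] = {}
    for m in members:
        lab = str(m["analysis"])
        best[lab] = max(best.get(lab, -np.inf), float(m["sigma2"]))
    r2 = float("nan")
    if geno is not None:
        v = geno.variants
        idx = np.flatnonzero((v["chrom"].astype(str) == str(chrom)).to_numpy()
                             & (v["pos"] >= start).to_numpy() & (v["pos"] <= end).to_numpy())
        r2 = mean_pairwise_r2(geno, idx)
    return QTLRegion(chrom=str(chrom), start=start, end=end,
                     first_id=str(firsts[0]["first_id"]), last_id=str(lasts[0]["last_id"]),
                     best_sigma2=best, mean_r2=r2)


def regions_frame(regions: list[QTLRegion], analyses: list[str] | None = None) -> pd.DataFrame:
    """Table-style report of regions (1-based inclusive coordinates)."""
    if analyses is None:
        analyses = sorted({a for r in regions for a in r.best_sigma2})
    rows = []
    for r in regions:
        row = {"chrom": r.chrom, "first_id": r.first_id, "last_id": r.last_id,
               "start_bp": r.start, "end_bp": r.end, "span_bp": r.span,
               "mean_r2": r.mean_r2, "ld": r.ld}
        for a in analyses:
            row[a] = r.best_sigma2.get(a, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def regions_bed(regions: list[QTLRegion]) -> pd.DataFrame:
    """BED-style (0-based half-open) view of regions."""
    rows = []
    for r in regions:
        best = max(r.best_sigma2.values())
        rows.append((r.chrom, r.start - 1, r.end, f"{r.first_id}__{r.last_id}", best, r.ld))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "best_sigma2", "ld"])


def detection_summary(regions_df: pd.DataFrame, analyses: list[str]) -> pd.DataFrame:
    """Per-analysis detection counts over the region set.

    A region counts as detected by an analysis when it has at least one
    flagged member window of that analysis (non-missing variance column).
    ``percent`` truncates toward zero; ``percent_rounded`` rounds to nearest
    (the two differ only near .5 boundaries — both are reported because
    printed summaries in the field mix the conventions).
    """
    n = len(regions_df)
    if n == 0:
        raise ValueError("no regions: detection summary undefined")
    rows = []
    for a in analyses:
        if a not in regions_df.columns:
            raise KeyError(f"analysis column {a!r} missing from region table")
        c = int(regions_df[a].notna().sum())
        rows.append((a, c, int(100 * c / n), int(round(100 * c / n))))
    return pd.DataFrame(rows, columns=["analysis", "n_detected", "percent", "percent_rounded"])
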