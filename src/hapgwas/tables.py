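"""Machine-readable reference tables of the published study and their verifiers.

``table1.tsv`` lists the eight single SNPs with the largest additive genetic
variance for shear force (allele frequencies, substitution effects, variance,
gene context).  ``table2.tsv`` lists the 33 haplotype-detected QTL regions
with their bp spans, LD class and the best variance per window-size analysis
(SNP, SW3..SW11); an empty variance cell means the analysis did not detect
the region.  The verifiers recompute the internally checkable quantities:
the SNP variance column from the printed (p, a) pairs, and the per-analysis
detection tallies.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from hapgwas.ld import detection_summary
from hapgwas.variance import snp_variance

ANALYSES = ["SNP", "SW3", "SW5", "SW7", "SW9", "SW11"]
HAP_ANALYSES = ["SW3", "SW5", "SW7", "SW9", "SW11"]


def _data_path(name: str):
    return importlib.resources.files("hapgwas").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    df = pd.read_csv(_data_path("table1.tsv"), sep="\t")
    if len(df) != 8:
        raise ValueError(f"table1 fixture must have 8 rows, got {len(df)}")
    return df


def load_table2() -> pd.DataFrame:
    df = pd.read_csv(_data_path("table2.tsv"), sep="\t")
    if len(df) != 33:
        raise ValueError(f"table2 fixture must have 33 rows, got {len(df)}")
    return df


def verify_table1(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Recompute 2 p (1 - p) a^2 per row and report the deviation from the table.

    Printed inputs are rounded to 2-3 decimals, so recomputed variances match
    the printed column to within 0.002 kg^2.
    """
    df = load_table1() if table is None else table
    required = {"marker", "freq1", "effect1", "variance"}
    if not required.issubset(df.columns):
        raise ValueError(f"malformed table1 fixture: need columns {sorted(required)}")
    recomputed = [snp_variance(p, a) for p, a in zip(df["freq1"], df["effect1"])]
    out = df[["marker", "freq1", "effect1", "variance"]].copy()
    out["recomputed"] = recomputed
    out["abs_dev"] = (out["recomputed"] - out["variance"]).abs()
    out["pass"] = out["abs_dev"] <= 0.002
    return out


def verify_table2(table: pd.DataFrame | None = None) -> dict:
    """Detection tallies of the region table.

    Returns per-analysis counts/percentages (floor and rounded), the number
    of regions found by all five window sizes and by at least two, the
    maximum haplotype-window variance, and the LD-class tally.
    """
    df = load_table2() if table is None else table
    if not set(ANALYSES).issubset(df.columns):
        raise ValueError(f"malformed table2 fixture: need columns {ANALYSES}")
    hap = df[HAP_ANALYSES]
    n_hits = hap.notna().sum(axis=1)
    summary = detection_summary(df, ANALYSES)
    return {
        "n_regions": len(df),
        "detection": summary,
        "detected_by_all_five": int((n_hits == 5).sum()),
        "detected_by_at_least_two": int((n_hits >= 2).sum()),
        "max_haplotype_variance": float(np.nanmax(hap.to_numpy(dtype=float))),
        "ld_classes": df["ld"].value_counts().to_dict(),
    }
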