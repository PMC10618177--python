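"""TSS-distance and gene-structure annotation of chromatin regions.

Each region (e.g. a differential histone-mark region) is annotated with its
nearest transcription start site and one of five genomic bins:
promoter_lt1kb (|distance| < 1 kb), promoter_1to5kb (1-5 kb), exon, intron,
intergenic — evaluated in that priority on the region midpoint.  The TSS is
the strand-aware 5' end of each gene's first exon; distances are signed on
the gene strand (negative = upstream of the TSS).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BINS = ("promoter_lt1kb", "promoter_1to5kb", "exon", "intron", "intergenic")
PROMOTER_NEAR = 1_000
PROMOTER_FAR = 5_000


def gene_table(exon_model: pd.DataFrame) -> pd.DataFrame:
    """Per-gene chrom, strand, TSS (0-based) and gene-body span."""
    if exon_model.empty:
        raise ValueError("empty exon model")
    rows = []
    for gene, sub in exon_model.groupby("gene_id", sort=True):
        strand = sub["strand"].iloc[0]
        chrom = sub["chrom"].iloc[0]
        body_start, body_end = int(sub["start"].min()), int(sub["end"].max())
        first = sub[sub["exon_number"] == sub["exon_number"].min()].iloc[0]
        tss = int(first["start"]) if strand == "+" else int(first["end"]) - 1
        rows.append((gene, chrom, strand, tss, body_start, body_end))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss",
                                       "body_start", "body_end"])


def region_midpoint(start: int, end: int) -> float:
    return (start + end - 1) / 2.0


def nearest_tss(region: pd.Series, genes: pd.DataFrame) -> tuple[str, float]:
    """Nearest gene and signed midpoint-to-TSS distance.

    Ties on |distance| go to the lexicographically smallest gene_id.
    Distance is negative upstream of the TSS on the gene's strand.  Genes on
    other chromosomes are ignored; with none on the region's chromosome the
    nearest over all genes is returned (distance infinite in spirit but
    computed on coordinates) — callers filter by chromosome beforehand.
    """
    if genes.empty:
        raise ValueError("empty gene table")
    sub = genes[genes["chrom"] == region["chrom"]]
    if sub.empty:
        return "", float("inf")
    mid = region_midpoint(int(region["start"]), int(region["end"]))
    raw = mid - sub["tss"].to_numpy(dtype=float)
    signed = np.where(sub["strand"].to_numpy() == "+", raw, -raw)
    absd = np.abs(signed)
    best = absd.min()
    tied = np.flatnonzero(absd == best)
    gene_ids = sub["gene_id"].to_numpy()
    pick = min(tied, key=lambda i: gene_ids[i])  # tie-break on gene_id
    return str(gene_ids[pick]), float(signed[pick])


def _bin_for(region: pd.Series, genes: pd.DataFrame, exon_model: pd.DataFrame,
             distance: float) -> str:
    if abs(distance) < PROMOTER_NEAR:
        return "promoter_lt1kb"
    if abs(distance) < PROMOTER_FAR:
        return "promoter_1to5kb"
    mid = region_midpoint(int(region["start"]), int(region["end"]))
    sub = genes[genes["chrom"] == region["chrom"]]
    in_body = sub[(sub["body_start"] <= mid) & (mid < sub["body_end"])]
    if in_body.empty:
        return "intergenic"
    exons = exon_model[exon_model["chrom"] == region["chrom"]]
    in_exon = ((exons["start"] <= mid) & (mid < exons["end"])).any()
    return "exon" if in_exon else "intron"


def annotate_regions(regions: pd.DataFrame,
                     exon_model: pd.DataFrame) -> pd.DataFrame:
    """Annotate every region with nearest gene, signed TSS distance and bin."""
    genes = gene_table(exon_model)
    rows = []
    for _, region in regions.iterrows():
        gene, dist = nearest_tss(region, genes)
        b = _bin_for(region, genes, exon_model, dist)
        rows.append((region["region_id"], gene, dist, b))
    return pd.DataFrame(rows, columns=["region_id", "nearest_gene",
                                       "tss_distance", "bin"])


def distribution_summary(annotations: pd.DataFrame,
                         trajectory_calls: pd.DataFrame) -> pd.DataFrame:
    """Percent of regions per genomic bin within each trajectory category.

    ``annotations`` joins ``trajectory_calls`` on region_id == feature_id;
    unmatched ids on either side are an error.  Percentages are one-decimal
    and sum to 100 per category up to rounding.
    """
    a_ids = set(annotations["region_id"])
    c_ids = set(trajectory_calls["feature_id"])
    if a_ids != c_ids:
        diff = sorted(a_ids ^ c_ids)
        raise ValueError(f"unmatched region ids: {diff[:20]}"
                         f"{'...' if len(diff) > 20 else ''}")
    merged = annotations.merge(trajectory_calls, left_on="region_id",
                               right_on="feature_id")
    rows = []
    for cat, sub in merged.groupby("category", sort=True):
        n = len(sub)
        for b in BINS:
            k = int((sub["bin"] == b).sum())
            rows.append((cat, b, k, n, round(100.0 * k / n, 1)))
    return pd.DataFrame(rows, columns=["category", "bin", "k", "n", "percent"])
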