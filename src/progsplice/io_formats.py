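"""Readers and writers for every table the pipeline touches.

All genomic intervals are held internally as 0-based half-open ``[start, end)``;
1-based inclusive coordinates appear only at the GTF/VCF/junction-table
boundary and are converted losslessly on the way in and out.  Splice junctions
are anchored on the intron: at I/O the two coordinates are the first and last
base of the intron (1-based inclusive, the ``SJ.out.tab`` convention);
internally the intron is the half-open interval ``[start, end)``.

Readers are strict: a file that violates the declared dialect raises
:class:`FormatError` naming the offending line or cell, never a silently
coerced table.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import gffutils.iterators
import numpy as np
import pandas as pd

GROUPS = ("RD", "FL", "HCC")

#: SJ.out.tab strand codes -> symbols. Code 0 (undefined) is rejected:
#: junction orientation is required downstream.
_SJ_STRAND = {"1": "+", "2": "-", "+": "+", "-": "-"}


class FormatError(ValueError):
    """A file violated its declared dialect."""


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSheet:
    """Sample-to-group assignment for the three-condition design.

    ``table`` has columns ``sample_id`` and ``group`` (plus any extra path
    columns passed through untouched); groups are restricted to RD/FL/HCC.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "group"):
            if col not in t.columns:
                raise FormatError(f"sample sheet lacks required column {col!r}")
        dup = t["sample_id"][t["sample_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample ids: {sorted(set(dup))}")
        bad = sorted(set(t["group"]) - set(GROUPS))
        if bad:
            raise FormatError(f"unknown group labels {bad}; expected one of {GROUPS}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> list[str]:
        """Group labels present, in canonical RD < FL < HCC order."""
        present = set(self.table["group"])
        return [g for g in GROUPS if g in present]

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    def group_of(self, sample_id: str) -> str:
        hit = self.table.loc[self.table["sample_id"] == sample_id, "group"]
        if hit.empty:
            raise KeyError(sample_id)
        return str(hit.iloc[0])


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str})
    if "sample" in df.columns and "sample_id" not in df.columns:
        df = df.rename(columns={"sample": "sample_id"})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    sheet.table.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def validate_count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()]
        raise FormatError(f"duplicate feature ids: {sorted(set(dup))}")
    if not all(np.issubdtype(d, np.integer) for d in counts.dtypes):
        bad = [c for c, d in counts.dtypes.items() if not np.issubdtype(d, np.integer)]
        raise FormatError(f"non-integer count columns: {bad}")
    if (counts.to_numpy() < 0).any():
        raise FormatError("negative entries in count matrix")
    return counts


def read_count_matrix(path: str | os.PathLike,
                      sample_sheet: SampleSheet | None = None) -> pd.DataFrame:
    """Read a feature x sample TSV of read counts.

    If a sample sheet is given, columns are restricted to and ordered by its
    ``sample_id`` list; a sheet sample missing from the header is a hard error.
    Non-integer cells are reported with their row/column location.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        vals = df[col]
        ok = pd.to_numeric(vals, errors="coerce")
        bad = ok.isna() | (ok != ok.round())
        if bad.any():
            row = df.index[int(np.argmax(bad.to_numpy()))]
            raise FormatError(
                f"non-integer count at feature {row!r}, sample {col!r}"
            )
        df[col] = ok.astype(np.int64)
    if sample_sheet is not None:
        missing = [s for s in sample_sheet.sample_ids if s not in df.columns]
        if missing:
            raise FormatError(f"count matrix lacks sample column(s): {missing}")
        df = df[sample_sheet.sample_ids]
    return validate_count_matrix(df)


def write_count_matrix(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_count_matrix(counts)
    counts.to_csv(path, sep="\t", index_label="feature_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# junction tables (SJ.out.tab dialect)
# ---------------------------------------------------------------------------

JUNCTION_COLUMNS = ["chrom", "intron_start", "intron_end", "strand",
                    "unique_reads", "sample_id"]


def read_junction_table(path: str | os.PathLike, sample_id: str) -> pd.DataFrame:
    """Read one sample's splice junctions from an ``SJ.out.tab``-style TSV.

    Consumed columns: chrom, intron start (1-based first intron base), intron
    end (1-based last intron base), strand code (1/2 or +/-), and unique read
    count (column 7; or column 5 for the short 5/6-column form).  Internally
    the intron becomes 0-based half-open.  Zero-read junctions are kept.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 columns, got {len(parts)}")
            chrom, s1, e1, strand_code = parts[0], parts[1], parts[2], parts[3]
            # full SJ.out.tab has motif/annotated at cols 5-6 and unique reads
            # at col 7; the short form puts unique reads at col 5
            reads_field = parts[6] if len(parts) >= 7 else parts[4]
            if strand_code not in _SJ_STRAND:
                raise FormatError(f"{path}:{lineno}: bad strand {strand_code!r}")
            try:
                start1, end1, reads = int(s1), int(e1), int(reads_field)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if start1 >= end1:
                raise FormatError(
                    f"{path}:{lineno}: intron start {start1} >= end {end1}"
                )
            if reads < 0:
                raise FormatError(f"{path}:{lineno}: negative read count")
            start0, end0 = to_zero_based(start1, end1)
            rows.append((chrom, start0, end0, _SJ_STRAND[strand_code], reads, sample_id))
    return pd.DataFrame(rows, columns=JUNCTION_COLUMNS).astype(
        {"intron_start": np.int64, "intron_end": np.int64, "unique_reads": np.int64}
    )


def write_junction_table(junctions: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write junctions back to the full 9-column SJ.out.tab dialect."""
    strand_code = {"+": 1, "-": 2}
    with open(path, "w") as fh:
        for rec in junctions.itertuples(index=False):
            s1, e1 = to_one_based(int(rec.intron_start), int(rec.intron_end))
            fh.write(f"{rec.chrom}\t{s1}\t{e1}\t{strand_code[rec.strand]}\t0\t0\t"
                     f"{int(rec.unique_reads)}\t0\t0\n")


# ---------------------------------------------------------------------------
# exon models (GTF subset)
# ---------------------------------------------------------------------------

EXON_COLUMNS = ["gene_id", "transcript_id", "exon_number", "chrom",
                "start", "end", "strand"]


def _validate_exon_model(df: pd.DataFrame) -> pd.DataFrame:
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"]].iloc[0]
        raise FormatError(f"exon with start >= end: {bad.to_dict()}")
    for (gene, tx), sub in df.groupby(["gene_id", "transcript_id"], sort=False):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise FormatError(f"overlapping exons in transcript {tx} of {gene}")
        order = sub.sort_values("exon_number")
        ascending = order["start"].is_monotonic_increasing
        descending = order["start"].is_monotonic_decreasing
        strand = sub["strand"].iloc[0]
        if strand == "+" and not ascending:
            raise FormatError(f"exon numbering of {tx} not in transcription order (+)")
        if strand == "-" and not descending:
            raise FormatError(f"exon numbering of {tx} not in transcription order (-)")
    return df.reset_index(drop=True)


def read_exon_model(path: str | os.PathLike) -> pd.DataFrame:
    """Read exon features from a GTF into a flat exon table (0-based half-open).

    Only ``exon`` features are consumed; each must carry gene_id,
    transcript_id and exon_number attributes.  Exon numbering is validated to
    follow transcription order on the feature's strand.
    """
    rows = []
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype != "exon":
            continue
        try:
            gene = feat.attributes["gene_id"][0]
            tx = feat.attributes["transcript_id"][0]
            num = int(feat.attributes["exon_number"][0])
        except (KeyError, IndexError, ValueError) as exc:
            raise FormatError(f"exon feature missing attribute: {exc}") from None
        if num < 1:
            raise FormatError(f"exon_number must be positive, got {num}")
        if feat.start < 1:
            raise FormatError(f"GTF start < 1 at {feat.seqid}:{feat.start}")
        start0, end0 = to_zero_based(feat.start, feat.end)
        rows.append((gene, tx, num, feat.seqid, start0, end0, feat.strand))
    df = pd.DataFrame(rows, columns=EXON_COLUMNS).astype(
        {"exon_number": np.int64, "start": np.int64, "end": np.int64}
    )
    return _validate_exon_model(df)


def write_exon_model(exons: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in exons.itertuples(index=False):
            s1, e1 = to_one_based(int(rec.start), int(rec.end))
            attrs = (f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}"; '
                     f'exon_number "{int(rec.exon_number)}";')
            fh.write(f"{rec.chrom}\tprogsplice\texon\t{s1}\t{e1}\t.\t{rec.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# variant tables (minimal VCF)
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "sample_id"]


def read_variant_table(path: str | os.PathLike, sample_id: str | None = None) -> pd.DataFrame:
    """Read a minimal VCF (CHROM, POS, REF, ALT; POS 1-based).

    Per-sample presence comes either from one file per sample (pass
    ``sample_id``) or from a non-standard trailing SAMPLE column declared in
    the ``#CHROM`` header line.
    """
    sample_col: int | None = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM") or line.startswith("#"):
                header = line.lstrip("#").split("\t")
                if "SAMPLE" in header:
                    sample_col = header.index("SAMPLE")
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 VCF columns")
            chrom, pos_s, ref, alt = parts[0], parts[1], parts[2], parts[3]
            # 8-column bodies follow the standard layout CHROM POS ID REF ALT...
            if sample_col is None and len(parts) >= 8:
                ref, alt = parts[3], parts[4]
            elif sample_col is not None:
                ref, alt = parts[3], parts[4]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer POS {pos_s!r}") from None
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: POS must be >= 1, got {pos}")
            if not ref or not alt or ref == "." or alt == ".":
                raise FormatError(f"{path}:{lineno}: empty REF/ALT")
            sid = parts[sample_col] if sample_col is not None else sample_id
            if sid is None:
                raise FormatError(
                    f"{path}:{lineno}: no SAMPLE column and no sample_id given"
                )
            rows.append((chrom, pos, ref, alt, sid))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS).astype({"pos": np.int64})


def write_variant_table(variants: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tSAMPLE\n")
        for rec in variants.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{int(rec.pos)}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t.\t"
                     f"{rec.sample_id}\n")


# ---------------------------------------------------------------------------
# region sets (BED4/BED6)
# ---------------------------------------------------------------------------

REGION_COLUMNS = ["chrom", "start", "end", "region_id", "score", "strand"]


def read_region_set(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED4/BED6 region set (already 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: BED4 requires >=4 columns")
            chrom, s, e, rid = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            score = parts[4] if len(parts) > 4 else "."
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append((chrom, start, end, rid, score, strand))
    df = pd.DataFrame(rows, columns=REGION_COLUMNS).astype({"start": np.int64, "end": np.int64})
    if df["region_id"].duplicated().any():
        dup = df["region_id"][df["region_id"].duplicated()]
        raise FormatError(f"duplicate region ids: {sorted(set(dup))}")
    return df


def write_region_set(regions: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in REGION_COLUMNS if c in regions.columns]
    regions[cols].to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# generic results writer
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path: str | os.PathLike,
                  float_format: str = "%.6g") -> None:
    """Write an analysis result table as TSV with a deterministic layout.

    Column order is the DataFrame's own, line endings are LF, floats use a
    fixed format so identical inputs give byte-identical files.
    """
    table.to_csv(path, sep="\t", index=False, lineterminator="\n",
                 float_format=float_format)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def df_to_tsv_bytes(table: pd.DataFrame, float_format: str = "%.6g") -> bytes:
    buf = io.StringIO()
    table.to_csv(buf, sep="\t", index=False, lineterminator="\n",
                 float_format=float_format)
    return buf.getvalue().encode()
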