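"""Targeted full-exon-skipping detection and four-way sample classification.

The archetype is Ctnnb1/CTNNB1 exon 3, whose in-frame loss removes the
phosphodegron that targets beta-catenin for degradation.  For a target exon
E_k with neighbours E_{k-1} and E_{k+1}, three canonical junctions exist:
the two inclusion junctions (E_{k-1}-E_k and E_k-E_{k+1}) and the skipping
junction (E_{k-1}-E_{k+1}).  A sample is skip-positive only when the
skipping junction is supported, the entire flanking exons are covered
(whole-exon presence), and no junction lands inside the target exon
(the exclusion must remove the whole exon, not part of it) — a screen that
separates true splice-level exclusion from genomic deletion artefacts.
Mutation independence is then established by checking a variant table
against the exon plus a splice-site pad.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_SKIP_READS = 3
DEFAULT_FLANK_BREADTH = 0.90
DEFAULT_FLANK_DEPTH = 1
DEFAULT_VARIANT_PAD = 6

CLASS_EXCLUSION = "exclusion"
CLASS_MUTATION = "exon3_mutation"
CLASS_DELETION = "e3e4_deletion"
CLASS_WILDTYPE = "wildtype"
CLASS_ORDER = (CLASS_DELETION, CLASS_MUTATION, CLASS_EXCLUSION, CLASS_WILDTYPE)


@dataclass(frozen=True)
class SkipCall:
    sample_id: str
    gene: str
    exon_number: int
    e_up_inc: int
    e_dn_inc: int
    e_skip: int
    exclusion_fraction: float
    flanks_intact: bool
    partial_sites: bool
    mutation_free: bool
    positive: bool


def _target_exons(exon_model: pd.DataFrame, gene: str,
                  exon_number: int) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Return (upstream, target, downstream) exons in genomic order."""
    sub = exon_model[(exon_model["gene_id"] == gene)]
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from exon model")
    tx_with_target = sub.loc[sub["exon_number"] == exon_number, "transcript_id"]
    if tx_with_target.empty:
        raise ValueError(f"exon {exon_number} of {gene!r} absent from exon model")
    tx = tx_with_target.iloc[0]
    exons = sub[sub["transcript_id"] == tx].set_index("exon_number")
    lo, hi = exons.index.min(), exons.index.max()
    if exon_number in (lo, hi):
        raise ValueError(
            f"exon {exon_number} is terminal in transcript {tx}; no skipping "
            "junction is definable"
        )
    trio = [exons.loc[exon_number - 1], exons.loc[exon_number],
            exons.loc[exon_number + 1]]
    trio.sort(key=lambda e: int(e["start"]))  # genomic order handles strand
    return trio[0], trio[1], trio[2]


def exclusion_fraction(e_up: int, e_dn: int, e_skip: int,
                       denominator: str = "average") -> float:
    """Fraction of transcripts skipping the target exon.

    ``average`` (default) divides the skip reads by skip + mean of the two
    inclusion junctions (both measure the same inclusion isoform);
    ``sum`` uses skip + (up + dn).
    """
    if denominator not in ("average", "sum"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    inc = (e_up + e_dn) / 2.0 if denominator == "average" else float(e_up + e_dn)
    denom = e_skip + inc
    return e_skip / denom if denom > 0 else 0.0


def _flank_coverage_ok(coverage: pd.DataFrame, chrom: str, start: int, end: int,
                       min_breadth: float, min_depth: int) -> bool:
    sub = coverage[(coverage["chrom"] == chrom)
                   & (coverage["pos0"] >= start) & (coverage["pos0"] < end)
                   & (coverage["depth"] >= min_depth)]
    covered = sub["pos0"].nunique()
    return covered >= min_breadth * (end - start)


def call_exon_skip(junctions: pd.DataFrame, exon_model: pd.DataFrame,
                   target: tuple[str, int], coverage_track: pd.DataFrame,
                   sample_id: str | None = None,
                   min_skip_reads: int = DEFAULT_MIN_SKIP_READS,
                   flank_breadth: float = DEFAULT_FLANK_BREADTH,
                   flank_depth: int = DEFAULT_FLANK_DEPTH,
                   denominator: str = "average",
                   variants: pd.DataFrame | None = None,
                   pad: int = DEFAULT_VARIANT_PAD) -> SkipCall:
    """Call full skipping of one target exon in one sample.

    ``junctions`` is that sample's junction table (intron intervals 0-based
    half-open); ``coverage_track`` has columns chrom/pos0/depth (optionally
    sample_id, filtered on ``sample_id``).  The three canonical junctions
    are identified by exact donor/acceptor match to the exon model.  When a
    variant table is supplied the call also records mutation independence
    over the padded exon window.
    """
    gene, exon_number = target
    up, tgt, dn = _target_exons(exon_model, gene, exon_number)
    chrom = str(tgt["chrom"])

    if sample_id is None:
        ids = set(junctions["sample_id"]) if "sample_id" in junctions else set()
        sample_id = next(iter(ids)) if len(ids) == 1 else ""
    cov = coverage_track
    if "sample_id" in cov.columns and sample_id:
        cov = cov[cov["sample_id"] == sample_id]

    lookup = {(r.chrom, int(r.intron_start), int(r.intron_end)): int(r.unique_reads)
              for r in junctions.itertuples(index=False)}
    e_up = lookup.get((chrom, int(up["end"]), int(tgt["start"])), 0)
    e_dn = lookup.get((chrom, int(tgt["end"]), int(dn["start"])), 0)
    e_skip = lookup.get((chrom, int(up["end"]), int(dn["start"])), 0)

    frac = exclusion_fraction(e_up, e_dn, e_skip, denominator)

    flanks = (_flank_coverage_ok(cov, chrom, int(up["start"]), int(up["end"]),
                                 flank_breadth, flank_depth)
              and _flank_coverage_ok(cov, chrom, int(dn["start"]), int(dn["end"]),
                                     flank_breadth, flank_depth))

    ts, te = int(tgt["start"]), int(tgt["end"])
    partial = False
    for r in junctions.itertuples(index=False):
        if r.chrom != chrom:
            continue
        s, e = int(r.intron_start), int(r.intron_end)
        # a donor at s truncates an exon ending inside the target; an
        # acceptor at e starts an exon inside it — both mean partial loss
        if ts < s < te or ts < e < te:
            partial = True
            break

    mut_free = True
    if variants is not None:
        mut_free = mutation_independence(variants, exon_model, target, pad=pad,
                                         sample_id=sample_id)

    positive = flanks and not partial and e_skip >= min_skip_reads
    return SkipCall(sample_id, gene, exon_number, e_up, e_dn, e_skip, frac,
                    flanks, partial, mut_free, positive)


def mutation_independence(variants: pd.DataFrame, exon_model: pd.DataFrame,
                          target: tuple[str, int],
                          pad: int = DEFAULT_VARIANT_PAD,
                          sample_id: str | None = None) -> bool:
    """True iff no variant touches the target exon extended by ``pad`` bases.

    The pad (default 6) covers the canonical splice-site dinucleotides and
    near-site positions on both flanks, so splice-site mutations mimicking
    exclusion are not declared "mutation independent".  Variant POS is
    1-based; multi-base REF alleles are treated as covering
    ``[pos, pos + len(ref) - 1]``.
    """
    gene, exon_number = target
    _, tgt, _ = _target_exons(exon_model, gene, exon_number)
    # padded window, 1-based inclusive
    win_lo = int(tgt["start"]) + 1 - pad
    win_hi = int(tgt["end"]) + pad
    v = variants
    if sample_id is not None and "sample_id" in v.columns:
        v = v[v["sample_id"] == sample_id]
    for r in v.itertuples(index=False):
        if r.chrom != tgt["chrom"]:
            continue
        v_lo = int(r.pos)
        v_hi = v_lo + max(len(str(r.ref)), 1) - 1
        if v_lo <= win_hi and v_hi >= win_lo:
            return False
    return True


def _variant_in_exon(variants: pd.DataFrame, tgt: pd.Series,
                     sample_id: str | None) -> bool:
    v = variants
    if sample_id is not None and "sample_id" in v.columns:
        v = v[v["sample_id"] == sample_id]
    lo1, hi1 = int(tgt["start"]) + 1, int(tgt["end"])
    for r in v.itertuples(index=False):
        if r.chrom != tgt["chrom"]:
            continue
        v_lo = int(r.pos)
        v_hi = v_lo + max(len(str(r.ref)), 1) - 1
        if v_lo <= hi1 and v_hi >= lo1:
            return True
    return False


def classify_sample(skip_call: SkipCall, variants: pd.DataFrame,
                    deletion_calls: pd.DataFrame, exon_model: pd.DataFrame,
                    target: tuple[str, int]) -> str:
    """Four-way splice-status class of one tumour sample.

    Priority: a genomic deletion spanning the target exon and its downstream
    neighbour wins; else a coding variant inside the target exon; else a
    positive skip call (exclusion); else wildtype.  ``deletion_calls`` has
    columns sample_id/chrom/start/end (0-based half-open spans).
    """
    gene, exon_number = target
    up, tgt, dn = _target_exons(exon_model, gene, exon_number)
    sample_id = skip_call.sample_id

    dels = deletion_calls
    if "sample_id" in dels.columns:
        dels = dels[dels["sample_id"] == sample_id]
    for r in dels.itertuples(index=False):
        if (r.chrom == tgt["chrom"]
                and int(r.start) < int(tgt["end"]) and int(r.end) > int(tgt["start"])
                and int(r.start) < int(dn["end"]) and int(r.end) > int(dn["start"])):
            return CLASS_DELETION
    if _variant_in_exon(variants, tgt, sample_id):
        return CLASS_MUTATION
    if skip_call.positive:
        return CLASS_EXCLUSION
    return CLASS_WILDTYPE


def cohort_frequencies(classes: pd.DataFrame,
                       denominators: dict[str, int] | None = None) -> pd.DataFrame:
    """Per cohort x class counts and percentages.

    ``classes`` has columns cohort/sample_id/class.  ``denominators``
    optionally overrides each cohort's total n (e.g. when only positives
    were tabulated).  Percentages are reported at one decimal and as the
    nearest integer (half away from zero); empty cohorts are omitted.
    """
    rows = []
    for cohort, sub in classes.groupby("cohort", sort=True):
        n = denominators.get(cohort, len(sub)) if denominators else len(sub)
        if n == 0:
            continue
        for cls in CLASS_ORDER:
            k = int((sub["class"] == cls).sum())
            pct = 100.0 * k / n
            rows.append((cohort, cls, k, n, round(pct, 1),
                         int(np.floor(pct + 0.5))))
    return pd.DataFrame(rows, columns=["cohort", "class", "k", "n",
                                       "percent", "percent_int"])
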