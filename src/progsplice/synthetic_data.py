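"""Synthetic three-state liver cohort with known ground truth.

Generates every input the pipeline consumes — negative-binomial gene (or
region) counts with planted progression categories, binomial splice-junction
reads with planted per-group PSI including one full-exon-skipping event,
Poisson ISH dot counts with a planted exclusion fraction, and a variant table
— so every downstream stage can be tested against a known truth without any
external download.

The design mirrors the study being emulated: three groups (RD regular-diet
control, FL fatty liver, HCC tumour), a handful of animals per group, genes
whose expression follows one of five progression trajectories, a sub-visible
exon-skipping isoform present only in tumours, and junction-specific in-situ
dots whose exclusion fraction tracks that isoform.

Determinism: all randomness flows from one integer seed through
``numpy.random.SeedSequence``; each data kind (counts, junctions, dots,
variants) gets its own child stream, so adding one generator never perturbs
another.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (GROUPS, JUNCTION_COLUMNS, SampleSheet,
                         write_count_matrix, write_exon_model,
                         write_junction_table, write_results,
                         write_sample_sheet, write_variant_table)

CATEGORIES = ("early", "gradual", "tumour_specific", "fatty_liver_specific",
              "switching", "none")

#: log2 fold-change multipliers per group (RD, FL, HCC) for each trajectory.
PATTERN_VECTORS = {
    "early": (0.0, 1.0, 1.0),
    "gradual": (0.0, 1.0, 2.0),
    "tumour_specific": (0.0, 0.0, 1.0),
    "fatty_liver_specific": (0.0, 1.0, 0.0),
    "switching": (0.0, 1.0, -1.0),
    "none": (0.0, 0.0, 0.0),
}

_STREAMS = ("counts", "junctions", "dots", "variants")


@dataclass(frozen=True)
class SkipEventSpec:
    """Target exon for the planted full-skipping event (Ctnnb1 exon-3 archetype).

    Coordinates are 0-based half-open on a toy chromosome; the three exons
    play the roles of E2/E3/E4, with the skipping junction joining E2 to E4.
    ``exclusion_frac`` gives the fraction of transcripts skipping the target
    exon per group.
    """

    gene: str = "Ctnnb1"
    chrom: str = "chr9"
    exons: tuple[tuple[int, int], ...] = ((10_000, 10_200),   # E2
                                          (10_500, 10_728),   # E3 (target)
                                          (11_000, 11_100))   # E4
    strand: str = "+"
    target_exon_number: int = 3
    exclusion_frac: dict[str, float] = field(
        default_factory=lambda: {"RD": 0.0, "FL": 0.0, "HCC": 0.25})


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort.

    Defaults describe the emulated study conditions: 5 animals per group,
    mean expression 100 with NB dispersion 0.05 and 4-fold planted effects,
    200 features per trajectory category, junction depth 200, a tumour-only
    exon-skipping fraction of 0.25, and an ISH exclusion-dot fraction of 0.12
    in tumours (10 microscopy fields of ~200 dots each per sample).
    """

    n_features_per_category: dict[str, int] = field(
        default_factory=lambda: {c: 200 for c in CATEGORIES})
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    base_mean: float = 100.0
    n_samples_per_group: int = 5
    library_size_sigma: float = 0.1

    n_splice_events: int = 60
    junction_depth_mean: float = 200.0
    #: event_id -> (psi_RD, psi_FL, psi_HCC) on the 0-100 scale; None builds
    #: the default deterministic mix (see ``default_psi_by_group``).
    psi_by_group: dict[str, tuple[float, float, float]] | None = None

    skip_event: SkipEventSpec = field(default_factory=SkipEventSpec)

    n_fields: int = 10
    dots_lambda: float = 200.0
    #: per-group (or per-sample) exclusion-dot fraction
    dots_exclusion_frac: dict[str, float] = field(
        default_factory=lambda: {"RD": 0.0, "FL": 0.0, "HCC": 0.12})

    #: sample_id -> "inside" | "outside": place one variant inside the target
    #: exon window or safely outside it; samples not listed get no variant.
    variant_placement: dict[str, str] = field(default_factory=dict)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        for name in ("nb_dispersion", "base_mean", "junction_depth_mean",
                     "dots_lambda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.library_size_sigma < 0:
            raise ValueError("library_size_sigma must be >= 0")
        if any(n < 0 for n in self.n_features_per_category.values()):
            raise ValueError("feature counts per category must be >= 0")
        bad = set(self.n_features_per_category) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories {sorted(bad)}")
        if self.psi_by_group is not None:
            for ev, psis in self.psi_by_group.items():
                if any(not 0 <= p <= 100 for p in psis):
                    raise ValueError(f"PSI outside [0,100] for event {ev}")
        for g, f in self.skip_event.exclusion_frac.items():
            if not 0 <= f <= 1:
                raise ValueError(f"skip exclusion fraction for {g} outside [0,1]")
        for k, f in self.dots_exclusion_frac.items():
            if not 0 <= f <= 1:
                raise ValueError(f"dot exclusion fraction for {k} outside [0,1]")


@dataclass
class GroundTruth:
    """Planted truth for every simulated quantity."""

    category_by_feature: dict[str, str] = field(default_factory=dict)
    sign_by_feature: dict[str, int] = field(default_factory=dict)
    size_factors: dict[str, float] = field(default_factory=dict)
    psi_by_event_group: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    skip_fraction_by_sample: dict[str, float] = field(default_factory=dict)
    dots_fraction_by_sample: dict[str, float] = field(default_factory=dict)
    variant_in_exon_by_sample: dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# RNG plumbing
# ---------------------------------------------------------------------------

def _rng_for(config: SimConfig, kind: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(kind)])


def make_sample_sheet(config: SimConfig) -> SampleSheet:
    rows = [(f"{g}_{i + 1}", g)
            for g in GROUPS for i in range(config.n_samples_per_group)]
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "group"]))


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mean, variance = mean + dispersion * mean^2); Poisson when dispersion=0."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the gene x sample count matrix with planted trajectories.

    Per feature ``f`` in category ``c`` with random sign ``z_f`` in {-1,+1}
    and sample ``s`` of group ``g``::

        counts ~ NB(mean = base_mean * sf_s * 2**(z_f * pattern_c[g] * effect),
                    variance = mean + dispersion * mean**2)

    with log-normal(0, library_size_sigma) size factors ``sf_s``.
    """
    rng = _rng_for(config, "counts")
    sheet = make_sample_sheet(config)
    samples = sheet.sample_ids
    group_idx = np.array([GROUPS.index(sheet.group_of(s)) for s in samples])

    features, cats = [], []
    for cat in CATEGORIES:
        n = config.n_features_per_category.get(cat, 0)
        features += [f"{cat}_{i + 1:04d}" for i in range(n)]
        cats += [cat] * n

    signs = rng.choice([-1, 1], size=len(features))
    sf = np.exp(rng.normal(0.0, config.library_size_sigma, size=len(samples)))

    pattern = np.array([PATTERN_VECTORS[c] for c in cats])          # F x 3
    log2shift = signs[:, None] * pattern * config.effect_log2fc     # F x 3
    mean = (config.base_mean * sf[None, :]
            * 2.0 ** log2shift[:, group_idx])                       # F x S
    counts = _nb_draw(rng, mean, config.nb_dispersion)

    truth = GroundTruth(
        category_by_feature=dict(zip(features, cats)),
        sign_by_feature=dict(zip(features, (int(z) for z in signs))),
        size_factors=dict(zip(samples, sf)),
    )
    matrix = pd.DataFrame(counts, index=pd.Index(features, name="feature_id"),
                          columns=samples)
    return matrix, truth


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------

def default_psi_by_group(config: SimConfig) -> dict[str, tuple[float, float, float]]:
    """Deterministic default event mix.

    Cycling over events: 40% constitutive (PSI 98 everywhere, never an ASE),
    30% shared intermediate (PSI 50 everywhere), 30% progression events (PSI
    95 in RD, 50 in FL, 45 in HCC) — so the per-sample ASE burden ranks
    HCC ~ FL > RD and the progression events are differential versus RD.
    """
    out = {}
    for i in range(config.n_splice_events):
        ev = f"ev_{i + 1:04d}"
        r = i % 10
        if r < 4:
            out[ev] = (98.0, 98.0, 98.0)
        elif r < 7:
            out[ev] = (50.0, 50.0, 50.0)
        else:
            out[ev] = (95.0, 50.0, 45.0)
    return out


def event_definitions(config: SimConfig) -> pd.DataFrame:
    """Junction coordinates for every simulated binary event.

    Generic events live on a toy chromosome ``chrSIM``: event ``i`` has an
    alternative exon with inclusion introns ``[a, b)`` / ``[c, d)`` and
    exclusion intron ``[a, d)``.  The planted skip event contributes its
    three canonical junctions (E2-E3, E3-E4, E2-E4) on the target gene.
    Coordinates are 0-based half-open intron intervals.
    """
    rows = []
    psi = config.psi_by_group or default_psi_by_group(config)
    for i, ev in enumerate(sorted(psi)):
        base = 100_000 + i * 10_000
        a, b = base, base + 1_000                 # upstream intron
        c, d = base + 1_200, base + 2_000         # downstream intron
        rows.append((ev, f"gene_{i + 1:04d}", "chrSIM", "+",
                     a, b, c, d, a, d))
    sk = config.skip_event
    (e2s, e2e), (e3s, e3e), (e4s, e4e) = sk.exons
    rows.append((f"{sk.gene}_exon{sk.target_exon_number}", sk.gene, sk.chrom,
                 sk.strand, e2e, e3s, e3e, e4s, e2e, e4s))
    return pd.DataFrame(rows, columns=[
        "event_id", "gene_id", "chrom", "strand",
        "inc1_start", "inc1_end", "inc2_start", "inc2_end",
        "exc_start", "exc_end"])


def skip_exon_model(config: SimConfig) -> pd.DataFrame:
    """Three-exon transcript model for the planted skip target."""
    sk = config.skip_event
    rows = []
    for k, (s, e) in enumerate(sk.exons):
        rows.append((sk.gene, f"{sk.gene}_tx1", sk.target_exon_number - 1 + k,
                     sk.chrom, s, e, sk.strand))
    from .io_formats import EXON_COLUMNS
    return pd.DataFrame(rows, columns=EXON_COLUMNS).astype(
        {"exon_number": np.int64, "start": np.int64, "end": np.int64})


def simulate_junctions(config: SimConfig) -> tuple[dict[str, pd.DataFrame],
                                                   pd.DataFrame, GroundTruth]:
    """Simulate per-sample junction tables plus a coverage track.

    Generic events: total reads ~ Poisson(junction_depth_mean), inclusion
    reads ~ Binomial(total, PSI/100) split evenly over the two inclusion
    junctions, remainder on the exclusion junction.  The planted skip event
    writes its three junctions with Poisson reads at rates depth*(1-f) on
    each inclusion junction and depth*f on the skipping junction, plus full
    coverage of both flanking exons in the returned coverage track.

    Returns ``(junction tables by sample, coverage track, truth)``.
    """
    rng = _rng_for(config, "junctions")
    sheet = make_sample_sheet(config)
    psi = config.psi_by_group or default_psi_by_group(config)
    for ev, vals in psi.items():
        if any(not 0 <= p <= 100 for p in vals):
            raise ValueError(f"PSI outside [0,100] for event {ev}")
    events = event_definitions(config)
    sk = config.skip_event
    skip_ev = f"{sk.gene}_exon{sk.target_exon_number}"

    truth = GroundTruth(psi_by_event_group=dict(psi))
    tables: dict[str, pd.DataFrame] = {}
    cov_rows = []
    for sample in sheet.sample_ids:
        group = sheet.group_of(sample)
        gi = GROUPS.index(group)
        recs = []
        for ev_rec in events.itertuples(index=False):
            if ev_rec.event_id == skip_ev:
                f = sk.exclusion_frac.get(group, 0.0)
                lam = config.junction_depth_mean
                e_up = rng.poisson(lam * (1 - f))
                e_dn = rng.poisson(lam * (1 - f))
                e_skip = rng.poisson(lam * f)
                truth.skip_fraction_by_sample[sample] = f
                triples = [(ev_rec.inc1_start, ev_rec.inc1_end, e_up),
                           (ev_rec.inc2_start, ev_rec.inc2_end, e_dn),
                           (ev_rec.exc_start, ev_rec.exc_end, e_skip)]
            else:
                p = psi[ev_rec.event_id][gi] / 100.0
                total = rng.poisson(config.junction_depth_mean)
                inc = rng.binomial(total, p) if total > 0 else 0
                exc = total - inc
                inc1 = inc // 2
                triples = [(ev_rec.inc1_start, ev_rec.inc1_end, inc1),
                           (ev_rec.inc2_start, ev_rec.inc2_end, inc - inc1),
                           (ev_rec.exc_start, ev_rec.exc_end, exc)]
            for s0, e0, reads in triples:
                recs.append((ev_rec.chrom, int(s0), int(e0), ev_rec.strand,
                             int(reads), sample))
        tables[sample] = pd.DataFrame(recs, columns=JUNCTION_COLUMNS)
        # coverage over the skip locus: flanks at full depth, target exon
        # thinned by the exclusion fraction
        f = sk.exclusion_frac.get(group, 0.0)
        depth = max(1, int(round(config.junction_depth_mean)))
        for k, (s0, e0) in enumerate(sk.exons):
            d = depth if k != 1 else max(0, int(round(depth * (1 - f))))
            for pos in range(s0, e0):
                cov_rows.append((sk.chrom, pos, d, sample))
    coverage = pd.DataFrame(cov_rows, columns=["chrom", "pos0", "depth", "sample_id"])
    return tables, coverage, truth


# ---------------------------------------------------------------------------
# ISH dots and variants
# ---------------------------------------------------------------------------

def _frac_for_sample(mapping: dict[str, float], sample: str, group: str) -> float:
    if sample in mapping:
        return mapping[sample]
    return mapping.get(group, 0.0)


def simulate_dots(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-field ISH dot counts: total ~ Poisson(dots_lambda), exclusion dots
    ~ Binomial(total, exclusion_frac)."""
    rng = _rng_for(config, "dots")
    sheet = make_sample_sheet(config)
    truth = GroundTruth()
    rows = []
    for sample in sheet.sample_ids:
        frac = _frac_for_sample(config.dots_exclusion_frac, sample,
                                sheet.group_of(sample))
        truth.dots_fraction_by_sample[sample] = frac
        for fld in range(1, config.n_fields + 1):
            total = rng.poisson(config.dots_lambda)
            exc = rng.binomial(total, frac) if total > 0 else 0
            rows.append((sample, fld, total - exc, exc))
    dots = pd.DataFrame(rows, columns=["sample_id", "field_index",
                                       "dots_inclusion", "dots_exclusion"])
    return dots, truth


def simulate_variants(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Place one SNV per configured sample inside or outside the target exon."""
    rng = _rng_for(config, "variants")
    sk = config.skip_event
    e3s, e3e = sk.exons[1]
    truth = GroundTruth()
    rows = []
    for sample in sorted(config.variant_placement):
        where = config.variant_placement[sample]
        if where not in ("inside", "outside"):
            raise ValueError(f"variant placement must be inside/outside, got {where!r}")
        if where == "inside":
            pos0 = int(rng.integers(e3s, e3e))
        else:
            pos0 = e3e + 1_000 + int(rng.integers(0, 500))
        ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
        rows.append((sk.chrom, pos0 + 1, str(ref), str(alt), sample))
        truth.variant_in_exon_by_sample[sample] = where == "inside"
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample_id"])
    if len(variants):
        variants = variants.astype({"pos": np.int64})
    return variants, truth


# ---------------------------------------------------------------------------
# whole-cohort convenience and on-disk output
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig) -> dict:
    """Run every generator and merge the ground truths."""
    counts, t_counts = simulate_counts(config)
    junctions, coverage, t_junc = simulate_junctions(config)
    dots, t_dots = simulate_dots(config)
    variants, t_var = simulate_variants(config)
    truth = GroundTruth(
        category_by_feature=t_counts.category_by_feature,
        sign_by_feature=t_counts.sign_by_feature,
        size_factors=t_counts.size_factors,
        psi_by_event_group=t_junc.psi_by_event_group,
        skip_fraction_by_sample=t_junc.skip_fraction_by_sample,
        dots_fraction_by_sample=t_dots.dots_fraction_by_sample,
        variant_in_exon_by_sample=t_var.variant_in_exon_by_sample,
    )
    return {"sample_sheet": make_sample_sheet(config), "counts": counts,
            "junctions": junctions, "coverage": coverage,
            "events": event_definitions(config),
            "exon_model": skip_exon_model(config), "dots": dots,
            "variants": variants, "truth": truth}


def truth_table(truth: GroundTruth) -> pd.DataFrame:
    """Flatten the ground truth into one long TSV-able table."""
    rows = [("feature_category", f, c) for f, c in truth.category_by_feature.items()]
    rows += [("feature_sign", f, s) for f, s in truth.sign_by_feature.items()]
    rows += [("psi", f"{ev}:{g}", p)
             for ev, psis in truth.psi_by_event_group.items()
             for g, p in zip(GROUPS, psis)]
    rows += [("skip_fraction", s, f) for s, f in truth.skip_fraction_by_sample.items()]
    rows += [("dots_fraction", s, f) for s, f in truth.dots_fraction_by_sample.items()]
    rows += [("variant_in_exon", s, v)
             for s, v in truth.variant_in_exon_by_sample.items()]
    return pd.DataFrame(rows, columns=["kind", "key", "value"])


def write_simulation(config: SimConfig, outdir: str | os.PathLike) -> dict:
    """Write the full synthetic cohort in the pipeline's input dialects."""
    out = simulate_all(config)
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_sample_sheet(out["sample_sheet"], os.path.join(outdir, "samples.csv"))
    write_count_matrix(out["counts"], os.path.join(outdir, "counts.tsv"))
    junc_dir = os.path.join(outdir, "junctions")
    os.makedirs(junc_dir, exist_ok=True)
    for sample, table in out["junctions"].items():
        write_junction_table(table, os.path.join(junc_dir, f"{sample}.SJ.out.tab"))
    write_results(out["coverage"], os.path.join(outdir, "coverage.tsv"))
    write_results(out["events"], os.path.join(outdir, "events.tsv"))
    write_exon_model(out["exon_model"], os.path.join(outdir, "exons.gtf"))
    write_results(out["dots"], os.path.join(outdir, "dots.csv"))
    write_variant_table(out["variants"], os.path.join(outdir, "variants.vcf"))
    write_results(truth_table(out["truth"]), os.path.join(outdir, "truth.tsv"))
    return out


def null_config(config: SimConfig) -> SimConfig:
    """Same cohort with all planted expression effects removed."""
    return replace(config, effect_log2fc=0.0)
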