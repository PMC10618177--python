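# Methods

This note documents the statistical models, defaults and design decisions
behind each stage. Nothing here states a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and coordinates

All genomic intervals are held internally as 0-based half-open; 1-based
inclusive coordinates exist only at the GTF/VCF/junction-table boundary and
conversion is lossless (property-tested). Splice junctions are
intron-anchored: the two coordinates of the `SJ.out.tab` dialect are the
first and last intron base. Only uniquely mapped junction reads are
consumed; whether multi-mappers should contribute to PSI is an open question
in the field and excluding them is the conservative choice. Region sets may
carry an undefined strand (`.`); junctions may not, since event definitions
and skip calls depend on orientation.

## Synthetic cohort

The generator emulates the three-condition design (RD/FL/HCC, default 5
samples per group) with one RNG stream per data kind spawned from a single
seed (`numpy.random.SeedSequence`), so adding a data kind never perturbs the
draws of another and outputs are bit-reproducible across platforms.

* **Counts**: per feature, counts ~ NB(mean = μ·sf·2^(z·pattern·e),
  var = μ + αμ²) with base mean μ = 100, dispersion α = 0.05, effect
  e = 2 log2 units, log-normal(0, 0.1) size factors and a random sign z per
  feature so both directions are exercised. Pattern vectors over
  (RD, FL, HCC): early (0,1,1), gradual (0,1,2), tumour-specific (0,0,1),
  fatty-liver-specific (0,1,0), switching (0,1,−1), none (0,0,0); 200
  features per category by default. The dispersion, mean and group size are
  chosen as a typical bulk liver RNA-seq regime in which a 4-fold change is
  reliably detectable with 5 animals per group — the recovery tests measure
  exactly that.
* **Junctions**: per event and sample, total reads ~ Poisson(200),
  inclusion ~ Binomial(total, PSI/100), remainder on the exclusion
  junction. The default event mix (40 % constitutive PSI 98, 30 % shared
  intermediate PSI 50, 30 % progression events PSI 95/50/45 over RD/FL/HCC)
  makes the per-sample ASE burden rank HCC ≈ FL > RD. The planted skip
  event writes the three canonical junctions with Poisson rates
  depth·(1−f), depth·(1−f), depth·f (tumour-only f = 0.25 by default) plus
  a full-breadth coverage track over both flanking exons.
* **ISH dots**: per field (10 per sample), total ~ Poisson(200), exclusion
  dots ~ Binomial(total, f) with f = 0.12 in tumours — the magnitude a
  junction-probe assay reports for an exon-exclusion isoform present in a
  quarter of transcripts after probe-efficiency losses, and directly
  testable against the quantifier.
* **Variants**: one SNV per configured sample, inside or outside the target
  exon window, to exercise the mutation-independence check in both
  directions.

What the generator does **not** emulate: per-gene mean–dispersion trends,
correlated features, batch structure, GC/length bias, soft-clipped or
multi-mapped junction evidence, and segmentation noise in dot counting.
Passing recovery tests therefore demonstrate correctness of the inference
under the stated model, not robustness to every artefact of real libraries.

## Differential engine

Median-of-ratios normalisation (per-sample median of count/geometric-mean
over features positive in all samples; a pseudo-count fallback is available
when no such feature exists). Features with a row sum below 10 reads over
all samples are dropped first; the alternative per-sample reading of that
filter is available via a flag but the row-sum reading is standard for the
phrasing. Per feature, the NB dispersion is method-of-moments
((s²−m)/m²) averaged over the two groups and floored at 1e−8 — deliberately
no empirical-Bayes shrinkage, so the engine stays self-contained and every
number is reproducible by hand. The Wald statistic contrasts log group
means with delta-method variance (1/m + α)/n per group.

**p-value reference.** With ~5 samples per group the variance estimate has
few degrees of freedom, and a normal reference makes the test markedly
anti-conservative (empirically ~3–4 % of null features at the 1 % level).
p-values therefore use a Student-t reference with pooled df (n_A + n_B − 2),
which restores calibration: the measured null rate lies inside the 99 %
binomial band around 1 % (see `test_differential.py` and the acceptance
script). Log2 fold-changes add a 0.5-count pseudo-offset so zero rows stay
bounded; the offset does not enter the test statistic except to floor an
exactly-zero group mean. Significance requires p < 0.01 **and**
BH-FDR < 0.01, both strict, ties non-significant.

## Trajectory classifier

A total function over the 27 triples of (FL vs RD, HCC vs RD, HCC vs FL)
statuses, evaluated most-specific-first: switching → tumour-specific →
early → gradual → fatty-liver-specific → none. Resolutions where the prose
definitions overlap:

* *(up, up, ns)* is **early**, not gradual: the change is present in FL and
  merely maintained in HCC.
* *(up, up, up)* is **gradual**: "increasingly dysregulated" is read as the
  HCC-vs-FL step sharing the FL-vs-RD sign.
* Gradual's second clause — significant only over the full RD→HCC span —
  is (FL vs RD = ns) ∧ (HCC vs FL = ns) ∧ (HCC vs RD ≠ ns).
* Tumour-specific requires FL vs RD = ns in addition to both HCC contrasts
  being significant with one sign; otherwise *(up, up, up)* would be
  swallowed by the higher-priority tumour-specific rule.
* A feature with FL vs RD and HCC vs FL significant in opposite directions
  is **switching** only when HCC vs RD opposes FL vs RD; when HCC vs RD
  agrees with (or is weaker than) FL vs RD the profile is an FL-directed
  hump and classifies **fatty-liver-specific**.
* Fatty-liver-specific collects every remaining triple in which FL differs
  from RD, from HCC, or from both; its direction is the FL-relative sign
  (FL vs RD, or the negated HCC vs FL when the former is ns), which is
  internally consistent in every reachable triple.

Direction is `mixed` only for switching; `none` carries the placeholder
direction `none`. The classifier applies unchanged to genes and chromatin
regions. The exhaustive 27-triple table is frozen in the test suite.

## Splicing

PSI = 100·inc/(inc+exc), undefined (NaN) at zero total. Coverage tiers are
a named ladder — N < 10, VLOW 10–14, LOW 15–19, OK 20–99, SOK ≥ 100 total
junction reads — re-specified numerically here since only the tier names
are conventional; the cut-points are configurable. The ASE bounds 10 and
90 are inclusive, consistent with "minimum of VLOW" being inclusive.

Differential splicing draws, per MC iteration, each usable sample's PSI
from Beta(inc+1, exc+1) (posterior under a uniform prior), forms group
means and records ΔPSI. `dpsi_hat` is the mean of the draws; `mv` is the
largest x ≥ 0 exceeded by at least `conf` of |ΔPSI| draws (empirical
(1−conf) quantile, midpoint interpolation). The default differential rule
is |dpsi_hat| > 10 ∧ mv > 0 ∧ sign-consistency of the central conf-level
interval; the alternative reading |dpsi_hat| > max(10, mv) is available as
`rule="exceeds_mv"`. Draws are generated per sample with an event-keyed
seed (SHA-256 of the event id mixed with the run seed), so results are
independent of event order and group swapping negates dPSI exactly.
Defaults: n_mc = 1000, conf = 0.99, min |dPSI| = 10.

## Exon-skip caller

The three canonical junctions are located by exact donor/acceptor match to
the exon model (genomic sorting of the exon trio handles either strand).
Exclusion fraction = skip / (skip + (up+dn)/2): the two inclusion junctions
measure the same isoform, so averaging halves their shot noise (summing is
available via a flag). A positive call requires
(1) ≥ 3 skip-junction reads — a floor standing in for visual
read-level inspection, configurable; (2) flank integrity, ≥ 90 % of the
bases of both neighbouring exons covered at ≥ 1 read — the operational
reading of "whole flanking exons present", thresholds exposed; and (3) no
junction using a splice site strictly inside the target exon (partial
exclusions are a different lesion class). The target exon must be internal.
Mutation independence screens variants against the exon ± 6 bp, covering
the canonical splice-site dinucleotides and near-site positions, so a
splice-site SNV is not certified as "mutation independent" even though it
lies outside the coding exon. Sample classes are assigned in the strict
priority deletion (spanning target and downstream exon) > coding variant in
the target exon > exclusion > wildtype.

## ISH quantification

Field percentage = 100·exc/(exc+inc) dots; sample statistic = unweighted
mean over fields with ≥ 1 dot. Per-field averaging mirrors manual
counting, where each field is one observation; the pooled-count estimator
(identical on fields with equal totals, tested) is available via a flag.
Zero-dot fields are excluded and counted. Group comparison is the same
pooled-variance two-tailed t-test used for ASE burden summaries.

## Region annotation

TSS = strand-aware 5′ end of each gene's first exon. Distance is signed on
the gene strand (negative upstream) and measured from the region midpoint —
one unambiguous number per region; edge-based distance would make the bins
depend on region width. Bins in priority order: |d| < 1 kb promoter,
1–5 kb promoter, exon, intron (midpoint in the gene body), intergenic.
Finer schemes (UTRs, downstream) are deliberately collapsed: the analyses
this feeds quantify only the two promoter bins and intron/intergenic. Ties
in nearest-TSS go to the lexicographically smallest gene id; correctness is
established against a brute-force all-pairs scan on random toy genomes.

## Orchestration and reproducibility

`run_pipeline` executes simulate → differential (3 contrasts) → classify →
splice → skip → ish → annotate → report; any stage error aborts naming the
stage. Every run writes a `report.json` stamped with the SHA-256 hash of
the full configuration and the seed; all randomness flows from that one
seed. Deterministic stages reproduce byte-identically on re-run; the MC
stage reproduces exactly as well because its streams are derived, not
global. Problem sizes in the test and acceptance runs (2000-feature nulls,
500 null splice events at n_mc = 1000, 10⁴ regions for the annotation
oracle) are chosen so each suite documents the statistical property it
checks with comfortable Monte-Carlo margins while completing in seconds.

## Known limitations

* The differential engine fits no covariates, no shrinkage and no outlier
  handling — adequate for a balanced three-group design, not for confounded
  cohorts.
* Splicing models binary inclusion/exclusion events only; complex events
  and de-novo junction discovery are out of scope.
* The skip caller is single-target (loopable); it does not screen
  genome-wide.
* Deletion calls and variants enter as tables; no alignment, peak calling
  or variant calling is performed.
* The minimal-VCF reader supports a non-standard trailing SAMPLE column for
  multi-sample tables; fully general VCF parsing is not attempted.
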