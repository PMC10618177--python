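"""PSI quantification, ASE calling and Monte-Carlo differential splicing.

A binary splice event is summarised per sample by its inclusion and
exclusion junction reads; PSI = 100 * inc / (inc + exc).  An event is an
alternative splice event (ASE) in a sample when its PSI lies in [10, 90]
(inclusive) and the junction coverage reaches at least the VLOW tier.
Coverage tiers follow a named ladder cut at total junction reads:
N < 10 <= VLOW < 15 <= LOW < 20 <= OK < 100 <= SOK.

Differential splicing between two groups uses a beta-binomial Monte Carlo:
per iteration, each sample's PSI is drawn from its posterior
Beta(inc+1, exc+1) (uniform prior), group means are formed, and the dPSI
draw is the difference of group means on the 0-100 scale.  An event is
differential when the mean dPSI exceeds 10 in absolute value and the draws
are sign-consistent at the chosen confidence (99% by default).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SampleSheet

COVERAGE_TIERS = ("N", "VLOW", "LOW", "OK", "SOK")
#: lower bounds (total junction reads) of VLOW / LOW / OK / SOK
TIER_CUTS = (10, 15, 20, 100)

ASE_PSI_LO = 10.0
ASE_PSI_HI = 90.0
MIN_DPSI = 10.0
DEFAULT_CONF = 0.99
DEFAULT_N_MC = 1000

_TIER_RANK = {t: i for i, t in enumerate(COVERAGE_TIERS)}


def coverage_tier(total_reads: int) -> str:
    if total_reads < 0:
        raise ValueError("read count must be non-negative")
    idx = int(np.searchsorted(TIER_CUTS, total_reads, side="right"))
    return COVERAGE_TIERS[idx]


def compute_psi(inc_reads: int, exc_reads: int) -> tuple[float, str]:
    """PSI (0-100) and coverage tier; PSI is NaN when no reads support the event."""
    if inc_reads < 0 or exc_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = inc_reads + exc_reads
    psi = float("nan") if total == 0 else 100.0 * inc_reads / total
    return psi, coverage_tier(total)


def call_ase(psi: float, coverage: str,
             lo: float = ASE_PSI_LO, hi: float = ASE_PSI_HI) -> bool:
    """True iff PSI lies in [lo, hi] (inclusive) with coverage >= VLOW."""
    if coverage not in _TIER_RANK:
        raise ValueError(f"unknown coverage tier {coverage!r}")
    if not np.isfinite(psi):
        return False
    return lo <= psi <= hi and _TIER_RANK[coverage] >= _TIER_RANK["VLOW"]


# ---------------------------------------------------------------------------
# PSI tables from junction evidence
# ---------------------------------------------------------------------------

def psi_table(junction_tables: dict[str, pd.DataFrame],
              events: pd.DataFrame) -> pd.DataFrame:
    """Quantify every event in every sample from raw junction tables.

    ``events`` follows the event-definition dialect (event_id, gene_id,
    chrom, strand, inc1/inc2/exc intron intervals, 0-based half-open); the
    two inclusion junction read counts are summed.  Junctions absent from a
    sample's table count as zero reads.
    """
    rows = []
    for sample_id in sorted(junction_tables):
        table = junction_tables[sample_id]
        lookup = {(r.chrom, int(r.intron_start), int(r.intron_end)): int(r.unique_reads)
                  for r in table.itertuples(index=False)}
        for ev in events.itertuples(index=False):
            inc = (lookup.get((ev.chrom, int(ev.inc1_start), int(ev.inc1_end)), 0)
                   + lookup.get((ev.chrom, int(ev.inc2_start), int(ev.inc2_end)), 0))
            exc = lookup.get((ev.chrom, int(ev.exc_start), int(ev.exc_end)), 0)
            psi, tier = compute_psi(inc, exc)
            rows.append((ev.event_id, ev.gene_id, sample_id, inc, exc, psi, tier))
    return pd.DataFrame(rows, columns=["event_id", "gene_id", "sample_id",
                                       "inc_reads", "exc_reads", "psi", "coverage"])


def summarize_sample(psi_records: pd.DataFrame) -> pd.Series:
    """ASE burden of one sample: event count, genes with an ASE, events/gene.

    With no ASE at all the ratio is reported as 0 with ``no_ase=True``.
    """
    samples = set(psi_records["sample_id"])
    if len(samples) > 1:
        raise ValueError(f"records from multiple samples: {sorted(samples)}")
    is_ase = psi_records.apply(
        lambda r: call_ase(r["psi"], r["coverage"]), axis=1) if len(psi_records) \
        else pd.Series(dtype=bool)
    n_ase = int(is_ase.sum())
    n_genes = psi_records.loc[is_ase, "gene_id"].nunique() if n_ase else 0
    ratio = n_ase / n_genes if n_genes else 0.0
    return pd.Series({
        "sample_id": next(iter(samples)) if samples else "",
        "n_ase": n_ase,
        "n_genes_with_ase": int(n_genes),
        "ase_per_gene": ratio,
        "no_ase": n_ase == 0,
    })


def summarize_all(psi_records: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame([
        summarize_sample(sub) for _, sub in psi_records.groupby("sample_id", sort=True)
    ]).reset_index(drop=True)


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test on two value vectors."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = stats.ttest_ind(b, a, equal_var=True)
    if np.isnan(t):  # zero variance in both groups and equal means
        t, p = 0.0, 1.0
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Monte-Carlo differential splicing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffSpliceResult:
    event_id: str
    group_a: str
    group_b: str
    dpsi_hat: float
    mv: float
    is_differential: bool
    n_a: int
    n_b: int
    defined: bool = True


def _event_rng(seed: int, event_id: str) -> np.random.Generator:
    digest = hashlib.sha256(event_id.encode()).digest()
    child = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence((seed, child)))


def diff_splice_event(records: pd.DataFrame, group_a: str, group_b: str,
                      sheet: SampleSheet, n_mc: int = DEFAULT_N_MC,
                      conf: float = DEFAULT_CONF, min_dpsi: float = MIN_DPSI,
                      seed: int = 0, rule: str = "mv_positive") -> DiffSpliceResult:
    """Beta-binomial Monte-Carlo dPSI for one event between two groups.

    Samples enter only with defined PSI and coverage >= VLOW.  Per MC
    iteration each entering sample contributes a Beta(inc+1, exc+1) PSI
    draw; dPSI draws are (mean of group B) - (mean of group A) on the 0-100
    scale.  ``dpsi_hat`` is their mean; ``mv`` is the largest x >= 0 such
    that at least ``conf`` of the |dPSI| draws exceed x (the empirical
    (1-conf) quantile of |dPSI|, midpoint interpolation).

    ``rule`` picks the differential criterion: ``"mv_positive"`` (default)
    requires |dpsi_hat| > min_dpsi, mv > 0 and the central conf-level dPSI
    interval to exclude zero; ``"exceeds_mv"`` requires
    |dpsi_hat| > max(min_dpsi, mv) with the same sign-consistency.
    """
    if rule not in ("mv_positive", "exceeds_mv"):
        raise ValueError(f"unknown rule {rule!r}")
    event_ids = set(records["event_id"])
    if len(event_ids) != 1:
        raise ValueError("records must describe exactly one event")
    event_id = next(iter(event_ids))

    usable = records[
        np.isfinite(records["psi"])
        & (records["coverage"].map(_TIER_RANK) >= _TIER_RANK["VLOW"])
    ]
    by_sample = usable.set_index("sample_id")
    in_a = sorted(s for s in by_sample.index if sheet.group_of(s) == group_a)
    in_b = sorted(s for s in by_sample.index if sheet.group_of(s) == group_b)
    if not in_a or not in_b:
        return DiffSpliceResult(event_id, group_a, group_b, float("nan"),
                                float("nan"), False, len(in_a), len(in_b),
                                defined=False)

    rng = _event_rng(seed, event_id)
    order = sorted(in_a + in_b)
    inc = by_sample.loc[order, "inc_reads"].to_numpy(dtype=float)
    exc = by_sample.loc[order, "exc_reads"].to_numpy(dtype=float)
    draws = rng.beta(inc + 1.0, exc + 1.0, size=(n_mc, len(order))) * 100.0
    cols = {s: j for j, s in enumerate(order)}
    delta = (draws[:, [cols[s] for s in in_b]].mean(axis=1)
             - draws[:, [cols[s] for s in in_a]].mean(axis=1))

    dpsi_hat = float(delta.mean())
    mv = max(0.0, float(np.quantile(np.abs(delta), 1.0 - conf, method="midpoint")))
    lo = float(np.quantile(delta, (1.0 - conf) / 2.0, method="midpoint"))
    hi = float(np.quantile(delta, 1.0 - (1.0 - conf) / 2.0, method="midpoint"))
    sign_consistent = lo > 0.0 or hi < 0.0

    if rule == "mv_positive":
        is_diff = abs(dpsi_hat) > min_dpsi and mv > 0.0 and sign_consistent
    else:
        is_diff = abs(dpsi_hat) > max(min_dpsi, mv) and sign_consistent
    return DiffSpliceResult(event_id, group_a, group_b, dpsi_hat, mv,
                            is_diff, len(in_a), len(in_b))


def diff_splice(psi_records: pd.DataFrame, group_a: str, group_b: str,
                sheet: SampleSheet, n_mc: int = DEFAULT_N_MC,
                conf: float = DEFAULT_CONF, min_dpsi: float = MIN_DPSI,
                seed: int = 0, rule: str = "mv_positive") -> pd.DataFrame:
    """Run the Monte-Carlo dPSI test for every event in a PSI table."""
    results = [
        diff_splice_event(sub, group_a, group_b, sheet, n_mc=n_mc, conf=conf,
                          min_dpsi=min_dpsi, seed=seed, rule=rule)
        for _, sub in psi_records.groupby("event_id", sort=True)
    ]
    return pd.DataFrame([r.__dict__ for r in results])
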