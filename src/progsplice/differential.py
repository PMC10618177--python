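"""Minimal negative-binomial two-group differential engine.

Applies to gene or chromatin-region count matrices alike.  The model is the
standard NB with variance mu + alpha*mu^2, median-of-ratios normalisation,
per-feature method-of-moments dispersion pooled across the two groups, and a
Wald test on the difference of log group means.  Features pass at
p < 0.01 AND BH-FDR < 0.01 (both strict), after discarding features with
fewer than 10 reads summed over all samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import SampleSheet, validate_count_matrix

P_THRESHOLD = 0.01
FDR_THRESHOLD = 0.01
MIN_TOTAL_READS = 10
LOG2FC_PSEUDOCOUNT = 0.5
MIN_DISPERSION = 1e-8

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"


@dataclass(frozen=True)
class Contrast:
    """Ordered pair of groups; fold-changes are ``b`` over ``a``."""

    a: str
    b: str

    def __str__(self) -> str:
        return f"{self.b}_vs_{self.a}"


def filter_low_counts(counts: pd.DataFrame, min_total: int = MIN_TOTAL_READS,
                      per_sample: bool = False) -> pd.DataFrame:
    """Keep features with at least ``min_total`` reads.

    Default reads the threshold against the row sum over all samples;
    ``per_sample=True`` instead requires ``min_total`` in every sample.
    Feature order is preserved.
    """
    validate_count_matrix(counts)
    if per_sample:
        keep = (counts >= min_total).all(axis=1)
    else:
        keep = counts.sum(axis=1) >= min_total
    return counts.loc[keep]


def estimate_size_factors(counts: pd.DataFrame,
                          pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each feature positive in every sample, form count / geometric mean
    across samples; the per-sample median of those ratios is the factor.
    ``pseudo_reference=True`` falls back to adding one pseudo-count
    everywhere, for matrices where no feature is positive throughout.
    """
    validate_count_matrix(counts)
    x = counts.to_numpy(dtype=float)
    if pseudo_reference:
        x = x + 1.0
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has positive counts in every sample; re-run with "
            "pseudo_reference=True to use a pseudo-count reference"
        )
    ref = x[all_pos]
    geomean = np.exp(np.log(ref).mean(axis=1, keepdims=True))
    factors = np.median(ref / geomean, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(p_values: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_moments(norm: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = norm[:, idx]
    return sub.mean(axis=1), sub.var(axis=1, ddof=1)


def nb_test(counts: pd.DataFrame, group_a: list[str], group_b: list[str],
            size_factors: pd.Series | None = None,
            contrast: Contrast | None = None) -> pd.DataFrame:
    """Per-feature NB Wald test of group B against group A.

    Counts are normalised by the size factors; the pooled method-of-moments
    dispersion alpha solves var = mu + alpha*mu^2 within each group and is
    averaged across the two, floored at 1e-8.  The Wald statistic contrasts
    log group means with variance ``(1/mu_g + alpha) / n_g`` per group; the
    p-value is two-sided normal and the FDR is BH over tested features.

    Returns a DataFrame with columns feature_id, contrast, log2fc, p_value,
    fdr, status.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = [s for s in (*group_a, *group_b) if s not in counts.columns]
    if missing:
        raise ValueError(f"samples absent from count matrix: {missing}")
    if size_factors is None:
        size_factors = estimate_size_factors(counts[list(group_a) + list(group_b)])

    sf = size_factors.reindex(counts.columns)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    ia = np.array([counts.columns.get_loc(s) for s in group_a])
    ib = np.array([counts.columns.get_loc(s) for s in group_b])

    m_a, v_a = _group_moments(norm, ia)
    m_b, v_b = _group_moments(norm, ib)

    eps = LOG2FC_PSEUDOCOUNT
    log2fc = np.log2((m_b + eps) / (m_a + eps))

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = np.where(m_a > 0, (v_a - m_a) / m_a**2, 0.0)
        alpha_b = np.where(m_b > 0, (v_b - m_b) / m_b**2, 0.0)
    alpha = np.maximum((alpha_a + alpha_b) / 2.0, MIN_DISPERSION)

    # Wald on log means; delta-method variance of log(mean of NB draws).
    # The test uses the raw means; an exactly-zero group mean is floored at
    # the pseudocount so the statistic stays finite (and large) there.
    na, nb = len(ia), len(ib)
    ma_t = np.where(m_a > 0, m_a, eps)
    mb_t = np.where(m_b > 0, m_b, eps)
    var_log = (1.0 / ma_t + alpha) / na + (1.0 / mb_t + alpha) / nb
    wald = np.log(mb_t) - np.log(ma_t)
    z = wald / np.sqrt(var_log)
    # Student-t reference with pooled degrees of freedom: the NB variance is
    # itself estimated from the same handful of samples, and a normal
    # reference is badly anti-conservative at cohort sizes of ~5 per group
    p = 2.0 * stats.t.sf(np.abs(z), df=na + nb - 2)
    p = np.clip(p, 0.0, 1.0)
    fdr = bh_adjust(p)

    status = np.where((p < P_THRESHOLD) & (fdr < FDR_THRESHOLD),
                      np.where(log2fc > 0, STATUS_UP, STATUS_DOWN), STATUS_NS)
    # a zero fold-change can never be called
    status = np.where(log2fc == 0, STATUS_NS, status)

    label = str(contrast) if contrast is not None else "B_vs_A"
    return pd.DataFrame({
        "feature_id": counts.index.to_numpy(),
        "contrast": label,
        "log2fc": log2fc,
        "p_value": p,
        "fdr": fdr,
        "status": status,
    })


def run_contrast(counts: pd.DataFrame, sheet: SampleSheet, contrast: Contrast,
                 min_total: int = MIN_TOTAL_READS,
                 size_factors: pd.Series | None = None) -> pd.DataFrame:
    """Filter, normalise and test one named contrast from a sample sheet."""
    kept = filter_low_counts(counts, min_total)
    ga, gb = sheet.samples_in(contrast.a), sheet.samples_in(contrast.b)
    cols = [s for s in sheet.sample_ids if s in set(ga) | set(gb)]
    if size_factors is None:
        size_factors = estimate_size_factors(kept[cols])
    return nb_test(kept, ga, gb, size_factors, contrast)
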