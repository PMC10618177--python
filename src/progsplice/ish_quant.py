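"""Junction-probe RNA-ISH dot quantification (BaseScope-style).

Two probes per section: one spanning the normal E2-E3 junction (inclusion
transcripts) and one spanning the E2-E4 junction (exon-3-excluded
transcripts).  Each dot is one detected transcript.  Quantification is per
microscopy field (10 fields per sample by default): the field-level
exclusion percentage is 100 * exclusion / (exclusion + inclusion) dots, and
the sample statistic is the unweighted mean over fields with at least one
dot (a pooled-count estimator is available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splicing import compare_groups

DEFAULT_N_FIELDS = 10


@dataclass(frozen=True)
class IshSampleResult:
    sample_id: str
    pct_exclusion: float
    n_fields_used: int
    n_fields_excluded: int


def field_pct(dots_inclusion: int, dots_exclusion: int) -> float:
    """Percentage of exclusion-probe dots over total dots in one field."""
    if dots_inclusion < 0 or dots_exclusion < 0:
        raise ValueError("dot counts must be non-negative")
    total = dots_inclusion + dots_exclusion
    if total == 0:
        raise ValueError("field has zero dots; exclude it upstream")
    return 100.0 * dots_exclusion / total


def sample_pct(fields: pd.DataFrame, estimator: str = "mean_of_fields") -> IshSampleResult:
    """Per-sample exclusion percentage from its field table.

    ``fields`` has columns sample_id/field_index/dots_inclusion/
    dots_exclusion.  Zero-dot fields are dropped (their ratio is undefined)
    and counted in ``n_fields_excluded``.  ``estimator`` is
    ``"mean_of_fields"`` (default; each usable field weighs equally, as in
    manual per-field counting) or ``"pooled"`` (dots summed across fields
    first).
    """
    if estimator not in ("mean_of_fields", "pooled"):
        raise ValueError(f"unknown estimator {estimator!r}")
    samples = set(fields["sample_id"])
    if len(samples) != 1:
        raise ValueError(f"expected one sample, got {sorted(samples)}")
    totals = fields["dots_inclusion"] + fields["dots_exclusion"]
    usable = fields[totals > 0]
    if usable.empty:
        raise ValueError(f"sample {next(iter(samples))!r} has no field with dots")
    if estimator == "mean_of_fields":
        pcts = [field_pct(int(r.dots_inclusion), int(r.dots_exclusion))
                for r in usable.itertuples(index=False)]
        pct = float(np.mean(pcts))
    else:
        exc = int(usable["dots_exclusion"].sum())
        inc = int(usable["dots_inclusion"].sum())
        pct = 100.0 * exc / (exc + inc)
    return IshSampleResult(next(iter(samples)), pct, len(usable),
                           len(fields) - len(usable))


def quantify_samples(dots: pd.DataFrame,
                     estimator: str = "mean_of_fields") -> pd.DataFrame:
    """Quantify every sample in a dot-count table."""
    return pd.DataFrame([
        sample_pct(sub, estimator).__dict__
        for _, sub in dots.groupby("sample_id", sort=True)
    ])


def compare_ish_groups(results_a: pd.DataFrame,
                       results_b: pd.DataFrame) -> tuple[float, float]:
    """Pooled-variance two-tailed t-test on sample-level exclusion percentages."""
    return compare_groups(results_a["pct_exclusion"].to_numpy(),
                          results_b["pct_exclusion"].to_numpy())
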