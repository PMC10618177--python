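"""Five-way progression-trajectory classification of differential features.

Each feature carries three pairwise contrast statuses across the disease
course RD -> FL -> HCC: FL vs RD, HCC vs RD, and HCC vs FL, each one of
up/down/ns.  The classifier maps every one of the 27 status triples to
exactly one category:

* **switching** — dysregulated in opposite directions in FL and HCC relative
  to RD (FL-vs-RD and HCC-vs-RD non-ns with opposite signs).
* **tumour_specific** — changed only in tumours: FL-vs-RD ns, while HCC
  differs from both RD and FL in the same direction.
* **early** — the change appears in fatty liver and is maintained in the
  tumour: FL-vs-RD and HCC-vs-RD share a sign and HCC-vs-FL is ns.
* **gradual** — either a change in FL that keeps growing in the same
  direction into HCC (HCC-vs-FL shares the FL-vs-RD sign), or a change
  reaching significance only over the full RD-to-HCC span (HCC-vs-RD non-ns
  with both single steps ns).
* **fatty_liver_specific** — FL differs from RD, from HCC, or from both,
  in every remaining pattern (the FL-elevated/depressed humps).
* **none** — all three contrasts ns.

Rules are evaluated in the priority order listed (most specific first);
direction is the sign of the defining contrasts, ``mixed`` only for
switching.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .differential import STATUS_DOWN, STATUS_NS, STATUS_UP

CATEGORY_ORDER = ("early", "gradual", "tumour_specific",
                  "fatty_liver_specific", "switching", "none")

DIR_ENRICHED = "enriched"
DIR_DEPLETED = "depleted"
DIR_MIXED = "mixed"
#: placeholder direction for category "none" (no defining contrast)
DIR_NONE = "none"

_SIGN = {STATUS_UP: 1, STATUS_DOWN: -1, STATUS_NS: 0}


@dataclass(frozen=True)
class TrajectoryCall:
    feature_id: str
    category: str
    direction: str


def _direction(sign: int) -> str:
    return DIR_ENRICHED if sign > 0 else DIR_DEPLETED


def classify_feature(s_fl_rd: str, s_hcc_rd: str, s_hcc_fl: str,
                     feature_id: str = "") -> TrajectoryCall:
    """Classify one feature from its three contrast statuses.

    Arguments are the statuses of FL vs RD, HCC vs RD and HCC vs FL, each in
    {"up", "down", "ns"}.  Total over all 27 triples.
    """
    for s in (s_fl_rd, s_hcc_rd, s_hcc_fl):
        if s not in _SIGN:
            raise ValueError(f"unknown contrast status {s!r}")
    s1, s2, s3 = _SIGN[s_fl_rd], _SIGN[s_hcc_rd], _SIGN[s_hcc_fl]

    if s1 != 0 and s2 != 0 and s1 == -s2:
        return TrajectoryCall(feature_id, "switching", DIR_MIXED)
    if s1 == 0 and s2 != 0 and s3 != 0 and s2 == s3:
        return TrajectoryCall(feature_id, "tumour_specific", _direction(s2))
    if s1 != 0 and s2 != 0 and s1 == s2 and s3 == 0:
        return TrajectoryCall(feature_id, "early", _direction(s1))
    if s1 != 0 and s3 != 0 and s1 == s3:
        return TrajectoryCall(feature_id, "gradual", _direction(s1))
    if s1 == 0 and s3 == 0 and s2 != 0:
        return TrajectoryCall(feature_id, "gradual", _direction(s2))
    if s1 != 0 or s3 != 0:
        # FL differs from RD, from HCC, or from both; the FL-relative sign
        # (s1 and/or -s3) is consistent in every triple that reaches here
        sign = s1 if s1 != 0 else -s3
        return TrajectoryCall(feature_id, "fatty_liver_specific", _direction(sign))
    return TrajectoryCall(feature_id, "none", DIR_NONE)


def decision_table() -> pd.DataFrame:
    """The full 27-triple decision table, for inspection and testing."""
    rows = []
    for s1, s2, s3 in product((STATUS_UP, STATUS_DOWN, STATUS_NS), repeat=3):
        call = classify_feature(s1, s2, s3)
        rows.append((s1, s2, s3, call.category, call.direction))
    return pd.DataFrame(rows, columns=["FL_vs_RD", "HCC_vs_RD", "HCC_vs_FL",
                                       "category", "direction"])


def classify_all(de_fl_rd: pd.DataFrame, de_hcc_rd: pd.DataFrame,
                 de_hcc_fl: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every feature of three differential result tables.

    The three tables must cover the same feature universe.  Returns
    ``(calls, summary)``: per-feature calls, and a summary holding the
    per-category/per-direction counts plus the pairwise differential totals
    and their intersections (the Venn accounting of a three-way comparison).
    """
    tables = {"FL_vs_RD": de_fl_rd, "HCC_vs_RD": de_hcc_rd, "HCC_vs_FL": de_hcc_fl}
    ids = {name: set(t["feature_id"]) for name, t in tables.items()}
    universe = ids["FL_vs_RD"]
    for name, s in ids.items():
        if s != universe:
            extra = sorted(s - universe) + sorted(universe - s)
            raise ValueError(
                f"feature universes differ (contrast {name}); asymmetric "
                f"difference: {extra[:20]}{'...' if len(extra) > 20 else ''}"
            )

    status = pd.DataFrame({
        name: t.set_index("feature_id")["status"] for name, t in tables.items()
    }).loc[sorted(universe)]

    calls = pd.DataFrame([
        classify_feature(r.FL_vs_RD, r.HCC_vs_RD, r.HCC_vs_FL, fid).__dict__
        for fid, r in zip(status.index, status.itertuples(index=False))
    ])

    cat_counts = (calls.groupby(["category", "direction"]).size()
                  .rename("count").reset_index())
    cat_counts.insert(0, "metric", "category")

    de_sets = {name: set(t.loc[t["status"] != STATUS_NS, "feature_id"])
               for name, t in tables.items()}
    venn_rows = [("venn", name, "", len(s)) for name, s in de_sets.items()]
    venn_rows.append(("venn", "HCC_vs_RD&HCC_vs_FL", "",
                      len(de_sets["HCC_vs_RD"] & de_sets["HCC_vs_FL"])))
    venn_rows.append(("venn", "FL_vs_RD&HCC_vs_RD", "",
                      len(de_sets["FL_vs_RD"] & de_sets["HCC_vs_RD"])))
    venn_rows.append(("venn", "FL_vs_RD&HCC_vs_FL", "",
                      len(de_sets["FL_vs_RD"] & de_sets["HCC_vs_FL"])))
    venn_rows.append(("venn", "all_three", "",
                      len(de_sets["FL_vs_RD"] & de_sets["HCC_vs_RD"]
                          & de_sets["HCC_vs_FL"])))
    venn = pd.DataFrame(venn_rows, columns=["metric", "category", "direction", "count"])

    summary = pd.concat([cat_counts, venn], ignore_index=True)
    return calls, summary


def direction_balance(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-category depleted/enriched percentages among non-mixed calls.

    Returns one row per non-empty category with percentages at one decimal
    plus the compact ``"54/46"``-style label (integers, round half away from
    zero).  Categories with no directional calls are omitted.
    """
    rows = []
    for cat in CATEGORY_ORDER:
        sub = calls.loc[(calls["category"] == cat)
                        & calls["direction"].isin([DIR_ENRICHED, DIR_DEPLETED])]
        n = len(sub)
        if n == 0:
            continue
        dep = int((sub["direction"] == DIR_DEPLETED).sum())
        enr = n - dep
        pct_dep, pct_enr = 100.0 * dep / n, 100.0 * enr / n
        label = f"{_round_half_away(pct_dep)}/{_round_half_away(pct_enr)}"
        rows.append((cat, n, round(pct_dep, 1), round(pct_enr, 1), label))
    return pd.DataFrame(rows, columns=["category", "n", "pct_depleted",
                                       "pct_enriched", "balance"])


def _round_half_away(x: float) -> int:
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0
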