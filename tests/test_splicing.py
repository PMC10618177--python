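"""PSI arithmetic, ASE calling, burden summaries and Monte-Carlo dPSI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import psi_frame
from progsplice import splicing as sp
from progsplice.synthetic_data import (SimConfig, event_definitions,
                                       make_sample_sheet, simulate_junctions)


# ---------------------------------------------------------------------------
# PSI and coverage tiers
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("inc,exc,psi,tier", [
    (30, 10, 75.0, "OK"),
    (0, 50, 0.0, "OK"),
    (7, 2, 700 / 9, "N"),       # total 9: below VLOW
    (10, 0, 100.0, "VLOW"),
    (15, 0, 100.0, "LOW"),
    (60, 40, 60.0, "SOK"),
])
def test_compute_psi_examples(inc, exc, psi, tier):
    got_psi, got_tier = sp.compute_psi(inc, exc)
    assert got_psi == pytest.approx(psi)
    assert got_tier == tier


def test_psi_undefined_on_zero_reads():
    psi, tier = sp.compute_psi(0, 0)
    assert np.isnan(psi) and tier == "N"


@given(inc=st.integers(0, 10**6), exc=st.integers(0, 10**6))
@settings(max_examples=200, deadline=None)
def test_psi_formula_and_symmetry(inc, exc):
    psi, _ = sp.compute_psi(inc, exc)
    if inc + exc == 0:
        assert np.isnan(psi)
    else:
        assert psi == pytest.approx(100.0 * inc / (inc + exc))
        mirror, _ = sp.compute_psi(exc, inc)
        assert psi + mirror == pytest.approx(100.0)


def test_ase_boundary_enumeration():
    """The rule: 10 <= PSI <= 90 (inclusive) and coverage >= VLOW."""
    for psi in (9.99, 10.0, 50.0, 90.0, 90.01):
        for tier in sp.COVERAGE_TIERS:
            expect = (10.0 <= psi <= 90.0) and tier != "N"
            assert sp.call_ase(psi, tier) is expect, (psi, tier)
    assert sp.call_ase(float("nan"), "SOK") is False


def test_ase_monotone_in_coverage():
    for psi in (5.0, 10.0, 50.0, 90.0, 95.0):
        calls = [sp.call_ase(psi, t) for t in sp.COVERAGE_TIERS]
        # upgrading coverage never turns an ASE call off
        assert all(b or not a for a, b in zip(calls, calls[1:]))


# ---------------------------------------------------------------------------
# burden summaries and group comparison
# ---------------------------------------------------------------------------

def test_summarize_sample_counts_genes():
    records = psi_frame([
        ("e1", "g1", "s", 30, 30), ("e2", "g1", "s", 40, 20),
        ("e3", "g2", "s", 50, 50), ("e4", "g3", "s", 100, 0),  # psi 100: not ASE
    ])
    out = sp.summarize_sample(records)
    assert out["n_ase"] == 3 and out["n_genes_with_ase"] == 2
    assert out["ase_per_gene"] == pytest.approx(1.5)
    assert not out["no_ase"]


def test_summarize_sample_no_ase_flagged():
    records = psi_frame([("e1", "g1", "s", 100, 0)])
    out = sp.summarize_sample(records)
    assert out["n_ase"] == 0 and out["ase_per_gene"] == 0.0 and out["no_ase"]


def test_group_burden_ranking_recovered(small_config):
    tables, _, _ = simulate_junctions(small_config)
    events = event_definitions(small_config)
    psi = sp.psi_table(tables, events)
    burden = sp.summarize_all(psi)
    sheet = make_sample_sheet(small_config)
    mean = {g: burden[burden["sample_id"].isin(sheet.samples_in(g))]["n_ase"].mean()
            for g in ("RD", "FL", "HCC")}
    assert mean["FL"] > mean["RD"] and mean["HCC"] > mean["RD"]


def test_pooled_t_matches_closed_form():
    a, b = [2.0, 4.0, 6.0], [8.0, 10.0, 12.0]
    t, p = sp.compare_groups(a, b)
    # hand-computed pooled t: diff 6, pooled var 4, se = 2*sqrt(2/3)
    expect_t = 6.0 / (2.0 * np.sqrt(2.0 / 3.0))
    assert t == pytest.approx(expect_t)
    assert p == pytest.approx(2 * stats.t.sf(expect_t, df=4))


def test_t_identical_groups_and_scale_invariance():
    t, p = sp.compare_groups([3.0, 4.0], [3.0, 4.0])
    assert t == 0.0 and p == 1.0
    t1, _ = sp.compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 7.0])
    t2, _ = sp.compare_groups([10.0, 20.0, 30.0], [40.0, 50.0, 70.0])
    assert t1 == pytest.approx(t2)


def test_t_requires_two_per_group():
    with pytest.raises(ValueError):
        sp.compare_groups([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# Monte-Carlo differential splicing
# ---------------------------------------------------------------------------

def _records(va, vb, sheet):
    rows = [("e", "g", s, inc, exc) for s, (inc, exc) in zip(["A1", "A2", "A3"], va)]
    rows += [("e", "g", s, inc, exc) for s, (inc, exc) in zip(["B1", "B2", "B3"], vb)]
    return psi_frame(rows)


def test_identical_groups_not_differential(two_group_sheet):
    rec = _records([(50, 50)] * 3, [(50, 50)] * 3, two_group_sheet)
    r = sp.diff_splice_event(rec, "RD", "HCC", two_group_sheet, seed=1)
    assert abs(r.dpsi_hat) < 5 and not r.is_differential


def test_extreme_separation_differential(two_group_sheet):
    rec = _records([(100, 0)] * 3, [(0, 100)] * 3, two_group_sheet)
    r = sp.diff_splice_event(rec, "RD", "HCC", two_group_sheet, seed=1)
    assert r.dpsi_hat < -95 and r.is_differential and r.mv > 90


def test_antisymmetry_exact(two_group_sheet):
    rec = _records([(80, 20)] * 3, [(30, 70)] * 3, two_group_sheet)
    fwd = sp.diff_splice_event(rec, "RD", "HCC", two_group_sheet, seed=9)
    rev = sp.diff_splice_event(rec, "HCC", "RD", two_group_sheet, seed=9)
    # per-sample posterior draws are shared, so the negation is exact
    assert fwd.dpsi_hat == pytest.approx(-rev.dpsi_hat, abs=1e-12)
    assert fwd.mv == pytest.approx(rev.mv, abs=1e-12)


def test_consistency_at_high_depth(two_group_sheet):
    """As reads grow with fixed true PSI, dpsi_hat converges to true dPSI."""
    depth = 10_000
    rec = _records([(int(0.7 * depth), int(0.3 * depth))] * 3,
                   [(int(0.4 * depth), int(0.6 * depth))] * 3, two_group_sheet)
    r = sp.diff_splice_event(rec, "RD", "HCC", two_group_sheet, seed=2,
                             n_mc=2000)
    assert r.dpsi_hat == pytest.approx(-30.0, abs=1.0)


def test_low_coverage_samples_excluded_and_flagged(two_group_sheet):
    rec = _records([(3, 2)] * 3, [(2, 3)] * 3, two_group_sheet)  # all below VLOW
    r = sp.diff_splice_event(rec, "RD", "HCC", two_group_sheet, seed=1)
    assert not r.defined and not r.is_differential


def test_null_false_positive_rate(two_group_sheet):
    """Null events (same binomial PSI both groups) are called at ~<=1%."""
    rng = np.random.default_rng(77)
    n_events, n_mc = 200, 400
    rows = []
    for i in range(n_events):
        for s in ("A1", "A2", "A3", "B1", "B2", "B3"):
            inc = rng.binomial(200, 0.5)
            rows.append((f"ev{i:03d}", "g", s, inc, 200 - inc))
    rec = psi_frame(rows)
    out = sp.diff_splice(rec, "RD", "HCC", two_group_sheet, n_mc=n_mc, seed=5)
    rate = out["is_differential"].mean()
    mc_se = np.sqrt(0.01 * 0.99 / n_events)
    assert rate <= 0.01 + 3 * mc_se


def test_rule_variants_exposed(two_group_sheet):
    rec = _records([(100, 0)] * 3, [(0, 100)] * 3, two_group_sheet)
    r = sp.diff_splice_event(rec, "RD", "HCC", two_group_sheet, seed=1,
                             rule="exceeds_mv")
    assert r.is_differential
    with pytest.raises(ValueError, match="rule"):
        sp.diff_splice_event(rec, "RD", "HCC", two_group_sheet, rule="bogus")
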