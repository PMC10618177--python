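"""Targeted exon-skip caller, mutation independence and sample classes."""

import dataclasses
from itertools import product

import numpy as np
import pandas as pd
import pytest

from progsplice import exon_skip as es
from progsplice.io_formats import EXON_COLUMNS, JUNCTION_COLUMNS
from progsplice.synthetic_data import (SimConfig, make_sample_sheet,
                                       simulate_junctions, skip_exon_model)

# toy three-exon gene: E2 [100,200), E3 [300,400), E4 [500,600) on chr1 (+)
MODEL = pd.DataFrame(
    [("g", "t", 2, "chr1", 100, 200, "+"),
     ("g", "t", 3, "chr1", 300, 400, "+"),
     ("g", "t", 4, "chr1", 500, 600, "+")], columns=EXON_COLUMNS)

FULL_COV = pd.DataFrame(
    [("chr1", p, 10) for p in range(100, 600)], columns=["chrom", "pos0", "depth"])


def _junctions(e_up, e_dn, e_skip, extra=()):
    rows = [("chr1", 200, 300, "+", e_up, "s"),
            ("chr1", 400, 500, "+", e_dn, "s"),
            ("chr1", 200, 500, "+", e_skip, "s")]
    rows += list(extra)
    return pd.DataFrame(rows, columns=JUNCTION_COLUMNS)


def test_quarter_exclusion_positive():
    call = es.call_exon_skip(_junctions(30, 30, 10), MODEL, ("g", 3), FULL_COV)
    assert call.exclusion_fraction == pytest.approx(0.25)
    assert call.positive and call.flanks_intact and not call.partial_sites


def test_no_skip_reads_not_positive():
    call = es.call_exon_skip(_junctions(30, 30, 0), MODEL, ("g", 3), FULL_COV)
    assert call.exclusion_fraction == 0.0 and not call.positive


def test_exclusion_fraction_limits():
    assert es.exclusion_fraction(0, 0, 0) == 0.0
    assert es.exclusion_fraction(0, 0, 50) == 1.0
    # sum denominator variant
    assert es.exclusion_fraction(30, 30, 10, denominator="sum") == pytest.approx(10 / 70)


def test_min_skip_reads_threshold():
    call = es.call_exon_skip(_junctions(50, 50, 2), MODEL, ("g", 3), FULL_COV)
    assert not call.positive
    call = es.call_exon_skip(_junctions(50, 50, 3), MODEL, ("g", 3), FULL_COV)
    assert call.positive


def test_partial_site_disqualifies():
    # a junction landing inside E3 (acceptor at 350)
    extra = [("chr1", 200, 350, "+", 9, "s")]
    call = es.call_exon_skip(_junctions(30, 30, 10, extra), MODEL, ("g", 3), FULL_COV)
    assert call.partial_sites and not call.positive


def test_exon_boundary_junctions_are_not_partial():
    # canonical junctions touch exon edges exactly; they must not count
    call = es.call_exon_skip(_junctions(30, 30, 10), MODEL, ("g", 3), FULL_COV)
    assert not call.partial_sites


def test_broken_flank_coverage_disqualifies():
    cov = FULL_COV[FULL_COV["pos0"] < 180]  # 80% of E2 covered, E4 absent
    call = es.call_exon_skip(_junctions(30, 30, 10), MODEL, ("g", 3), cov)
    assert not call.flanks_intact and not call.positive


def test_terminal_exon_rejected():
    with pytest.raises(ValueError, match="terminal"):
        es.call_exon_skip(_junctions(1, 1, 1), MODEL, ("g", 2), FULL_COV)


def test_planted_fraction_recovered_and_controls_negative():
    cfg = SimConfig(seed=13)  # defaults: depth 200, HCC fraction 0.25
    tables, coverage, truth = simulate_junctions(cfg)
    model = skip_exon_model(cfg)
    sheet = make_sample_sheet(cfg)
    target = (cfg.skip_event.gene, cfg.skip_event.target_exon_number)
    fracs = []
    for sample, table in tables.items():
        call = es.call_exon_skip(table, model, target, coverage,
                                 sample_id=sample)
        if sheet.group_of(sample) == "HCC":
            assert call.positive
            fracs.append(call.exclusion_fraction)
        else:
            assert not call.positive and call.e_skip == 0
    n_eff = 200 * len(fracs)  # ~depth reads per sample on the skip junction
    se = np.sqrt(0.25 * 0.75 / n_eff)
    assert np.mean(fracs) == pytest.approx(0.25, abs=3 * se)


# ---------------------------------------------------------------------------
# mutation independence
# ---------------------------------------------------------------------------

def _variant(pos1):
    return pd.DataFrame([("chr1", pos1, "A", "T", "s")],
                        columns=["chrom", "pos", "ref", "alt", "sample_id"])


@pytest.mark.parametrize("pos1,free", [
    (350, False),      # exon midpoint
    (400 + 100, True),   # 100 bp downstream of exon end
    (400 + 6, False),    # pad boundary: still inside
    (400 + 7, True),     # first base beyond the pad
    (300 + 1 - 6, False),  # upstream pad boundary (1-based exon start 301)
    (300 + 1 - 7, True),
])
def test_mutation_independence_pad_boundaries(pos1, free):
    got = es.mutation_independence(_variant(pos1), MODEL, ("g", 3), pad=6)
    assert got is free


def test_mutation_independence_respects_sample_filter():
    v = _variant(350)
    assert es.mutation_independence(v, MODEL, ("g", 3), sample_id="other")
    assert not es.mutation_independence(v, MODEL, ("g", 3), sample_id="s")


# ---------------------------------------------------------------------------
# four-way classification and cohort frequencies
# ---------------------------------------------------------------------------

EMPTY_DELS = pd.DataFrame(columns=["sample_id", "chrom", "start", "end"])
E3E4_DEL = pd.DataFrame([("s", "chr1", 250, 620)],
                        columns=["sample_id", "chrom", "start", "end"])
NO_VARIANTS = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "sample_id"])


def _skip_call(positive):
    junc = _junctions(30, 30, 10 if positive else 0)
    return es.call_exon_skip(junc, MODEL, ("g", 3), FULL_COV)


def test_classification_priority_enumeration():
    """Deletion > exon-3 mutation > exclusion > wildtype, over all flag combos."""
    for has_del, has_mut, skip_pos in product([True, False], repeat=3):
        dels = E3E4_DEL if has_del else EMPTY_DELS
        variants = _variant(350) if has_mut else NO_VARIANTS
        got = es.classify_sample(_skip_call(skip_pos), variants, dels,
                                 MODEL, ("g", 3))
        if has_del:
            expect = es.CLASS_DELETION
        elif has_mut:
            expect = es.CLASS_MUTATION
        elif skip_pos:
            expect = es.CLASS_EXCLUSION
        else:
            expect = es.CLASS_WILDTYPE
        assert got == expect


def test_deletion_must_span_both_exons():
    # deletion of E3 only does not qualify as the E3-E4 deletion class
    del_e3 = pd.DataFrame([("s", "chr1", 290, 410)],
                          columns=["sample_id", "chrom", "start", "end"])
    got = es.classify_sample(_skip_call(True), NO_VARIANTS, del_e3, MODEL, ("g", 3))
    assert got == es.CLASS_EXCLUSION


def test_splice_site_variant_is_not_exon3_mutation_class():
    """A pad-zone variant breaks mutation independence but sits outside the
    coding exon, so the sample still classifies by its skip call."""
    v = _variant(403)  # intronic, within the 6 bp pad
    assert not es.mutation_independence(v, MODEL, ("g", 3))
    got = es.classify_sample(_skip_call(True), v, EMPTY_DELS, MODEL, ("g", 3))
    assert got == es.CLASS_EXCLUSION


@pytest.mark.parametrize("k,n,pct,pct_int", [
    (6, 471, 1.3, 1),
    (10, 44, 22.7, 23),
    (0, 5, 0.0, 0),
])
def test_cohort_frequencies_arithmetic(k, n, pct, pct_int):
    classes = pd.DataFrame({
        "cohort": "c",
        "sample_id": [f"s{i}" for i in range(n)],
        "class": [es.CLASS_EXCLUSION] * k + [es.CLASS_WILDTYPE] * (n - k),
    })
    table = es.cohort_frequencies(classes)
    row = table[(table["class"] == es.CLASS_EXCLUSION)].iloc[0]
    assert (row["k"], row["n"]) == (k, n)
    assert row["percent"] == pytest.approx(pct)
    assert row["percent_int"] == pct_int
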