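"""Determinism and moment checks of the synthetic cohort generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from progsplice.synthetic_data import (CATEGORIES, SimConfig, SkipEventSpec,
                                       default_psi_by_group, event_definitions,
                                       make_sample_sheet, simulate_counts,
                                       simulate_dots, simulate_junctions,
                                       simulate_variants)


def test_same_seed_bitwise_identical(small_config):
    c1, _ = simulate_counts(small_config)
    c2, _ = simulate_counts(small_config)
    pd.testing.assert_frame_equal(c1, c2)
    j1, cov1, _ = simulate_junctions(small_config)
    j2, cov2, _ = simulate_junctions(small_config)
    for s in j1:
        pd.testing.assert_frame_equal(j1[s], j2[s])
    pd.testing.assert_frame_equal(cov1, cov2)
    d1, _ = simulate_dots(small_config)
    d2, _ = simulate_dots(small_config)
    pd.testing.assert_frame_equal(d1, d2)


def test_streams_independent(small_config):
    """Drawing another data kind does not perturb the counts stream."""
    c1, _ = simulate_counts(small_config)
    simulate_dots(small_config)
    c2, _ = simulate_counts(small_config)
    pd.testing.assert_frame_equal(c1, c2)


def test_null_effect_behaves_as_none():
    cfg = SimConfig(seed=5, effect_log2fc=0.0,
                    n_features_per_category={c: 30 for c in CATEGORIES},
                    library_size_sigma=0.0)
    counts, _ = simulate_counts(cfg)
    # no group structure: all per-group means within 5 SE of base_mean
    se = np.sqrt((100 + 0.05 * 100**2) / 5)
    sheet = make_sample_sheet(cfg)
    for g in ("RD", "FL", "HCC"):
        gm = counts[sheet.samples_in(g)].mean(axis=1)
        assert (np.abs(gm - 100) < 5 * se).mean() > 0.99


def test_nb_moments_match_mean_variance_relation():
    """Empirical mean/variance of a "none" feature follow mu + alpha*mu^2."""
    cfg = SimConfig(seed=9, n_features_per_category={"none": 1},
                    n_samples_per_group=3334, library_size_sigma=0.0,
                    base_mean=100.0, nb_dispersion=0.05)
    counts, _ = simulate_counts(cfg)
    x = counts.iloc[0].to_numpy(dtype=float)  # ~10^4 iid draws
    mu, var = x.mean(), x.var(ddof=1)
    se_mean = np.sqrt(var / x.size)
    assert abs(mu - 100.0) < 3 * se_mean
    expected_var = 100 + 0.05 * 100**2
    # chi2-based SE of a sample variance of ~n NB draws
    se_var = expected_var * np.sqrt(2.0 / (x.size - 1)) * 2
    assert abs(var - expected_var) < 4 * se_var


def test_planted_category_patterns(small_config):
    """Mean shifts track the pattern vectors (0,1,1), (0,1,2), ... per group."""
    cfg = dataclasses.replace(small_config, library_size_sigma=0.0,
                              nb_dispersion=0.01)
    counts, truth = simulate_counts(cfg)
    sheet = make_sample_sheet(cfg)
    gm = {g: counts[sheet.samples_in(g)].mean(axis=1) for g in ("RD", "FL", "HCC")}
    for f, cat in truth.category_by_feature.items():
        if cat != "early":
            continue
        z = truth.sign_by_feature[f]
        ratio_fl = gm["FL"][f] / gm["RD"][f]
        assert ratio_fl > 2 if z > 0 else ratio_fl < 0.5


def test_psi_100_means_no_exclusion_reads():
    cfg = SimConfig(seed=2, n_splice_events=3,
                    psi_by_group={"e1": (100.0, 100.0, 100.0),
                                  "e2": (100.0, 100.0, 100.0),
                                  "e3": (100.0, 100.0, 100.0)},
                    n_samples_per_group=2)
    tables, _, _ = simulate_junctions(cfg)
    events = event_definitions(cfg)
    exc = set(zip(events["chrom"], events["exc_start"], events["exc_end"]))
    skip_ev = events.iloc[-1]
    exc.discard((skip_ev["chrom"], skip_ev["exc_start"], skip_ev["exc_end"]))
    for table in tables.values():
        for r in table.itertuples(index=False):
            if (r.chrom, r.intron_start, r.intron_end) in exc:
                assert r.unique_reads == 0


def test_realized_psi_within_binomial_se():
    cfg = SimConfig(seed=4, n_splice_events=1, junction_depth_mean=10_000,
                    psi_by_group={"e1": (50.0, 50.0, 50.0)}, n_samples_per_group=2)
    tables, _, _ = simulate_junctions(cfg)
    ev = event_definitions(cfg).iloc[0]
    for table in tables.values():
        look = {(r.intron_start, r.intron_end): r.unique_reads
                for r in table.itertuples(index=False) if r.chrom == "chrSIM"}
        inc = look[(ev["inc1_start"], ev["inc1_end"])] + look[(ev["inc2_start"], ev["inc2_end"])]
        exc = look[(ev["exc_start"], ev["exc_end"])]
        total = inc + exc
        se = 100 * np.sqrt(0.25 / total)
        assert abs(100 * inc / total - 50) < 3 * se


def test_skip_junction_only_in_hcc(small_config):
    tables, _, truth = simulate_junctions(small_config)
    sk = small_config.skip_event
    sheet = make_sample_sheet(small_config)
    for sample, table in tables.items():
        e24 = table[(table["chrom"] == sk.chrom)
                    & (table["intron_start"] == sk.exons[0][1])
                    & (table["intron_end"] == sk.exons[2][0])]
        reads = int(e24["unique_reads"].iloc[0])
        if sheet.group_of(sample) == "HCC":
            assert reads > 0
        else:
            assert reads == 0
    assert truth.skip_fraction_by_sample["HCC_1"] == 0.25


def test_dots_zero_fraction_and_pooled_recovery():
    cfg = SimConfig(seed=6, dots_lambda=100.0, n_fields=10,
                    dots_exclusion_frac={"RD": 0.0, "FL": 0.0, "HCC": 0.12})
    dots, truth = simulate_dots(cfg)
    rd = dots[dots["sample_id"].str.startswith("RD")]
    assert (rd["dots_exclusion"] == 0).all()
    hcc = dots[dots["sample_id"] == "HCC_1"]
    tot = (hcc["dots_inclusion"] + hcc["dots_exclusion"]).sum()
    frac = hcc["dots_exclusion"].sum() / tot
    se = np.sqrt(0.12 * 0.88 / tot)
    assert abs(frac - 0.12) < 3 * se


def test_variant_placement_inside_outside():
    cfg = SimConfig(seed=8, variant_placement={"HCC_1": "inside", "HCC_2": "outside"})
    variants, truth = simulate_variants(cfg)
    e3s, e3e = cfg.skip_event.exons[1]
    v1 = variants[variants["sample_id"] == "HCC_1"].iloc[0]
    assert e3s < v1["pos"] <= e3e  # 1-based pos inside 0-based half-open exon
    v2 = variants[variants["sample_id"] == "HCC_2"].iloc[0]
    assert v2["pos"] > e3e
    assert truth.variant_in_exon_by_sample == {"HCC_1": True, "HCC_2": False}


def test_config_validation_errors():
    with pytest.raises(ValueError, match="PSI"):
        SimConfig(psi_by_group={"e": (101.0, 50.0, 50.0)})
    with pytest.raises(ValueError, match="base_mean"):
        SimConfig(base_mean=0.0)
    with pytest.raises(ValueError, match="exclusion fraction"):
        SimConfig(skip_event=SkipEventSpec(exclusion_frac={"HCC": 1.5}))


def test_default_event_mix_burden_ranks():
    cfg = SimConfig(n_splice_events=20)
    psi = default_psi_by_group(cfg)
    ase = {g: sum(1 for v in psi.values() if 10 <= v[i] <= 90)
           for i, g in enumerate(("RD", "FL", "HCC"))}
    assert ase["HCC"] == ase["FL"] > ase["RD"]
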