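# progsplice

Desk-scale analysis toolkit for three-state liver disease cohorts
(regular-diet control **RD**, fatty liver **FL**, tumour **HCC**), covering
five computational stages that usually live in ad-hoc study scripts:

1. **Trajectory classification** — every differential feature (gene or
   chromatin region) is assigned one of five progression categories from its
   three pairwise contrast calls (FL vs RD, HCC vs RD, HCC vs FL):
   *early* (changed in FL, maintained in HCC), *gradual* (keeps moving in the
   same direction along RD → FL → HCC), *tumour-specific*,
   *fatty-liver-specific*, and *switching* (opposite directions in FL and
   HCC), plus *none*.
2. **Differential testing** — a self-contained negative-binomial two-group
   engine (median-of-ratios normalisation, method-of-moments dispersion,
   Wald statistic on log group means with a pooled-df Student-t reference);
   features pass at p < 0.01 **and** BH-FDR < 0.01 after a ≥ 10-read row-sum
   filter.
3. **Splicing** — percent-spliced-in quantification from splice-junction
   tables, PSI = 100·inc/(inc+exc); an event is an alternative splice event
   (ASE) in a sample when 10 ≤ PSI ≤ 90 with at least "VLOW" junction
   coverage; group differences are tested with a beta-binomial Monte Carlo:
   per-sample PSI ~ Beta(inc+1, exc+1), dPSI = difference of group means,
   differential when |dPSI| > 10 with sign-consistent draws at 99%
   confidence.
4. **Targeted exon skipping** — a mutation-independent caller for full
   exclusion of one exon (the β-catenin exon-3 archetype, whose loss removes
   the phosphodegron and stabilises the protein): the three canonical
   junctions E2–E3, E3–E4 and E2–E4 are read from the junction table, the
   exclusion fraction is skip/(skip + mean of the two inclusion junctions),
   and a positive call additionally requires intact flanking exons and no
   junction inside the target exon. A variant table is screened against the
   exon ± 6 bp to certify mutation independence, and samples classify
   four ways: deletion > exon-3 mutation > exclusion > wildtype.
5. **ISH dot quantification and region annotation** — junction-probe
   (BaseScope-style) dot counts per microscopy field are converted to a
   per-sample exclusion percentage (mean over fields of
   100·exc/(exc+inc)); chromatin regions are binned by distance of their
   midpoint to the nearest strand-aware TSS (< 1 kb, 1–5 kb, exon, intron,
   intergenic).

A synthetic-data module generates every input with known ground truth
(NB counts with planted trajectories, binomial junction reads with planted
PSI and a tumour-only skip event, Poisson ISH dots, a variant table), so the
whole pipeline is testable end to end without any external data.

## Worked example

```bash
progsplice run --outdir demo --seed 42
```

runs the full pipeline on the default synthetic cohort (5 samples per group,
200 features per trajectory category at 4-fold effects, 60 splice events at
depth 200, a 25 % tumour-only skip fraction and a 12 % tumour ISH exclusion
fraction) and prints

```
report bundle in demo (config hash aa26c455682f823e)
```

`demo/` then contains one table per stage. `demo/report.json` holds the
headline numbers; from a run with seed 42:

```
"stage_record_counts": { "de_FL_vs_RD": 1200, ..., "skip_calls": 15 }
"category_counts": { "early": 204, "gradual": 200, "tumour_specific": 198,
                     "fatty_liver_specific": 203, "switching": 201, "none": 194 }
```

i.e. of 1200 simulated features (200 planted per category) almost all are
recovered in their planted category; the `skip_calls.tsv` table shows every
HCC sample skip-positive with exclusion fractions near 0.25 and every RD/FL
sample negative, and `ish_samples.tsv` shows tumour exclusion percentages
near 12 %.

The same stages are available individually (`progsplice simulate / de /
classify / splice / skip / ish / annotate`) and as library functions, e.g.

```python
from progsplice import compute_psi, classify_feature
compute_psi(30, 10)                  # (75.0, 'OK')
classify_feature("up", "up", "ns")   # early, enriched
```

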