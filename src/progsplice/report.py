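"""End-to-end pipeline orchestration and the cohort-frequency report.

``run_pipeline`` drives the stages in method order — simulate (optional),
differential testing of the three pairwise contrasts, trajectory
classification, splicing (PSI / ASE burden / Monte-Carlo dPSI), targeted
exon-skip calling with mutation-independence, ISH dot quantification, and
region annotation — then writes one results table per stage plus a JSON
report stamped with the config hash and seed.  All randomness flows from
the single config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import (differential, exon_skip, io_formats, ish_quant, regions,
               splicing, synthetic_data, trajectory)
from .differential import Contrast
from .io_formats import write_results
from .synthetic_data import SimConfig

log = logging.getLogger("progsplice")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs.

    With ``simulate=True`` all inputs come from the synthetic generator
    (``sim`` holds its configuration); otherwise the path fields must point
    at existing files in the io_formats dialects.
    """

    outdir: str = "progsplice_out"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)

    # input paths (ignored when simulate=True)
    sample_sheet: str | None = None
    counts: str | None = None
    junction_dir: str | None = None
    events: str | None = None
    coverage: str | None = None
    exons: str | None = None
    variants: str | None = None
    dots: str | None = None
    regions_bed: str | None = None
    deletions: str | None = None

    # thresholds
    min_total_reads: int = differential.MIN_TOTAL_READS
    min_dpsi: float = splicing.MIN_DPSI
    conf: float = splicing.DEFAULT_CONF
    n_mc: int = splicing.DEFAULT_N_MC
    min_skip_reads: int = exon_skip.DEFAULT_MIN_SKIP_READS
    variant_pad: int = exon_skip.DEFAULT_VARIANT_PAD

    @staticmethod
    def from_yaml(path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        skip_raw = sim_raw.pop("skip_event", None)
        if skip_raw is not None:
            skip_raw["exons"] = tuple(tuple(e) for e in skip_raw.get(
                "exons", synthetic_data.SkipEventSpec().exons))
            sim_raw["skip_event"] = synthetic_data.SkipEventSpec(**skip_raw)
        cfg = PipelineConfig(**raw, sim=SimConfig(**sim_raw)) if sim_raw else \
            PipelineConfig(**raw)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(dataclasses.asdict(self)),
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def freq_pct(k: int, n: int, style: str = "exact") -> str:
    """Format k out of n as a percentage in one of the report styles.

    ``approx`` rounds half-away-from-zero to an integer with a "~" prefix
    ("~ 89%"); ``int`` (alias ``exact-int``) the same without the prefix
    ("25%"); ``exact`` keeps one decimal ("1.3%"); ``bound`` floors and
    prefixes ">" ("> 1%").
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    pct = 100.0 * k / n
    if style == "approx":
        return f"~ {int(np.floor(pct + 0.5))}%"
    if style in ("int", "exact-int"):
        return f"{int(np.floor(pct + 0.5))}%"
    if style == "exact":
        return f"{pct:.1f}%"
    if style == "bound":
        return f"> {int(np.floor(pct))}%"
    raise ValueError(f"unknown style {style!r}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return out
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


@_stage("simulate")
def _load_inputs(config: PipelineConfig) -> dict:
    if config.simulate:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        log.info("simulating synthetic cohort (seed %d)", config.seed)
        data = synthetic_data.simulate_all(sim)
        data["regions"] = _demo_regions(data["exon_model"])
        data["deletions"] = pd.DataFrame(
            columns=["sample_id", "chrom", "start", "end"])
        return data
    data = {}
    # each missing input is reported under the stage that consumes it
    required = {"sample_sheet": (config.sample_sheet, "inputs"),
                "counts": (config.counts, "de"),
                "junction_dir": (config.junction_dir, "splice"),
                "events": (config.events, "splice"),
                "coverage": (config.coverage, "skip"),
                "exons": (config.exons, "skip"),
                "dots": (config.dots, "ish")}
    for name, (path, stage) in required.items():
        if path is None or not os.path.exists(path):
            raise PipelineError(f"stage {stage!r} failed: missing input "
                                f"{name!r} ({path})")
    sheet = io_formats.read_sample_sheet(config.sample_sheet)
    data["sample_sheet"] = sheet
    data["counts"] = io_formats.read_count_matrix(config.counts, sheet)
    data["junctions"] = {
        s: io_formats.read_junction_table(
            os.path.join(config.junction_dir, f"{s}.SJ.out.tab"), s)
        for s in sheet.sample_ids}
    data["events"] = pd.read_csv(config.events, sep="\t")
    data["coverage"] = pd.read_csv(config.coverage, sep="\t")
    data["exon_model"] = io_formats.read_exon_model(config.exons)
    data["dots"] = pd.read_csv(config.dots)
    data["variants"] = (io_formats.read_variant_table(config.variants)
                        if config.variants else
                        pd.DataFrame(columns=io_formats.VARIANT_COLUMNS))
    data["regions"] = (io_formats.read_region_set(config.regions_bed)
                       if config.regions_bed else _demo_regions(data["exon_model"]))
    data["deletions"] = (pd.read_csv(config.deletions, sep="\t")
                         if config.deletions else
                         pd.DataFrame(columns=["sample_id", "chrom", "start", "end"]))
    data["truth"] = None
    return data


def _demo_regions(exon_model: pd.DataFrame) -> pd.DataFrame:
    """Small deterministic region set spanning all five genomic bins."""
    genes = regions.gene_table(exon_model)
    g = genes.iloc[0]
    tss = int(g["tss"])
    spots = [("r_prom_near", tss - 400), ("r_prom_far", tss + 3_000),
             ("r_body", (int(g["body_start"]) + int(g["body_end"])) // 2),
             ("r_far", int(g["body_end"]) + 50_000)]
    rows = [(g["chrom"], max(0, p - 100), p + 100, rid, ".", ".")
            for rid, p in spots]
    return pd.DataFrame(rows, columns=io_formats.REGION_COLUMNS)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into ``config.outdir``.

    Returns a dict with the in-memory stage outputs and the report payload.
    """
    os.makedirs(config.outdir, exist_ok=True)
    counts_log: dict[str, int] = {}

    data = _load_inputs(config)
    sheet = data["sample_sheet"]

    # differential testing: the three pairwise contrasts of the design
    contrasts = [Contrast("RD", "FL"), Contrast("RD", "HCC"), Contrast("FL", "HCC")]
    de_tables = {}
    for c in contrasts:
        try:
            de_tables[str(c)] = differential.run_contrast(
                data["counts"], sheet, c, min_total=config.min_total_reads)
        except Exception as exc:
            raise PipelineError(f"stage 'de' failed ({c}): {exc}") from exc
        counts_log[f"de_{c}"] = len(de_tables[str(c)])
        write_results(de_tables[str(c)],
                      os.path.join(config.outdir, f"de_{c}.tsv"))

    try:
        calls, summary = trajectory.classify_all(
            de_tables["FL_vs_RD"], de_tables["HCC_vs_RD"], de_tables["HCC_vs_FL"])
    except Exception as exc:
        raise PipelineError(f"stage 'classify' failed: {exc}") from exc
    counts_log["trajectory"] = len(calls)
    write_results(calls, os.path.join(config.outdir, "trajectory.tsv"))
    write_results(summary, os.path.join(config.outdir, "trajectory_summary.tsv"))

    try:
        psi = splicing.psi_table(data["junctions"], data["events"])
        ase = splicing.summarize_all(psi)
        dsp = pd.concat([
            splicing.diff_splice(psi, "RD", "FL", sheet, n_mc=config.n_mc,
                                 conf=config.conf, min_dpsi=config.min_dpsi,
                                 seed=config.seed),
            splicing.diff_splice(psi, "RD", "HCC", sheet, n_mc=config.n_mc,
                                 conf=config.conf, min_dpsi=config.min_dpsi,
                                 seed=config.seed),
        ], ignore_index=True)
    except Exception as exc:
        raise PipelineError(f"stage 'splice' failed: {exc}") from exc
    counts_log["psi"] = len(psi)
    counts_log["diff_splice"] = len(dsp)
    write_results(psi, os.path.join(config.outdir, "psi.tsv"))
    write_results(ase, os.path.join(config.outdir, "ase_summary.tsv"))
    write_results(dsp, os.path.join(config.outdir, "diff_splice.tsv"))

    sk = config.sim.skip_event if config.simulate else None
    target = (sk.gene, sk.target_exon_number) if sk else \
        (data["exon_model"]["gene_id"].iloc[0], 3)
    try:
        skip_calls = []
        classes = []
        for sample in sheet.sample_ids:
            call = exon_skip.call_exon_skip(
                data["junctions"][sample], data["exon_model"], target,
                data["coverage"], sample_id=sample,
                min_skip_reads=config.min_skip_reads,
                variants=data["variants"], pad=config.variant_pad)
            skip_calls.append(call.__dict__)
            classes.append((sheet.group_of(sample), sample,
                            exon_skip.classify_sample(
                                call, data["variants"], data["deletions"],
                                data["exon_model"], target)))
        skip_df = pd.DataFrame(skip_calls)
        class_df = pd.DataFrame(classes, columns=["cohort", "sample_id", "class"])
        freqs = exon_skip.cohort_frequencies(class_df)
    except Exception as exc:
        raise PipelineError(f"stage 'skip' failed: {exc}") from exc
    counts_log["skip_calls"] = len(skip_df)
    write_results(skip_df, os.path.join(config.outdir, "skip_calls.tsv"))
    write_results(freqs, os.path.join(config.outdir, "cohort_frequencies.tsv"))

    try:
        ish = ish_quant.quantify_samples(data["dots"])
        groups = {g: ish[ish["sample_id"].isin(sheet.samples_in(g))]
                  for g in sheet.groups}
        ish_tests = []
        for a, b in (("RD", "HCC"), ("FL", "HCC")):
            if len(groups.get(a, ())) >= 2 and len(groups.get(b, ())) >= 2:
                t, p = ish_quant.compare_ish_groups(groups[a], groups[b])
                ish_tests.append((f"{b}_vs_{a}", t, p))
    except Exception as exc:
        raise PipelineError(f"stage 'ish' failed: {exc}") from exc
    counts_log["ish_samples"] = len(ish)
    write_results(ish, os.path.join(config.outdir, "ish_samples.tsv"))

    try:
        annot = regions.annotate_regions(data["regions"], data["exon_model"])
    except Exception as exc:
        raise PipelineError(f"stage 'annotate' failed: {exc}") from exc
    counts_log["region_annotation"] = len(annot)
    write_results(annot, os.path.join(config.outdir, "region_annotation.tsv"))

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_record_counts": counts_log,
        "category_counts": {
            cat: int((calls["category"] == cat).sum())
            for cat in trajectory.CATEGORY_ORDER},
        "cohort_frequencies": [
            {"cohort": r.cohort, "class": r["class"], "k": int(r.k),
             "n": int(r.n),
             "freq": freq_pct(int(r.k), int(r.n), "exact")}
            for _, r in freqs.iterrows() if r.k > 0],
        "ish_group_tests": [
            {"contrast": c, "t": t, "p": p} for c, t, p in ish_tests],
    }
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(_as_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", counts_log)

    return {"config": config, "de": de_tables, "trajectory": calls,
            "trajectory_summary": summary, "psi": psi, "ase": ase,
            "diff_splice": dsp, "skip_calls": skip_df, "classes": class_df,
            "cohort_frequencies": freqs, "ish": ish, "annotation": annot,
            "report": report, "truth": data.get("truth")}
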