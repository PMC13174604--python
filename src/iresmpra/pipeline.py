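"""Stage orchestration: simulate -> process -> quant -> stress -> classify -> profile.

Each stage reads its predecessor's TSV artifacts from the output directory
and writes its own, so stages can be rerun individually; rerunning with the
same config and seed is bit-identical. A JSON manifest records the config,
its hash and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, validate_config
from .quant import (
    CountMatrix,
    combine_replicates,
    compute_rpm,
    compute_te,
    filter_low_input,
    replicate_correlation,
)
from .readproc import ReadProcParams, process_samplesheet, read_sample_sheet
from .reference import load_constructs, write_constructs
from .simulate import (
    SimConfig,
    build_truth,
    make_sample_sheet,
    random_library,
    simulate_reads,
)
from .stress import SpikeInSet, adjust_te, differential_te, fit_spikein_factors
from .structfunc import classify_active, compare_gc_groups, gc_pair_fraction, mutagenesis_profile
from .structures import read_structure_file

logger = logging.getLogger(__name__)

STAGES = ("simulate", "process", "quant", "stress", "classify", "profile")


class PipelineError(RuntimeError):
    pass


def _require(path: Path, what: str) -> Path:
    if not Path(path).exists():
        raise PipelineError(f"{what} not found: {path}")
    return Path(path)


def _sim_config(cfg: RunConfig) -> SimConfig:
    s = cfg.simulate
    return SimConfig(
        reads_per_sample=s["n_reads"],
        epsilon=s["epsilon"],
        te_log2_range=tuple(s["te_log2_range"]),
        duplication_mean=s["duplication_mean"],
        abundance_sigma=s["abundance_sigma"],
        spike_ratio=tuple(s["spike_ratio"]),
        spike_fraction=s["spike_fraction"],
        conditions=s["conditions"],
    )


def _load_library(cfg: RunConfig, outdir: Path):
    ref = cfg["reference_fasta"] or (outdir / "library.fasta")
    return load_constructs(_require(Path(ref), "reference FASTA"))


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    s = cfg.simulate
    if cfg["reference_fasta"]:
        library = load_constructs(_require(Path(cfg["reference_fasta"]), "reference FASTA"))
    else:
        library = random_library(s["n_constructs"], s["utr_length"], cfg.seed)
        write_constructs(library, outdir / "library.fasta")
    truth = build_truth(library, _sim_config(cfg), cfg.seed)
    truth.to_tsv(outdir / "truth.tsv")
    sheet = make_sample_sheet(
        list(s["conditions"]), s["n_bio_rep"], s["n_tech_rep"], str(outdir / "reads")
    )
    (outdir / "reads").mkdir(exist_ok=True)
    n_pairs = 0
    for row in sheet.itertuples(index=False):
        n_pairs += simulate_reads(
            truth,
            library,
            row.role,
            row.fastq_r1,
            row.fastq_r2,
            sample_id=row.sample_id,
            condition=row.condition,
            sidecar=str(Path(row.fastq_r1).with_suffix("")) + ".truth.tsv",
        )
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    return {"samples": len(sheet), "read_pairs": n_pairs}


def stage_process(cfg: RunConfig, outdir: Path) -> dict:
    library = _load_library(cfg, outdir)
    sheet_path = cfg["sample_sheet"] or (outdir / "samples.tsv")
    sheet = read_sample_sheet(_require(Path(sheet_path), "sample sheet"))
    p = cfg.parameters
    params = ReadProcParams(
        min_overlap=p["min_overlap"],
        max_mismatch_rate=p["max_mismatch_rate"],
        max_mismatches=p["max_mismatches"],
        error_rate_single=p["error_rate_single"],
        error_rate_paired=p["error_rate_paired"],
    )
    cm, reports = process_samplesheet(sheet, library, params=params)
    cm.to_tsv(outdir / "counts.tsv", outdir / "count_samples.tsv")
    reports.to_csv(outdir / "process_report.tsv", sep="\t", index=False)
    return {"count_rows": len(cm.counts), "reads": int(reports["total"].sum())}


def stage_quant(cfg: RunConfig, outdir: Path) -> dict:
    _require(outdir / "counts.tsv", "counts file")
    cm = CountMatrix.from_tsv(outdir / "counts.tsv", outdir / "count_samples.tsv")
    p = cfg.parameters
    tech = combine_replicates(cm, "technical")
    # replicate QC before the biological sum, when >= 2 bio replicates exist
    qc_rows = []
    for cond in tech.samples["condition"].unique():
        bio_ids = tech.samples.loc[tech.samples["condition"] == cond, "bio_rep"].unique()
        if len(bio_ids) < 2:
            continue
        per_rep = {}
        for b in bio_ids:
            sub_samples = tech.samples[
                (tech.samples["condition"] == cond) & (tech.samples["bio_rep"] == b)
            ]
            sub = CountMatrix(
                tech.counts[tech.counts["sample_id"].isin(sub_samples["sample_id"])],
                sub_samples,
            )
            flags = filter_low_input(sub, p["min_input"])
            rpm = compute_rpm(sub, flags, p["pseudocount"])
            per_rep[f"{cond}_b{b}"] = compute_te(rpm, sub.samples, flags)
        qc_rows.append(replicate_correlation(per_rep))
    if qc_rows:
        pd.concat(qc_rows, ignore_index=True).to_csv(
            outdir / "replicate_qc.tsv", sep="\t", index=False
        )
    combined = combine_replicates(tech, "biological")
    flags = filter_low_input(combined, p["min_input"])
    rpm = compute_rpm(combined, flags, p["pseudocount"])
    te = compute_te(rpm, combined.samples, flags)
    for cond, sub in te.groupby("condition"):
        sub.to_csv(outdir / f"te_{cond}.tsv", sep="\t", index=False)
    te.to_csv(outdir / "te_all.tsv", sep="\t", index=False)
    return {"te_rows": len(te), "conditions": int(te["condition"].nunique())}


def _te_tables(outdir: Path) -> dict[str, pd.DataFrame]:
    te = pd.read_csv(_require(outdir / "te_all.tsv", "TE table"), sep="\t")
    return {str(c): sub.reset_index(drop=True) for c, sub in te.groupby("condition")}


def stage_stress(cfg: RunConfig, outdir: Path) -> dict:
    tables = _te_tables(outdir)
    ref = cfg.parameters["reference_condition"]
    if len(tables) < 2:
        logger.info("stress stage: single condition, nothing to normalize")
        return {"conditions": len(tables)}
    library = _load_library(cfg, outdir)
    spike_ids = library.spike_ids
    if len(spike_ids) != 3:
        raise PipelineError(
            f"stress normalization needs exactly 3 spike_in constructs, found {len(spike_ids)}"
        )
    spikes = fit_spikein_factors(tables, SpikeInSet(tuple(spike_ids)), ref)
    pd.DataFrame(
        [
            {
                "condition": c,
                "factor": spikes.fitted_factor[c],
                "linearity_r2": spikes.linearity_r2.get(c),
            }
            for c in sorted(spikes.fitted_factor)
        ]
    ).to_csv(outdir / "spikein_factors.tsv", sep="\t", index=False)
    adjusted = {c: adjust_te(t, spikes, c) for c, t in tables.items()}
    n_rows = 0
    for cond, t in adjusted.items():
        t.to_csv(outdir / f"te_{cond}_adjusted.tsv", sep="\t", index=False)
    for cond in tables:
        if cond == ref:
            continue
        diff = differential_te(adjusted[ref], adjusted[cond])
        diff.to_csv(outdir / f"differential_{cond}_vs_{ref}.tsv", sep="\t", index=False)
        n_rows += len(diff)
    return {"differential_rows": n_rows, "factors": spikes.fitted_factor}


def stage_classify(cfg: RunConfig, outdir: Path) -> dict:
    tables = _te_tables(outdir)
    ref = cfg.parameters["reference_condition"]
    te = tables[ref] if ref in tables else next(iter(tables.values()))
    calls = classify_active(te, cfg.parameters["threshold_construct"])
    calls.to_csv(outdir / "activity_calls.tsv", sep="\t", index=False)
    out = {"n_active": int(calls["active"].sum()), "n_constructs": len(calls)}
    if cfg["structure_file"]:
        structures = read_structure_file(_require(Path(cfg["structure_file"]), "structure file"))
        fracs = pd.Series(
            {sid: gc_pair_fraction(s) for sid, s in structures.items() if s.pairs},
            name="gc_pct",
        )
        fracs.rename_axis("construct_id").reset_index().to_csv(
            outdir / "gc_fractions.tsv", sep="\t", index=False
        )
        try:
            report = compare_gc_groups(fracs, calls)
        except ValueError as exc:
            logger.warning("GC group comparison skipped: %s", exc)
        else:
            with open(outdir / "gc_comparison.json", "w") as fh:
                json.dump(report, fh, indent=2)
            out["gc_p_value"] = report["p_value"]
    return out


def stage_profile(cfg: RunConfig, outdir: Path) -> dict:
    if not cfg["design_manifest"]:
        logger.info("profile stage: no design manifest configured, skipping")
        return {"windows": 0}
    manifest = pd.read_csv(
        _require(Path(cfg["design_manifest"]), "design manifest"), sep="\t"
    )
    tables = _te_tables(outdir)
    ref = cfg.parameters["reference_condition"]
    te = tables[ref] if ref in tables else next(iter(tables.values()))
    prof = mutagenesis_profile(te, manifest)
    prof["windows"].to_csv(outdir / "mutagenesis_profile.tsv", sep="\t", index=False)
    prof["track"].to_csv(outdir / "mutagenesis_track.tsv", sep="\t", index=False)
    return {"windows": len(prof["windows"]), "min_fold": prof["min_fold"]}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "process": stage_process,
    "quant": stage_quant,
    "stress": stage_stress,
    "classify": stage_classify,
    "profile": stage_profile,
}


def run_pipeline(config, stages=STAGES) -> dict:
    """Run the requested stages in fixed order; returns the manifest dict."""
    cfg = validate_config(config)
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
    manifest = {
        "version": __version__,
        "config": cfg.data,
        "config_sha256": hashlib.sha256(cfg.to_json().encode()).hexdigest(),
        "stages": {},
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("[%s] starting", stage)
        manifest["stages"][stage] = _STAGE_FUNCS[stage](cfg, outdir)
        logger.info("[%s] done: %s", stage, manifest["stages"][stage])
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
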