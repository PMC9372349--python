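"""End-to-end orchestration: classify -> score -> filter -> integrate.

Every run writes its outputs plus a ``manifest.json`` recording the full
configuration, the master seed, the package version and the SHA-256 of each
output file, so any number in the outputs is reproducible from the manifest
alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ChipXpressError, ValidationError
from .expression import activated_for_tss, filter_deregulated
from .io import (
    read_counts,
    read_gene_stats,
    read_gene_table,
    read_narrowpeak,
)
from .peaks import classify_peak_overlap, sqrt_scaled_difference, UNIQUE_MUT
from .tss import (
    ACTIVATED,
    NONREGULATED,
    assign_peaks_to_tss,
    compute_tss_ratios,
    cumulative_curve,
    group_comparison,
    shuffle_null,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run.

    Threshold defaults are the analysis' reference values: >3-fold for the
    deregulated gene lists, >2-fold for the TSS gene set, adjusted p < 0.05,
    mean TPM > 5 in at least one condition, CPM >= 1 low-expression cutoff,
    a +-500 bp TSS window, pseudocount 0.5 CPM, 100 shuffles, top 300 peaks
    with 150 bp flanks for motif windows, and +-1,500 bp summit profiles.
    """

    # inputs
    peaks_wt: str = ""
    peaks_mut: str = ""
    chip_counts: str = ""
    chip_samples: str = ""
    genes: str = ""
    gene_stats: str = ""
    outdir: str = "chipxpress_run"

    # thresholds
    min_overlap_bp: int = 1
    fold_threshold: float = 3.0
    tss_fold_threshold: float = 2.0
    padj_threshold: float = 0.05
    tpm_threshold: float = 5.0
    cpm_threshold: float = 1.0
    tss_window: int = 500
    pseudocount: float = 0.5
    n_shuffles: int = 100
    n_top: int = 300
    flank: int = 150
    span: int = 1500

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def derive_stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _require(path: str, what: str) -> str:
    if not path:
        raise ValidationError(f"no path configured for {what}")
    if not os.path.exists(path):
        raise ChipXpressError(f"missing input file for {what}: {path}")
    return path


def load_chip_counts(counts_path: str, samples_path: str):
    """Read a count table plus its sample sheet (sample, library_size, genotype)."""
    sheet = pd.read_csv(samples_path, sep="\t", comment="#")
    libs = dict(zip(sheet["sample"], sheet["library_size"].astype(int)))
    genotypes = dict(zip(sheet["sample"], sheet["genotype"]))
    return read_counts(counts_path, libs, genotypes)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute classify -> score -> filter -> integrate and write all outputs.

    Returns a summary dict with the key result numbers and output paths.
    """
    os.makedirs(config.outdir, exist_ok=True)
    outputs: dict[str, str] = {}

    def outpath(name: str) -> str:
        outputs[name] = os.path.join(config.outdir, name)
        return outputs[name]

    # ---- load inputs -----------------------------------------------------
    peaks_wt = read_narrowpeak(_require(config.peaks_wt, "wt peaks"))
    peaks_mut = read_narrowpeak(_require(config.peaks_mut, "mut peaks"))
    genes = read_gene_table(_require(config.genes, "gene table"))
    table = load_chip_counts(
        _require(config.chip_counts, "ChIP counts"),
        _require(config.chip_samples, "ChIP sample sheet"),
    )
    stats = read_gene_stats(_require(config.gene_stats, "gene statistics"))
    if "low_expression" in stats.columns:
        stats = stats.loc[~stats["low_expression"].astype(bool)].reset_index(drop=True)
    logger.info(
        "loaded %d wt peaks, %d mut peaks, %d genes, %d tested genes",
        len(peaks_wt), len(peaks_mut), len(genes), len(stats),
    )

    # ---- stage 1: classify ----------------------------------------------
    classification = classify_peak_overlap(peaks_wt, peaks_mut, config.min_overlap_bp)
    class_rows = [
        {"peak_id": pid, "genotype": "wt", "peak_class": cls}
        for pid, cls in classification.labels_wt.items()
    ] + [
        {"peak_id": pid, "genotype": "mut", "peak_class": cls}
        for pid, cls in classification.labels_mut.items()
    ]
    pd.DataFrame(class_rows).to_csv(outpath("peak_classes.tsv"), sep="\t", index=False)
    logger.info("classified peaks: %s", classification.counts())

    # ---- stage 2: score --------------------------------------------------
    classes = dict(classification.labels_wt)
    for pid, cls in classification.labels_mut.items():
        if cls == UNIQUE_MUT:
            classes[pid] = cls
    scores = sqrt_scaled_difference(table, classes=classes)
    pd.DataFrame(
        {
            "peak_id": [s.peak_id for s in scores],
            "d": [s.d for s in scores],
            "peak_class": [s.peak_class or "" for s in scores],
        }
    ).to_csv(outpath("binding_scores.tsv"), sep="\t", index=False)

    # ---- stage 3: filter genes ------------------------------------------
    activated, repressed = filter_deregulated(
        stats,
        fold_threshold=config.fold_threshold,
        padj_threshold=config.padj_threshold,
        tpm_threshold=config.tpm_threshold,
    )
    activated_tss = activated_for_tss(
        stats,
        fold_threshold=config.tss_fold_threshold,
        padj_threshold=config.padj_threshold,
        tpm_threshold=config.tpm_threshold,
    )
    for name, ids in (
        ("activated_genes.txt", activated),
        ("repressed_genes.txt", repressed),
        ("activated_genes_tss.txt", activated_tss),
    ):
        with open(outpath(name), "wt", encoding="utf-8") as fh:
            fh.write("".join(f"{g}\n" for g in ids))
    logger.info(
        "filtered genes: %d activated, %d repressed, %d activated at the TSS cutoff",
        len(activated), len(repressed), len(activated_tss),
    )

    # ---- stage 4: integrate at the TSS ----------------------------------
    assigned = assign_peaks_to_tss(peaks_wt, genes, window=config.tss_window)
    stats_idx = stats.set_index("gene_id")
    tpm_max = stats_idx[["mean_tpm_wt", "mean_tpm_mut"]].max(axis=1)
    log2_cut = np.log2(config.tss_fold_threshold)
    groups: dict[str, str] = {}
    for gene_id in stats_idx.index:
        if gene_id not in assigned:
            continue
        if gene_id in set(activated_tss):
            groups[gene_id] = ACTIVATED
        elif (
            tpm_max[gene_id] > config.tpm_threshold
            and abs(stats_idx.at[gene_id, "log2fc"]) <= log2_cut
            and not bool(stats_idx.at[gene_id, "is_immunoglobulin"])
        ):
            groups[gene_id] = NONREGULATED
    ratios = compute_tss_ratios(assigned, table, groups, pseudocount=config.pseudocount)
    ratio_df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in ratios],
            "cpm_wt_union": [r.cpm_wt_union for r in ratios],
            "cpm_mut_union": [r.cpm_mut_union for r in ratios],
            "r": [r.r for r in ratios],
            "group": [r.group for r in ratios],
        }
    )
    ratio_df.to_csv(outpath("tss_ratios.tsv"), sep="\t", index=False)

    comparison = group_comparison(
        [r.r for r in ratios if r.group == ACTIVATED],
        [r.r for r in ratios if r.group == NONREGULATED],
    )
    summary = {
        "seed": config.seed,
        "n_activated": comparison.n_activated,
        "n_nonregulated": comparison.n_nonregulated,
        "median_activated": comparison.median_activated,
        "median_nonregulated": comparison.median_nonregulated,
        "median_difference": comparison.median_difference,
        "t": comparison.t,
        "p": comparison.p,
    }
    with open(outpath("group_comparison.json"), "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info(
        "group comparison: median r %.3f (activated) vs %.3f (nonregulated), p=%.3g",
        comparison.median_activated, comparison.median_nonregulated, comparison.p,
    )

    expression_diff = {
        r.gene_id: -float(stats_idx.at[r.gene_id, "log2fc"])
        for r in ratios
        if r.group == ACTIVATED
    }
    activated_ratios = [r for r in ratios if r.group == ACTIVATED]
    curve = cumulative_curve(activated_ratios, expression_diff)
    curve = shuffle_null(
        curve,
        n_shuffles=config.n_shuffles,
        seed=derive_stage_seed(config.seed, "shuffle"),
    )
    env = curve.envelope()
    pd.DataFrame(
        {
            "rank": np.arange(1, len(curve.gene_ids) + 1),
            "gene_id": curve.gene_ids,
            "r": curve.ratios,
            "observed": curve.observed,
            "null_p2.5": env[2.5],
            "null_p50": env[50.0],
            "null_p97.5": env[97.5],
        }
    ).to_csv(outpath("cumulative_curve.tsv"), sep="\t", index=False)

    # ---- manifest --------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "shuffle_seed": derive_stage_seed(config.seed, "shuffle"),
        "version": __version__,
        "peak_counts": classification.counts(),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    obs_min, p_low = curve.min_exceedance()
    return {
        "outdir": config.outdir,
        "manifest": manifest_path,
        "classification": classification.counts(),
        "n_activated_genes": len(activated),
        "n_repressed_genes": len(repressed),
        "n_tss_activated_genes": len(activated_tss),
        "comparison": comparison,
        "curve": curve,
        "curve_min": obs_min,
        "curve_min_p": p_low,
    }


def analyze_in_memory(
    peaks_wt,
    peaks_mut,
    genes,
    table,
    stats: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """The pipeline's analysis stages on in-memory objects, no file output.

    Same computation as :func:`run_pipeline` (classification, scoring, gene
    filtering, TSS integration); used for seed sweeps where file round trips
    would dominate the run time.
    """
    config = config or PipelineConfig()
    if "low_expression" in stats.columns:
        stats = stats.loc[~stats["low_expression"].astype(bool)].reset_index(drop=True)

    classification = classify_peak_overlap(peaks_wt, peaks_mut, config.min_overlap_bp)
    classes = dict(classification.labels_wt)
    for pid, cls in classification.labels_mut.items():
        if cls == UNIQUE_MUT:
            classes[pid] = cls
    scores = sqrt_scaled_difference(table, classes=classes)

    activated, repressed = filter_deregulated(
        stats,
        fold_threshold=config.fold_threshold,
        padj_threshold=config.padj_threshold,
        tpm_threshold=config.tpm_threshold,
    )
    activated_tss = activated_for_tss(
        stats,
        fold_threshold=config.tss_fold_threshold,
        padj_threshold=config.padj_threshold,
        tpm_threshold=config.tpm_threshold,
    )

    assigned = assign_peaks_to_tss(peaks_wt, genes, window=config.tss_window)
    stats_idx = stats.set_index("gene_id")
    tpm_max = stats_idx[["mean_tpm_wt", "mean_tpm_mut"]].max(axis=1)
    log2_cut = np.log2(config.tss_fold_threshold)
    activated_tss_set = set(activated_tss)
    groups: dict[str, str] = {}
    for gene_id in stats_idx.index:
        if gene_id not in assigned:
            continue
        if gene_id in activated_tss_set:
            groups[gene_id] = ACTIVATED
        elif (
            tpm_max[gene_id] > config.tpm_threshold
            and abs(stats_idx.at[gene_id, "log2fc"]) <= log2_cut
            and not bool(stats_idx.at[gene_id, "is_immunoglobulin"])
        ):
            groups[gene_id] = NONREGULATED
    ratios = compute_tss_ratios(assigned, table, groups, pseudocount=config.pseudocount)

    comparison = group_comparison(
        [r.r for r in ratios if r.group == ACTIVATED],
        [r.r for r in ratios if r.group == NONREGULATED],
    )
    activated_ratios = [r for r in ratios if r.group == ACTIVATED]
    expression_diff = {
        r.gene_id: -float(stats_idx.at[r.gene_id, "log2fc"]) for r in activated_ratios
    }
    curve = cumulative_curve(activated_ratios, expression_diff)
    curve = shuffle_null(
        curve,
        n_shuffles=config.n_shuffles,
        seed=derive_stage_seed(config.seed, "shuffle"),
    )
    obs_min, p_low = curve.min_exceedance()
    return {
        "classification": classification.counts(),
        "scores": scores,
        "n_activated_genes": len(activated),
        "n_repressed_genes": len(repressed),
        "n_tss_activated_genes": len(activated_tss),
        "ratios": ratios,
        "comparison": comparison,
        "curve": curve,
        "curve_min": obs_min,
        "curve_min_p": p_low,
    }
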