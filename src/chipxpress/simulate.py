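"""Synthetic data generator with coupled binding/expression structure.

The generator emulates the data the pipeline is designed for: a wild-type
(wt) transcription factor peak landscape in which a configurable fraction of
promoter (TSS) peaks collapses to background in the mutant (the
"all-or-nothing" pattern), lognormal peak intensities over a low background,
and negative-binomial expression counts in which genes that lose their TSS
peak are down-regulated by a configurable effect size. Ground truth is
retained for recovery tests.

All randomness derives from a single master seed via spawned child streams,
so e.g. skipping genome-sequence generation changes no other output.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CapacityError, ValidationError
from .expression import benjamini_hochberg
from .io import (
    write_bedgraph,
    write_counts,
    write_fasta,
    write_gene_table,
    write_narrowpeak,
)
from .types import GeneModel, GenomicInterval, Peak, PeakCountTable


@dataclass
class SimulationConfig:
    """All knobs of the synthetic landscape and expression model.

    Defaults describe the reference condition used throughout the test
    suite: 2,000 genes on a 10-Mb genome, 30% of genes TSS-bound, 25% of
    TSS peaks lost in the mutant, a 4-fold expression knock-down
    (``coupling_log2fc = -2``) at genes losing their peak, and 3 RNA
    replicates per genotype.
    """

    # genome / gene layout
    n_chroms: int = 4
    chrom_length_bp: int = 2_500_000
    n_genes: int = 2000
    edge_margin_bp: int = 5000

    # peak landscape
    frac_genes_with_tss_peak: float = 0.30
    frac_tss_peaks_lost: float = 0.25
    n_distal_peaks: int = 800
    n_mut_only_peaks: int = 50
    peak_lognormal_mu: float = math.log(25.0)  # log-CPM of bound peaks
    peak_lognormal_sigma: float = 0.7
    background_cpm: float = 0.25
    tss_summit_jitter_bp: int = 100
    peak_halfwidth_min_bp: int = 100
    peak_halfwidth_max_bp: int = 200

    # ChIP counts
    n_chip_replicates: int = 2
    chip_library_size: int = 10_000_000

    # expression model
    coupling_log2fc: float = -2.0
    graded_coupling: bool = True
    decouple_binding: bool = False
    n_replicates: int = 3
    rna_library_size: int = 5_000_000
    nb_dispersion: float = 0.05
    tpm_lognormal_mu: float = math.log(20.0)
    tpm_lognormal_sigma: float = 1.3
    frac_immunoglobulin: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_genes_with_tss_peak,
            self.frac_tss_peaks_lost,
            self.frac_immunoglobulin,
        )
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValidationError("fractions must lie in [0, 1]")
        positives = (
            self.n_chroms,
            self.chrom_length_bp,
            self.n_genes,
            self.n_chip_replicates,
            self.n_replicates,
            self.chip_library_size,
            self.rna_library_size,
        )
        if any(v <= 0 for v in positives):
            raise ValidationError("counts, lengths and library sizes must be positive")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        if self.coupling_log2fc > 0:
            raise ValidationError("coupling_log2fc must be <= 0")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names}


@dataclass
class GroundTruth:
    """Per-gene and per-peak ground truth for recovery tests.

    ``genes`` is indexed by gene_id with columns has_tss_peak,
    tss_peak_lost, is_deregulated, true_log2fc, is_immunoglobulin;
    ``peaks`` is indexed by peak_id with column true_class.
    """

    genes: pd.DataFrame
    peaks: pd.DataFrame


@dataclass
class Landscape:
    config: SimulationConfig
    genes: list[GeneModel]
    peaks_wt: list[Peak]
    peaks_mut: list[Peak]
    counts: PeakCountTable
    truth: GroundTruth
    #: true mean CPM per region and genotype (columns wt, mut)
    true_cpm: pd.DataFrame
    genome: Optional[dict[str, str]] = None


def _spawned_rngs(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _place_genes(config: SimulationConfig, rng: np.random.Generator,
                 ig_mask: np.ndarray) -> list[GeneModel]:
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    idx = 0
    for chrom, n_here in zip(config.chrom_names, per_chrom):
        cursor = config.edge_margin_bp
        for _ in range(n_here):
            gap = int(rng.integers(500, 1500))
            body_len = int(rng.integers(1000, 3000))
            start = cursor + gap
            end = start + body_len
            if end > config.chrom_length_bp - config.edge_margin_bp:
                raise CapacityError(
                    f"cannot place {config.n_genes} genes on "
                    f"{config.n_chroms} x {config.chrom_length_bp} bp"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            genes.append(
                GeneModel(
                    gene_id=f"gene_{idx:05d}",
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    body=GenomicInterval(chrom, start, end, strand),
                    is_immunoglobulin=bool(ig_mask[idx]),
                )
            )
            cursor = end
            idx += 1
    return genes


def _peak_score(cpm: float) -> float:
    # Monotone stand-in for a caller's -log10 p significance.
    return round(10.0 + 25.0 * math.log10(1.0 + cpm), 3)


def _make_peak(chrom: str, summit: int, half_lo: int, half_hi: int,
               cpm: float, peak_id: str, rng: np.random.Generator) -> Peak:
    left = int(rng.integers(half_lo, half_hi + 1))
    right = int(rng.integers(half_lo, half_hi + 1))
    return Peak(
        interval=GenomicInterval(chrom, summit - left, summit + right),
        summit=summit,
        score=_peak_score(cpm),
        peak_id=peak_id,
    )


def simulate_landscape(
    config: SimulationConfig, with_sequence: bool = True
) -> Landscape:
    """Generate genes, wt/mut peak sets, a ChIP count table and ground truth.

    Genes are placed non-overlapping with a margin; a fraction receives a
    TSS peak (summit within +-``tss_summit_jitter_bp`` of the TSS); of
    those, ``frac_tss_peaks_lost`` are unique to wt (the mutant draws
    background-level counts and the peak is not emitted in the mutant peak
    file). Distal peaks are placed away from any TSS window and are common
    to both genotypes; a small mutant-only set mirrors gained peaks. Counts
    are Poisson around CPM x library / 1e6 per replicate. Fully
    deterministic given ``config.seed``.
    """
    rng_seq, rng_layout, rng_intensity, rng_counts, _, rng_flags = _spawned_rngs(
        config.seed, 6
    )

    ig_mask = rng_flags.random(config.n_genes) < config.frac_immunoglobulin
    genes = _place_genes(config, rng_layout, ig_mask)

    n_bound = int(round(config.frac_genes_with_tss_peak * config.n_genes))
    bound_idx = np.sort(rng_layout.choice(config.n_genes, size=n_bound, replace=False))
    n_lost = int(round(config.frac_tss_peaks_lost * n_bound))
    lost_idx = np.sort(rng_layout.choice(bound_idx, size=n_lost, replace=False))
    lost_set = set(lost_idx.tolist())

    peaks_wt: list[Peak] = []
    peaks_mut: list[Peak] = []
    rows = []  # (peak_id, true_class, cpm_wt, cpm_mut)
    half_lo, half_hi = config.peak_halfwidth_min_bp, config.peak_halfwidth_max_bp

    gene_peak: dict[int, str] = {}
    for gi in bound_idx.tolist():
        g = genes[gi]
        pid = f"peak_tss_{gi:05d}"
        jit = int(rng_layout.integers(-config.tss_summit_jitter_bp,
                                      config.tss_summit_jitter_bp + 1))
        intensity = float(rng_intensity.lognormal(config.peak_lognormal_mu,
                                                  config.peak_lognormal_sigma))
        peak = _make_peak(g.chrom, g.tss + jit, half_lo, half_hi, intensity, pid,
                          rng_layout)
        peaks_wt.append(peak)
        gene_peak[gi] = pid
        if gi in lost_set:
            rows.append((pid, "unique_wt", intensity, config.background_cpm))
        else:
            peaks_mut.append(peak)
            rows.append((pid, "common", intensity, intensity))

    # distal peaks, kept clear of every TSS window
    tss_by_chrom: dict[str, np.ndarray] = {
        chrom: np.sort(np.array([g.tss for g in genes if g.chrom == chrom]))
        for chrom in config.chrom_names
    }
    clearance = 1500 + half_hi
    placed = 0
    lo = config.edge_margin_bp
    hi = config.chrom_length_bp - config.edge_margin_bp
    while placed < config.n_distal_peaks + config.n_mut_only_peaks:
        chrom = config.chrom_names[int(rng_layout.integers(config.n_chroms))]
        pos = int(rng_layout.integers(lo, hi))
        tss_arr = tss_by_chrom[chrom]
        j = np.searchsorted(tss_arr, pos)
        near = min(
            abs(pos - int(tss_arr[j - 1])) if j > 0 else 10**9,
            abs(int(tss_arr[j]) - pos) if j < tss_arr.size else 10**9,
        )
        if near < clearance:
            continue
        intensity = float(rng_intensity.lognormal(config.peak_lognormal_mu,
                                                  config.peak_lognormal_sigma))
        if placed < config.n_distal_peaks:
            pid = f"peak_distal_{placed:05d}"
            peak = _make_peak(chrom, pos, half_lo, half_hi, intensity, pid, rng_layout)
            peaks_wt.append(peak)
            peaks_mut.append(peak)
            rows.append((pid, "common", intensity, intensity))
        else:
            pid = f"peak_mutonly_{placed - config.n_distal_peaks:05d}"
            peak = _make_peak(chrom, pos, half_lo, half_hi, intensity, pid, rng_layout)
            peaks_mut.append(peak)
            rows.append((pid, "unique_mut", config.background_cpm, intensity))
        placed += 1

    true_cpm = pd.DataFrame(
        {
            "wt": [r[2] for r in rows],
            "mut": [r[3] for r in rows],
        },
        index=pd.Index([r[0] for r in rows], name="peak_id"),
    )
    truth_peaks = pd.DataFrame(
        {"true_class": [r[1] for r in rows]},
        index=true_cpm.index,
    )

    # ChIP counts: Poisson around CPM x library / 1e6 per replicate
    counts = {}
    scale = config.chip_library_size / 1e6
    for gt in ("wt", "mut"):
        lam = true_cpm[gt].to_numpy() * scale
        for rep in range(1, config.n_chip_replicates + 1):
            counts[f"{gt}_{rep}"] = rng_counts.poisson(lam)
    count_df = pd.DataFrame(counts, index=true_cpm.index)
    table = PeakCountTable(
        count_df,
        library_sizes={s: config.chip_library_size for s in count_df.columns},
        genotypes={s: s.split("_")[0] for s in count_df.columns},
    )

    # gene-level truth, incl. which genes carry the expression effect
    has_peak = np.zeros(config.n_genes, dtype=bool)
    has_peak[bound_idx] = True
    peak_lost = np.zeros(config.n_genes, dtype=bool)
    peak_lost[lost_idx] = True
    if config.decouple_binding:
        dereg_idx = np.sort(rng_layout.choice(bound_idx, size=n_lost, replace=False))
    else:
        dereg_idx = lost_idx
    deregulated = np.zeros(config.n_genes, dtype=bool)
    deregulated[dereg_idx] = True

    # Per-gene expression effect. With graded coupling the knock-down scales
    # with (log) peak intensity, so stronger-bound promoters lose more
    # expression -- the rank correlation the cumulative-curve statistic
    # detects. coupling_log2fc is the effect at the typical bound intensity
    # exp(peak_lognormal_mu). In the decoupled null regime the grading
    # intensity is drawn afresh, independent of the gene's own peak, so the
    # effect-size distribution is unchanged while binding and expression stay
    # independent.
    ref = math.log2(1.0 + math.exp(config.peak_lognormal_mu))
    true_log2fc = np.zeros(config.n_genes)
    for gi in dereg_idx.tolist():
        if not config.graded_coupling:
            scale = 1.0
        elif config.decouple_binding:
            scale = (
                math.log2(1.0 + rng_intensity.lognormal(
                    config.peak_lognormal_mu, config.peak_lognormal_sigma)) / ref
            )
        else:
            scale = math.log2(1.0 + float(true_cpm.at[gene_peak[gi], "wt"])) / ref
        true_log2fc[gi] = config.coupling_log2fc * scale

    truth_genes = pd.DataFrame(
        {
            "has_tss_peak": has_peak,
            "tss_peak_lost": peak_lost,
            "is_deregulated": deregulated,
            "true_log2fc": true_log2fc,
            "is_immunoglobulin": ig_mask,
            "tss_peak_id": [gene_peak.get(i, "") for i in range(config.n_genes)],
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )

    genome = None
    if with_sequence:
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        genome = {
            chrom: alphabet[rng_seq.integers(0, 4, size=config.chrom_length_bp)]
            .tobytes()
            .decode("ascii")
            for chrom in config.chrom_names
        }

    return Landscape(
        config=config,
        genes=genes,
        peaks_wt=peaks_wt,
        peaks_mut=peaks_mut,
        counts=table,
        truth=GroundTruth(genes=truth_genes, peaks=truth_peaks),
        true_cpm=true_cpm,
        genome=genome,
    )


@dataclass
class ExpressionResult:
    """Synthetic per-gene expression: stats table plus per-sample matrices."""

    stats: pd.DataFrame
    tpm: pd.DataFrame
    counts: pd.DataFrame


def simulate_expression(config: SimulationConfig, truth: GroundTruth) -> ExpressionResult:
    """Negative-binomial expression counts plus a stand-in DE statistics table.

    Baseline expression is lognormal across genes; genes flagged deregulated
    in the truth have their mutant mean scaled by ``2**coupling_log2fc``.
    Per-gene raw p-values come from a two-sample t test on log2 TPM (a
    deliberately simple stand-in — the pipeline's filters only need
    plausible (p, log2fc, TPM) triples), adjusted by Benjamini-Hochberg over
    the genes passing the low-expression filter.
    """
    rngs = _spawned_rngs(config.seed, 6)
    rng = rngs[4]  # expression stream; landscape streams untouched

    gene_ids = truth.genes.index.to_numpy()
    n = gene_ids.size
    base = rng.lognormal(config.tpm_lognormal_mu, config.tpm_lognormal_sigma, size=n)
    mean_wt = base
    mean_mut = base * np.power(2.0, truth.genes["true_log2fc"].to_numpy())

    disp = config.nb_dispersion
    nb_n = 1.0 / disp
    scale = config.rna_library_size / 1e6

    def draw(mean_vec: np.ndarray) -> np.ndarray:
        mu = np.maximum(mean_vec * scale, 1e-12)
        p = nb_n / (nb_n + mu)
        return rng.negative_binomial(nb_n, p, size=mu.size)

    cols = {}
    for gt, mean_vec in (("wt", mean_wt), ("mut", mean_mut)):
        for rep in range(1, config.n_replicates + 1):
            cols[f"{gt}_{rep}"] = draw(mean_vec)
    count_df = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    tpm_df = count_df / config.rna_library_size * 1e6

    wt_cols = [c for c in tpm_df.columns if c.startswith("wt")]
    mut_cols = [c for c in tpm_df.columns if c.startswith("mut")]
    obs_wt = tpm_df[wt_cols].mean(axis=1).to_numpy()
    obs_mut = tpm_df[mut_cols].mean(axis=1).to_numpy()
    log2fc = np.log2((obs_mut + 0.5) / (obs_wt + 0.5))

    log_mut = np.log2(tpm_df[mut_cols].to_numpy() + 0.5)
    log_wt = np.log2(tpm_df[wt_cols].to_numpy() + 0.5)
    with warnings.catch_warnings():
        # near-identical replicates trip scipy's precision-loss warning;
        # the resulting NaN p-values are set to 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = sps.ttest_ind(log_mut, log_wt, axis=1)
    p_raw = np.where(np.isnan(t_res.pvalue), 1.0, t_res.pvalue)

    retained = (tpm_df >= 1.0).any(axis=1).to_numpy()  # CPM >= 1 in >= 1 sample
    p_adj = np.full(n, np.nan)
    if retained.any():
        p_adj[retained] = benjamini_hochberg(p_raw[retained])

    stats = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mean_tpm_wt": obs_wt,
            "mean_tpm_mut": obs_mut,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "is_immunoglobulin": truth.genes["is_immunoglobulin"].to_numpy(),
            "low_expression": ~retained,
        }
    )
    return ExpressionResult(stats=stats, tpm=tpm_df, counts=count_df)


def simulate_coverage(landscape: Landscape, genotype: str) -> dict[str, np.ndarray]:
    """Per-base coverage arrays with a triangular pileup at each peak.

    Each peak contributes a symmetric triangle around its summit spanning its
    interval, with apex height proportional to its true CPM; a noise-free
    idealization adequate for summit-profile demonstrations and tests.
    """
    if genotype not in ("wt", "mut"):
        raise ValidationError("genotype must be 'wt' or 'mut'")
    arrays = {
        chrom: np.zeros(length, dtype=np.float64)
        for chrom, length in landscape.config.chrom_lengths.items()
    }
    peaks = landscape.peaks_wt if genotype == "wt" else landscape.peaks_mut
    for p in peaks:
        cpm = float(landscape.true_cpm.at[p.peak_id, genotype])
        half = max(p.summit - p.start, p.end - p.summit)
        pos = np.arange(p.summit - half, p.summit + half)
        tri = cpm * (1.0 - np.abs(pos - p.summit) / half)
        lo = max(0, pos[0])
        hi = min(arrays[p.chrom].size, pos[-1] + 1)
        arrays[p.chrom][lo:hi] += tri[(lo - pos[0]) : (hi - pos[0])]
    return arrays


def coverage_to_bedgraph(per_base: dict[str, np.ndarray], path: str | os.PathLike) -> None:
    """Run-length-encode per-base coverage into a 4-column bedGraph."""
    intervals = []
    for chrom in sorted(per_base):
        arr = per_base[chrom]
        if arr.size == 0:
            continue
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [arr.size]])
        for s, e in zip(starts, ends):
            if arr[s] != 0.0:
                intervals.append((chrom, int(s), int(e), float(arr[s])))
    write_bedgraph(intervals, path)


def write_landscape(
    landscape: Landscape, outdir: str | os.PathLike, write_genome: bool = True
) -> dict[str, str]:
    """Write every landscape artefact in the formats the pipeline consumes."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genes": os.path.join(outdir, "genes.bed"),
        "peaks_wt": os.path.join(outdir, "peaks_wt.narrowPeak"),
        "peaks_mut": os.path.join(outdir, "peaks_mut.narrowPeak"),
        "chip_counts": os.path.join(outdir, "chip_counts.tsv"),
        "chip_samples": os.path.join(outdir, "chip_samples.tsv"),
        "truth_genes": os.path.join(outdir, "truth_genes.tsv"),
        "truth_peaks": os.path.join(outdir, "truth_peaks.tsv"),
    }
    write_gene_table(landscape.genes, paths["genes"])
    sig_wt = landscape.true_cpm["wt"].to_dict()
    sig_mut = landscape.true_cpm["mut"].to_dict()
    write_narrowpeak(landscape.peaks_wt, paths["peaks_wt"], signal=sig_wt)
    write_narrowpeak(landscape.peaks_mut, paths["peaks_mut"], signal=sig_mut)
    write_counts(landscape.counts, paths["chip_counts"])
    samples = pd.DataFrame(
        {
            "sample": landscape.counts.samples,
            "library_size": [
                landscape.counts.library_sizes[s] for s in landscape.counts.samples
            ],
            "genotype": [
                landscape.counts.genotypes[s] for s in landscape.counts.samples
            ],
        }
    )
    samples.to_csv(paths["chip_samples"], sep="\t", index=False)
    landscape.truth.genes.to_csv(paths["truth_genes"], sep="\t")
    landscape.truth.peaks.to_csv(paths["truth_peaks"], sep="\t")
    if write_genome and landscape.genome is not None:
        paths["genome"] = os.path.join(outdir, "genome.fa")
        write_fasta(landscape.genome.items(), paths["genome"])
    return paths


def write_expression(expr: ExpressionResult, outdir: str | os.PathLike) -> dict[str, str]:
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "gene_stats": os.path.join(outdir, "gene_stats.tsv"),
        "rna_tpm": os.path.join(outdir, "rna_tpm.tsv"),
        "rna_counts": os.path.join(outdir, "rna_counts.tsv"),
    }
    expr.stats.to_csv(paths["gene_stats"], sep="\t", index=False)
    expr.tpm.to_csv(paths["rna_tpm"], sep="\t")
    expr.counts.to_csv(paths["rna_counts"], sep="\t")
    return paths
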