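"""Core domain types: genomic intervals, peaks, gene models and count tables.

Coordinate convention
---------------------
All coordinates in this package are **0-based, half-open** ``[start, end)``,
the BED/narrowPeak convention. A transcription start site (TSS) is a single
base position: ``start`` for a ``+``-strand gene and ``end - 1`` for a
``-``-strand gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

STRANDS = ("+", "-", ".")
GENOTYPES = ("wt", "mut")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A called peak: interval, summit position and caller significance score.

    ``score`` is interpreted as the caller's significance (e.g. -log10 p);
    ``summit`` is an absolute base position inside the interval.
    """

    interval: GenomicInterval
    summit: int
    score: float
    peak_id: str

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"peak {self.peak_id}: summit {self.summit} outside "
                f"[{self.interval.start},{self.interval.end})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with its strand-dependent TSS and optional body interval."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: Optional[GenomicInterval] = None
    is_immunoglobulin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.body is not None:
            expected = self.body.start if self.strand == "+" else self.body.end - 1
            if self.tss != expected:
                raise ValidationError(
                    f"gene {self.gene_id}: TSS {self.tss} inconsistent with "
                    f"{self.strand} strand body [{self.body.start},{self.body.end})"
                )


@dataclass(frozen=True)
class BindingDifferenceScore:
    """Square-root-scaled CPM difference for one peak.

    ``d = sqrt(cpm_mut / mean_mut) - sqrt(cpm_wt / mean_wt)`` where the CPM
    values are replicate-averaged within genotype and the means are taken over
    all scored peaks within each genotype. Negative ``d`` means binding lost
    in the mutant.
    """

    peak_id: str
    d: float
    peak_class: Optional[str] = None  # common / unique_wt / unique_mut


class PeakCountTable:
    """Per-peak raw read counts with explicit library sizes and genotypes.

    Library sizes are supplied by the caller (total mapped reads) rather than
    inferred from column sums: per-peak tables cannot recover the genome-wide
    totals that CPM is defined against.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        library_sizes: Mapping[str, int],
        genotypes: Mapping[str, str],
    ) -> None:
        if counts.index.has_duplicates:
            raise ValidationError("duplicate peak_id in count table")
        if counts.isna().any().any():
            raise ValidationError("missing cells in count table (no imputation)")
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative count in count table")
        for sample in counts.columns:
            if sample not in library_sizes:
                raise ConfigurationError(f"sample {sample!r} has no library size")
            if sample not in genotypes:
                raise ConfigurationError(f"sample {sample!r} has no genotype")
            if genotypes[sample] not in GENOTYPES:
                raise ConfigurationError(
                    f"sample {sample!r}: genotype must be one of {GENOTYPES}"
                )
            if library_sizes[sample] <= 0:
                raise ValidationError(f"sample {sample!r}: library size must be > 0")
        self.counts = counts.astype(np.int64)
        self.library_sizes = {s: int(library_sizes[s]) for s in counts.columns}
        self.genotypes = {s: genotypes[s] for s in counts.columns}

    @property
    def peak_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def cpm(self) -> pd.DataFrame:
        """Counts per million: count / library_size * 1e6, per sample."""
        libs = pd.Series(self.library_sizes, dtype=float)
        return self.counts / libs * 1e6

    def genotype_mean_cpm(self) -> pd.DataFrame:
        """Replicate-averaged CPM per genotype; columns 'wt' and 'mut'."""
        cpm = self.cpm()
        out = {}
        for gt in GENOTYPES:
            cols = [s for s in cpm.columns if self.genotypes[s] == gt]
            if not cols:
                raise ConfigurationError(f"no samples for genotype {gt!r}")
            out[gt] = cpm[cols].mean(axis=1)
        return pd.DataFrame(out)


#: Required columns of a per-gene differential-expression statistics table.
GENE_STAT_COLUMNS = (
    "gene_id",
    "mean_tpm_wt",
    "mean_tpm_mut",
    "log2fc",
    "p_raw",
    "p_adj",
    "is_immunoglobulin",
)


def validate_gene_stats(stats: pd.DataFrame, require_finite_fc: bool = True) -> None:
    """Validate a gene statistics table against the documented schema.

    ``log2fc`` is mutant over wild type. ``p_adj`` may contain NaN for genes
    excluded from testing (e.g. low expression); such genes never pass filters.
    """
    missing = [c for c in GENE_STAT_COLUMNS if c not in stats.columns]
    if missing:
        raise ValidationError(f"gene stats table missing columns: {missing}")
    if stats["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in gene stats table")
    if (stats[["mean_tpm_wt", "mean_tpm_mut"]].to_numpy() < 0).any():
        raise ValidationError("negative TPM in gene stats table")
    for col in ("p_raw", "p_adj"):
        vals = stats[col].to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValidationError(f"{col} outside [0, 1]")
    if require_finite_fc and not np.isfinite(stats["log2fc"].to_numpy(float)).all():
        raise ValidationError("non-finite log2fc in gene stats table")
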