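"""Readers and writers for the genomic text formats the pipeline touches.

Formats: ENCODE narrowPeak (10 columns), BED6 gene tables, TSV count tables
with a header row, per-gene statistics TSV, 4-column bedGraph, and FASTA.
All writers emit tab-separated UTF-8; lines starting with ``#`` are treated
as comments by every reader.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LookupMissingError, ParseError, ValidationError
from .types import GeneModel, GenomicInterval, Peak, PeakCountTable

# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------


def read_narrowpeak(path: str | os.PathLike) -> list[Peak]:
    """Read an ENCODE narrowPeak file into a list of :class:`Peak`.

    Column 8 (-log10 p) becomes the peak score; the summit is ``start`` plus
    the column-10 offset. An offset of -1 (summit unknown) falls back to the
    interval midpoint, rounded down. Peaks are returned in file order.
    """
    peaks: list[Peak] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(
                    f"{path}:{lineno}: expected >=10 tab-separated narrowPeak "
                    f"fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                score = float(fields[7])
                offset = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            summit = start + offset if offset >= 0 else start + (end - start) // 2
            try:
                peaks.append(
                    Peak(
                        interval=GenomicInterval(chrom, start, end, strand),
                        summit=summit,
                        score=score,
                        peak_id=name,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    ids = [p.peak_id for p in peaks]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate peak_id in narrowPeak file")
    return peaks


def write_narrowpeak(
    peaks: Iterable[Peak], path: str | os.PathLike, signal: Mapping[str, float] | None = None
) -> None:
    """Write peaks as 10-column narrowPeak (col 8 = score, col 10 = summit offset)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for p in peaks:
            sig = signal[p.peak_id] if signal is not None else 0.0
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.peak_id,
                        "0",
                        p.interval.strand,
                        f"{sig:g}",
                        f"{p.score:g}",
                        "-1",
                        str(p.summit - p.start),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6 gene tables
# ---------------------------------------------------------------------------


def read_gene_table(
    path: str | os.PathLike, immunoglobulin_prefixes: Sequence[str] = ()
) -> list[GeneModel]:
    """Read a 6-column BED gene table; the TSS is derived from the strand.

    Genes whose id starts with one of ``immunoglobulin_prefixes`` are flagged
    as immunoglobulin genes.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}"
                )
            chrom, gene_id, strand = fields[0], fields[3], fields[5]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise ValidationError(
                    f"{path}:{lineno}: unknown strand symbol {strand!r}"
                )
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            body = GenomicInterval(chrom, start, end, strand)
            tss = start if strand == "+" else end - 1
            is_ig = any(gene_id.startswith(pfx) for pfx in immunoglobulin_prefixes)
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    body=body,
                    is_immunoglobulin=is_ig,
                )
            )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for g in genes:
            if g.body is None:
                raise ValidationError(f"gene {g.gene_id} has no body interval to write")
            fh.write(
                f"{g.chrom}\t{g.body.start}\t{g.body.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


def read_counts(
    path: str | os.PathLike,
    library_sizes: Mapping[str, int],
    genotypes: Mapping[str, str],
) -> PeakCountTable:
    """Read a TSV count table (first column ``peak_id``, one column per sample)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing cells in count table")
    for sample in df.columns:
        if sample not in library_sizes:
            raise ValidationError(f"{path}: no library size for sample {sample!r}")
    return PeakCountTable(df, library_sizes, genotypes)


def write_counts(table: PeakCountTable, path: str | os.PathLike) -> None:
    df = table.counts.copy()
    df.index.name = "peak_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# gene statistics tables
# ---------------------------------------------------------------------------


def read_gene_stats(path: str | os.PathLike) -> pd.DataFrame:
    stats = pd.read_csv(path, sep="\t", comment="#")
    stats["is_immunoglobulin"] = stats["is_immunoglobulin"].astype(bool)
    return stats


def write_gene_stats(stats: pd.DataFrame, path: str | os.PathLike) -> None:
    stats.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------


class CoverageTrack:
    """Per-base coverage from a bedGraph, with O(1) window means.

    Internally one prefix-sum array per chromosome; chromosome length is the
    largest ``end`` seen (or the supplied ``chrom_lengths``). Suitable for the
    megabase-scale contigs this package simulates, not whole mammalian genomes.
    """

    def __init__(self, per_base: Mapping[str, np.ndarray]) -> None:
        self._cumsum = {
            chrom: np.concatenate([[0.0], np.cumsum(arr, dtype=np.float64)])
            for chrom, arr in per_base.items()
        }
        self.chrom_lengths = {chrom: len(arr) for chrom, arr in per_base.items()}

    def has_window(self, chrom: str, start: int, end: int) -> bool:
        return (
            chrom in self.chrom_lengths
            and start >= 0
            and end <= self.chrom_lengths[chrom]
        )

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        if not self.has_window(chrom, start, end):
            raise LookupMissingError(
                f"window {chrom}:[{start},{end}) outside coverage track"
            )
        cs = self._cumsum[chrom]
        return float(cs[end] - cs[start])

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        return self.window_sum(chrom, start, end) / (end - start)


def read_bedgraph(
    path: str | os.PathLike, chrom_lengths: Mapping[str, int] | None = None
) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`.

    Bases not covered by any record have coverage 0.
    """
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}"
                )
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end or start < 0:
                raise ValidationError(f"{path}:{lineno}: invalid interval")
            records.setdefault(fields[0], []).append((start, end, value))
    per_base: dict[str, np.ndarray] = {}
    lengths = dict(chrom_lengths or {})
    for chrom, recs in records.items():
        length = lengths.get(chrom, max(end for _, end, _ in recs))
        arr = np.zeros(length, dtype=np.float64)
        for start, end, value in recs:
            arr[start:end] = value
        per_base[chrom] = arr
    for chrom, length in lengths.items():
        per_base.setdefault(chrom, np.zeros(length, dtype=np.float64))
    return CoverageTrack(per_base)


def write_bedgraph(
    intervals: Iterable[tuple[str, int, int, float]], path: str | os.PathLike
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for chrom, start, end, value in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | os.PathLike, width: int = 80
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch ``[start, end)`` from a genome: a pyfaidx.Fasta or a dict of str."""
    if chrom not in genome:
        raise LookupMissingError(f"chromosome {chrom!r} not in genome")
    seq = genome[chrom][start:end]
    return str(getattr(seq, "seq", seq))


def contig_length(genome, chrom: str) -> int:
    if chrom not in genome:
        raise LookupMissingError(f"chromosome {chrom!r} not in genome")
    return len(genome[chrom])
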