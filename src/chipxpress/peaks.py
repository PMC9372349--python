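"""Peak-level comparisons between two genotypes.

Implements the "all-or-nothing" peak classification (common vs genotype-
unique by interval overlap), the square-root-scaled CPM difference score
used to rank binding loss, summit-window extraction for motif discovery,
and binned coverage profiles around peak summits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .errors import DegenerateNormalizationError, ValidationError
from .io import CoverageTrack, contig_length, fetch_sequence
from .types import BindingDifferenceScore, Peak, PeakCountTable

logger = logging.getLogger(__name__)

COMMON = "common"
UNIQUE_WT = "unique_wt"
UNIQUE_MUT = "unique_mut"


@dataclass
class OverlapClassification:
    """Result of the common/unique peak classification.

    ``labels_wt``/``labels_mut`` map each peak id to ``common`` or its
    genotype-unique label; ``pairs`` lists every overlapping (wt, mut) peak
    id combination.
    """

    labels_wt: dict[str, str]
    labels_mut: dict[str, str]
    pairs: list[tuple[str, str]]

    def counts(self) -> dict[str, int]:
        return {
            "n_wt": len(self.labels_wt),
            "n_mut": len(self.labels_mut),
            "n_common_wt": sum(v == COMMON for v in self.labels_wt.values()),
            "n_common_mut": sum(v == COMMON for v in self.labels_mut.values()),
            "n_unique_wt": sum(v == UNIQUE_WT for v in self.labels_wt.values()),
            "n_unique_mut": sum(v == UNIQUE_MUT for v in self.labels_mut.values()),
        }


def _check_unique_ids(peaks: Sequence[Peak], label: str) -> None:
    ids = [p.peak_id for p in peaks]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate peak ids in {label} peak set")


def classify_peak_overlap(
    peaks_wt: Sequence[Peak],
    peaks_mut: Sequence[Peak],
    min_overlap_bp: int = 1,
) -> OverlapClassification:
    """Label peaks common or genotype-unique by reciprocal interval overlap.

    A wild-type peak is ``common`` iff it overlaps at least one mutant peak
    by ``min_overlap_bp`` bases, and symmetrically for mutant peaks; labels
    are exhaustive and exclusive.
    """
    if min_overlap_bp < 1:
        raise ValidationError("min_overlap_bp must be >= 1")
    _check_unique_ids(peaks_wt, "wt")
    _check_unique_ids(peaks_mut, "mut")

    trees: dict[str, IntervalTree] = {}
    for p in peaks_mut:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)

    labels_wt = {p.peak_id: UNIQUE_WT for p in peaks_wt}
    labels_mut = {p.peak_id: UNIQUE_MUT for p in peaks_mut}
    pairs: list[tuple[str, str]] = []
    for p in peaks_wt:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(p.start, p.end)):
            q: Peak = iv.data
            if min(p.end, q.end) - max(p.start, q.start) >= min_overlap_bp:
                labels_wt[p.peak_id] = COMMON
                labels_mut[q.peak_id] = COMMON
                pairs.append((p.peak_id, q.peak_id))
    return OverlapClassification(labels_wt, labels_mut, pairs)


def sqrt_scaled_difference(
    table: PeakCountTable,
    classes: Optional[Mapping[str, str]] = None,
) -> list[BindingDifferenceScore]:
    """Score per-peak binding differences as sqrt-scaled CPM differences.

    For each peak, ``d = sqrt(cpm_mut / mean_mut) - sqrt(cpm_wt / mean_wt)``
    where CPM values are replicate-averaged within genotype and each mean is
    taken over all peaks in the table. Scaling by the genotype mean makes the
    score invariant to library-depth differences between genotypes; the
    square root stabilizes the variance of count-derived intensities.
    """
    if len(table.peak_ids) == 0:
        raise ValidationError("count table contains no peaks")
    mean_cpm = table.genotype_mean_cpm()
    means = mean_cpm.mean(axis=0)
    for gt in ("wt", "mut"):
        if means[gt] == 0:
            raise DegenerateNormalizationError(
                f"genotype {gt!r} has all-zero CPM; cannot normalize"
            )
    d = np.sqrt(mean_cpm["mut"] / means["mut"]) - np.sqrt(mean_cpm["wt"] / means["wt"])
    return [
        BindingDifferenceScore(
            peak_id=pid,
            d=float(d.loc[pid]),
            peak_class=None if classes is None else classes.get(pid),
        )
        for pid in table.peak_ids
    ]


@dataclass
class MotifRegions:
    """Summit-centred windows selected for motif discovery, as FASTA records."""

    common: list[tuple[str, str]]
    unique: list[tuple[str, str]]
    dropped: list[str]


def _sort_key(peak: Peak) -> tuple[str, int, str]:
    return (peak.chrom, peak.start, peak.peak_id)


def _extract_windows(
    peaks: Sequence[Peak], genome, flank: int
) -> tuple[list[tuple[str, str]], list[str]]:
    records: list[tuple[str, str]] = []
    dropped: list[str] = []
    for p in peaks:
        start, end = p.summit - flank, p.summit + flank
        if start < 0 or end > contig_length(genome, p.chrom):
            dropped.append(p.peak_id)
            logger.warning(
                "motif window for peak %s clipped at contig edge; dropped", p.peak_id
            )
            continue
        records.append((f"{p.peak_id}|{p.chrom}:{start}-{end}", fetch_sequence(genome, p.chrom, start, end)))
    return records, dropped


def select_motif_regions(
    peaks: Sequence[Peak],
    scores: Sequence[BindingDifferenceScore],
    genome,
    n_top: int = 300,
    flank: int = 150,
) -> MotifRegions:
    """Select summit windows of top common and top binding-lost peaks.

    The *common* set takes the ``n_top`` peaks classified common, ranked by
    caller score descending; the *unique* set takes the ``n_top`` peaks with
    the most negative difference score ``d`` (binding lost in the mutant).
    Windows of ``2*flank`` bases centred on the summit; windows running off a
    contig edge are dropped with a warning so every emitted sequence has
    identical length.
    """
    by_id = {p.peak_id: p for p in peaks}
    missing = [s.peak_id for s in scores if s.peak_id not in by_id]
    if missing:
        raise ValidationError(f"scored peaks missing from peak list: {missing[:5]}")

    common_peaks = [by_id[s.peak_id] for s in scores if s.peak_class == COMMON]
    common_ranked = sorted(common_peaks, key=lambda p: (-p.score, _sort_key(p)))
    if len(common_ranked) < n_top:
        logger.warning(
            "only %d common peaks available for n_top=%d", len(common_ranked), n_top
        )
    unique_ranked = [
        by_id[s.peak_id]
        for s in sorted(scores, key=lambda s: (s.d, _sort_key(by_id[s.peak_id])))
    ]
    if len(unique_ranked) < n_top:
        logger.warning(
            "only %d scored peaks available for n_top=%d", len(unique_ranked), n_top
        )

    common_records, dropped_c = _extract_windows(common_ranked[:n_top], genome, flank)
    unique_records, dropped_u = _extract_windows(unique_ranked[:n_top], genome, flank)
    return MotifRegions(common_records, unique_records, dropped_c + dropped_u)


@dataclass
class DensityProfile:
    """Binned mean coverage around peak summits.

    ``matrix`` is peaks x bins; ``bin_edges`` are positions relative to the
    summit (length ``n_bins + 1``); ``peak_ids`` lists the retained peaks.
    """

    matrix: np.ndarray
    bin_edges: np.ndarray
    peak_ids: list[str]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def summit_density_profile(
    coverage: CoverageTrack,
    summits: Iterable[Peak],
    span: int = 1500,
    bin_width: int = 50,
) -> DensityProfile:
    """Mean per-base coverage in fixed bins spanning ``+-span`` around summits.

    Peaks whose window exceeds the contig bounds are dropped.
    """
    if span <= 0 or bin_width <= 0 or (2 * span) % bin_width != 0:
        raise ValidationError("bin_width must be positive and divide 2*span")
    n_bins = 2 * span // bin_width
    rows: list[np.ndarray] = []
    kept: list[str] = []
    for p in summits:
        start, end = p.summit - span, p.summit + span
        if not coverage.has_window(p.chrom, start, end):
            continue
        row = np.array(
            [
                coverage.window_mean(p.chrom, start + i * bin_width, start + (i + 1) * bin_width)
                for i in range(n_bins)
            ]
        )
        rows.append(row)
        kept.append(p.peak_id)
    matrix = np.vstack(rows) if rows else np.empty((0, n_bins))
    edges = np.arange(-span, span + 1, bin_width)
    return DensityProfile(matrix=matrix, bin_edges=edges, peak_ids=kept)
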