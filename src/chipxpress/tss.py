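"""TSS-level integration of differential binding with differential expression.

Per-gene binding is summarized as CPM over the de-duplicated set of peaks
assigned to a window around the TSS, compared between genotypes as a log2
ratio with a pseudocount. Activated and nonregulated gene groups are
compared by medians and a two-sample t test, and the ranked cumulative sum
of ratios is contrasted with a randomized-ranking (shuffle) null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats as sps

from .errors import (
    InsufficientDataError,
    LookupMissingError,
    ValidationError,
)
from .types import GeneModel, Peak, PeakCountTable


def assign_peaks_to_tss(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window: int = 500,
) -> dict[str, list[Peak]]:
    """Map each gene to the peaks overlapping its TSS window.

    A peak is assigned to a gene iff its interval overlaps
    ``[tss - window, tss + window)`` by at least one base. A peak may serve
    multiple genes; genes without any assigned peak are absent from the map.
    """
    if window <= 0:
        raise ValidationError("TSS window must be > 0")
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    assigned: dict[str, list[Peak]] = {}
    for g in genes:
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        lo, hi = g.tss - window, g.tss + window
        hits = sorted(tree.overlap(lo, hi))
        if hits:
            assigned[g.gene_id] = [iv.data for iv in hits]
    return assigned


def union_region_cpm(
    assigned_peaks: Sequence[Peak],
    table: PeakCountTable,
    _mean_cpm=None,
) -> tuple[float, float]:
    """Per-genotype CPM summed over the de-duplicated assigned peak set.

    Each distinct peak contributes its replicate-averaged CPM once, even if
    listed twice or overlapping a neighbour; base-level union of overlapping
    intervals is not resolvable from per-peak counts and is approximated by
    this de-duplicated sum. ``_mean_cpm`` lets callers reuse a precomputed
    ``table.genotype_mean_cpm()``.
    """
    seen: set[str] = set()
    mean_cpm = table.genotype_mean_cpm() if _mean_cpm is None else _mean_cpm
    cpm_wt = cpm_mut = 0.0
    for p in assigned_peaks:
        if p.peak_id in seen:
            continue
        seen.add(p.peak_id)
        if p.peak_id not in mean_cpm.index:
            raise LookupMissingError(f"peak {p.peak_id!r} absent from count table")
        cpm_wt += float(mean_cpm.at[p.peak_id, "wt"])
        cpm_mut += float(mean_cpm.at[p.peak_id, "mut"])
    return cpm_wt, cpm_mut


def tss_log2_ratio(cpm_wt_union: float, cpm_mut_union: float, pseudocount: float = 0.5) -> float:
    """log2((cpm_mut + c) / (cpm_wt + c)); finite for any pseudocount c > 0."""
    if cpm_wt_union < 0 or cpm_mut_union < 0:
        raise ValidationError("union CPM values must be non-negative")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    return float(np.log2((cpm_mut_union + pseudocount) / (cpm_wt_union + pseudocount)))


ACTIVATED = "activated"
NONREGULATED = "nonregulated"


@dataclass(frozen=True)
class TssBindingRatio:
    """Per-gene TSS binding summary: union CPMs, log2 ratio, group label."""

    gene_id: str
    cpm_wt_union: float
    cpm_mut_union: float
    r: float
    group: str


def compute_tss_ratios(
    assigned: Mapping[str, Sequence[Peak]],
    table: PeakCountTable,
    groups: Mapping[str, str],
    pseudocount: float = 0.5,
) -> list[TssBindingRatio]:
    """Binding ratios for every gene in ``groups`` that has assigned peaks."""
    out = []
    mean_cpm = table.genotype_mean_cpm()
    for gene_id, group in groups.items():
        if gene_id not in assigned:
            continue
        cpm_wt, cpm_mut = union_region_cpm(assigned[gene_id], table, _mean_cpm=mean_cpm)
        out.append(
            TssBindingRatio(
                gene_id=gene_id,
                cpm_wt_union=cpm_wt,
                cpm_mut_union=cpm_mut,
                r=tss_log2_ratio(cpm_wt, cpm_mut, pseudocount),
                group=group,
            )
        )
    return out


@dataclass
class GroupComparison:
    """Median comparison and two-sample t test between gene groups."""

    median_activated: float
    median_nonregulated: float
    median_difference: float
    t: float
    p: float
    n_activated: int
    n_nonregulated: int


def group_comparison(
    activated_r: Sequence[float],
    nonregulated_r: Sequence[float],
    equal_var: bool = True,
) -> GroupComparison:
    """Compare binding ratios of activated vs nonregulated genes.

    Reports both medians, their difference (activated minus nonregulated) and
    a two-tailed two-sample t test (Student's pooled-variance by default;
    Welch with ``equal_var=False``).
    """
    a = np.asarray(activated_r, dtype=float)
    b = np.asarray(nonregulated_r, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"each group needs n >= 2 (got {a.size} and {b.size})"
        )
    if np.allclose(a.var(ddof=1), 0) and np.allclose(b.var(ddof=1), 0):
        # Degenerate: no within-group variance. Identical means -> no signal.
        t = 0.0 if np.isclose(a.mean(), b.mean()) else np.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if t == 0.0 else 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return GroupComparison(
        median_activated=float(np.median(a)),
        median_nonregulated=float(np.median(b)),
        median_difference=float(np.median(a) - np.median(b)),
        t=t,
        p=p,
        n_activated=int(a.size),
        n_nonregulated=int(b.size),
    )


@dataclass
class CumulativeCurveResult:
    """Observed cumulative ratio curve and its shuffle-null ensemble.

    ``gene_ids`` are ranked by expression difference descending; ``observed``
    is the running sum of per-gene ratios in that order. ``null`` (after
    :func:`shuffle_null`) holds one cumulative curve per random permutation
    of the gene order; every null curve ends at the observed endpoint because
    the total is permutation-invariant.
    """

    gene_ids: list[str]
    ratios: np.ndarray
    observed: np.ndarray
    null: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def envelope(self, percentiles: Sequence[float] = (2.5, 50.0, 97.5)) -> dict[float, np.ndarray]:
        """Per-position percentiles of the null ensemble."""
        if self.null is None:
            raise ValidationError("shuffle_null has not been run")
        return {q: np.percentile(self.null, q, axis=0) for q in percentiles}

    def min_exceedance(self) -> tuple[float, float]:
        """Observed curve minimum and its rank-based tail probability.

        Returns ``(observed_min, p_low)`` where ``p_low`` is the add-one
        fraction of null curves whose minimum is at least as low as the
        observed minimum — a global (family-wise) alternative to comparing
        the curve against pointwise percentile bands.
        """
        if self.null is None:
            raise ValidationError("shuffle_null has not been run")
        obs_min = float(self.observed.min())
        null_mins = self.null.min(axis=1)
        p_low = (1 + int((null_mins <= obs_min).sum())) / (1 + self.null.shape[0])
        return obs_min, p_low

    def within_global_envelope(self, alpha: float = 0.05) -> bool:
        """True iff the observed extremes are unexceptional under the null.

        Uses the null distributions of the curve minimum and maximum at
        ``alpha/2`` each side, which has family-wise coverage ``~1 - alpha``
        by construction (a pointwise band does not).
        """
        if self.null is None:
            raise ValidationError("shuffle_null has not been run")
        null_mins = self.null.min(axis=1)
        null_maxs = self.null.max(axis=1)
        lo = np.percentile(null_mins, 100 * alpha / 2)
        hi = np.percentile(null_maxs, 100 * (1 - alpha / 2))
        return bool(self.observed.min() >= lo and self.observed.max() <= hi)


def cumulative_curve(
    ratios: Sequence[TssBindingRatio],
    expression_diff: Mapping[str, float],
) -> CumulativeCurveResult:
    """Running sum of binding ratios over genes ranked by expression difference.

    Genes are sorted by ``expression_diff`` descending (most strongly
    down-regulated first when the difference is -log2fc), ties broken by
    gene_id; the curve is the cumulative sum of ``r`` in that order.
    """
    by_gene = {r.gene_id: r for r in ratios}
    missing = [g for g in expression_diff if g not in by_gene]
    if missing:
        raise LookupMissingError(
            f"ranked genes missing a binding ratio: {sorted(missing)[:5]}"
        )
    ranked = sorted(expression_diff, key=lambda g: (-expression_diff[g], g))
    r = np.array([by_gene[g].r for g in ranked], dtype=float)
    return CumulativeCurveResult(gene_ids=ranked, ratios=r, observed=np.cumsum(r))


def shuffle_null(
    result: CumulativeCurveResult,
    n_shuffles: int = 100,
    seed: int = 0,
) -> CumulativeCurveResult:
    """Complete a curve result with a randomized-ranking null ensemble.

    Each shuffle permutes the gene order uniformly at random (ratios stay
    attached to genes; only the ranking is randomized) and recomputes the
    cumulative sum. Deterministic given ``seed``.
    """
    if n_shuffles < 1:
        raise ValidationError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    n = result.ratios.size
    # argsort of iid uniforms = one uniform random permutation per row
    perms = np.argsort(rng.random((n_shuffles, n)), axis=1)
    null = np.cumsum(result.ratios[perms], axis=1)
    return CumulativeCurveResult(
        gene_ids=result.gene_ids,
        ratios=result.ratios,
        observed=result.observed,
        null=null,
        seed=seed,
    )
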