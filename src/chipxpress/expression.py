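"""Deregulated-gene filtering from per-gene differential-expression statistics.

The cascade: genes with CPM < 1 in every sample are removed; the remaining
raw p-values are adjusted by Benjamini-Hochberg; genes are called activated
(down in the mutant, i.e. normally activated by the factor) or repressed when
they clear a fold-change cutoff, the adjusted-p cutoff, a minimum expression
level in at least one condition, and are not immunoglobulin genes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import validate_gene_stats

#: Gene-name prefixes treated as immunoglobulin loci when no flag is supplied.
DEFAULT_IG_PREFIXES = ("Igh", "Igk", "Igl", "Igj")


def benjamini_hochberg(p_raw: Sequence[float] | np.ndarray) -> np.ndarray:
    """Step-up false-discovery-rate adjustment of raw p-values.

    With order statistics ``p_(1) <= ... <= p_(m)``, the adjusted value at
    rank ``j`` is ``min_{k >= j} (m * p_(k) / k)`` capped at 1; output order
    matches input order.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_raw must be one-dimensional")
    if p.size == 0:
        return np.empty(0)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def filter_low_expression(cpm: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Gene ids retained by the low-expression filter.

    A gene is kept iff its CPM reaches ``threshold`` in at least one sample.
    """
    if cpm.shape[1] < 1:
        raise ValidationError("CPM table needs at least one sample")
    keep = (cpm >= threshold).any(axis=1)
    return cpm.index[keep]


def _passing(
    stats: pd.DataFrame,
    fold_threshold: float,
    padj_threshold: float,
    tpm_threshold: float,
    apply_significance: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (activated, repressed) for the filtering cascade."""
    log2_cut = np.log2(fold_threshold)
    log2fc = stats["log2fc"].to_numpy(float)
    padj = stats["p_adj"].to_numpy(float)
    tpm_max = stats[["mean_tpm_wt", "mean_tpm_mut"]].to_numpy(float).max(axis=1)
    not_ig = ~stats["is_immunoglobulin"].to_numpy(bool)
    base = not_ig
    if apply_significance:
        # NaN p_adj (gene excluded from testing) never passes.
        base = base & ~np.isnan(padj) & (padj < padj_threshold) & (tpm_max > tpm_threshold)
    activated = base & (log2fc < -log2_cut)
    repressed = base & (log2fc > log2_cut)
    return activated, repressed


def filter_deregulated(
    stats: pd.DataFrame,
    fold_threshold: float = 3.0,
    padj_threshold: float = 0.05,
    tpm_threshold: float = 5.0,
) -> tuple[list[str], list[str]]:
    """Activated and repressed gene lists under the full filtering cascade.

    Activated genes are down-regulated in the mutant beyond ``fold_threshold``
    (strictly more than ``fold_threshold``-fold) with adjusted p below
    ``padj_threshold`` and a mean TPM above ``tpm_threshold`` in at least one
    condition; repressed genes are the symmetric up-regulated set.
    Immunoglobulin genes are excluded from both lists.
    """
    validate_gene_stats(stats)
    activated, repressed = _passing(
        stats, fold_threshold, padj_threshold, tpm_threshold, apply_significance=True
    )
    return (
        stats.loc[activated, "gene_id"].tolist(),
        stats.loc[repressed, "gene_id"].tolist(),
    )


def activated_for_tss(
    stats: pd.DataFrame,
    fold_threshold: float = 2.0,
    padj_threshold: float = 0.05,
    tpm_threshold: float = 5.0,
    apply_significance: bool = True,
) -> list[str]:
    """Activated genes at the looser fold cutoff used for the TSS analysis.

    Same cascade as :func:`filter_deregulated`'s activated arm but with a
    2-fold default; the significance and expression criteria can be switched
    off with ``apply_significance=False``.
    """
    validate_gene_stats(stats)
    activated, _ = _passing(
        stats, fold_threshold, padj_threshold, tpm_threshold, apply_significance
    )
    return stats.loc[activated, "gene_id"].tolist()


def flag_immunoglobulin(
    gene_ids: Sequence[str], prefixes: Sequence[str] = DEFAULT_IG_PREFIXES
) -> np.ndarray:
    """Boolean mask marking gene ids that match immunoglobulin name prefixes."""
    return np.array(
        [any(g.startswith(pfx) for pfx in prefixes) for g in gene_ids], dtype=bool
    )
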