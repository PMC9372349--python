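import numpy as np
import pandas as pd
import pytest

from chipxpress import (
    GeneModel,
    GenomicInterval,
    Peak,
    PeakCountTable,
)


def make_peak(chrom, start, end, peak_id, summit=None, score=10.0):
    summit = summit if summit is not None else start + (end - start) // 2
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        summit=summit,
        score=score,
        peak_id=peak_id,
    )


def make_gene(gene_id, chrom, tss, strand="+", length=2000, is_ig=False):
    if strand == "+":
        body = GenomicInterval(chrom, tss, tss + length, strand)
    else:
        body = GenomicInterval(chrom, tss + 1 - length, tss + 1, strand)
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, tss=tss, body=body,
        is_immunoglobulin=is_ig,
    )


def make_count_table(cpm_wt, cpm_mut, peak_ids=None, library_size=1_000_000):
    """Count table whose single-replicate CPM equals the given vectors."""
    cpm_wt = np.asarray(cpm_wt, dtype=float)
    cpm_mut = np.asarray(cpm_mut, dtype=float)
    if peak_ids is None:
        peak_ids = [f"p{i}" for i in range(cpm_wt.size)]
    counts = pd.DataFrame(
        {
            "wt_1": np.round(cpm_wt * library_size / 1e6).astype(int),
            "mut_1": np.round(cpm_mut * library_size / 1e6).astype(int),
        },
        index=pd.Index(peak_ids, name="peak_id"),
    )
    return PeakCountTable(
        counts,
        library_sizes={"wt_1": library_size, "mut_1": library_size},
        genotypes={"wt_1": "wt", "mut_1": "mut"},
    )


def random_peaks(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, prefix="p"):
    peaks = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        end = start + int(rng.integers(1, 400))
        peaks.append(make_peak(chrom, start, end, f"{prefix}{i}"))
    return peaks


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
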