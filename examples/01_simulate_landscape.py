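"""Generate a small synthetic binding/expression landscape with ground truth.

The generator places genes on a toy genome, gives a fraction of them a
promoter (TSS) peak, removes a fraction of those peaks in the mutant
("all-or-nothing" binding loss), and knocks down the expression of the
affected genes.
"""

import chipxpress as cx

config = cx.SimulationConfig(
    n_genes=400, n_chroms=2, chrom_length_bp=800_000,
    n_distal_peaks=100, n_mut_only_peaks=10, seed=42,
)
landscape = cx.simulate_landscape(config)
expr = cx.simulate_expression(config, landscape.truth)

truth = landscape.truth.genes
print(f"genes placed:            {len(landscape.genes)}")
print(f"wt peaks / mut peaks:    {len(landscape.peaks_wt)} / {len(landscape.peaks_mut)}")
print(f"genes with a TSS peak:   {truth['has_tss_peak'].sum()}")
print(f"TSS peaks lost in mut:   {truth['tss_peak_lost'].sum()}")
print(f"mean true knock-down of affected genes: "
      f"{truth.loc[truth['is_deregulated'], 'true_log2fc'].mean():.2f} log2 units")
print(f"RNA samples simulated:   {list(expr.tpm.columns)}")

# Everything can be written in the standard formats the pipeline consumes:
paths = cx.write_landscape(landscape, "scratch_example_data")
paths.update(cx.write_expression(expr, "scratch_example_data"))
print(f"wrote {len(paths)} files (narrowPeak, BED6, TSV, FASTA) to scratch_example_data/")
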