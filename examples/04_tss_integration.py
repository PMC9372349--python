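"""Integrate binding loss at TSS regions with expression loss.

Per gene, binding is the CPM over the de-duplicated peaks within +-500 bp
of the TSS, compared between genotypes as r = log2((mut+c)/(wt+c)). The
activated group (down-regulated >2-fold) is compared with expressed
nonregulated genes by medians and a two-tailed Student's t test, and the
cumulative sum of r over genes ranked by expression difference is contrasted
with 100 random re-rankings.
"""

import chipxpress as cx

config = cx.SimulationConfig(seed=42)
landscape = cx.simulate_landscape(config, with_sequence=False)
expr = cx.simulate_expression(config, landscape.truth)

result = cx.analyze_in_memory(
    landscape.peaks_wt, landscape.peaks_mut, landscape.genes,
    landscape.counts, expr.stats, cx.PipelineConfig(seed=42),
)

comp = result["comparison"]
print(f"activated genes with a wt TSS peak:  {comp.n_activated}")
print(f"nonregulated comparison genes:       {comp.n_nonregulated}")
print(f"median r activated:     {comp.median_activated:+.3f}")
print(f"median r nonregulated:  {comp.median_nonregulated:+.3f}")
print(f"Student's t = {comp.t:.1f}, two-tailed p = {comp.p:.3g}")

curve = result["curve"]
dips = bool((curve.observed < curve.envelope()[2.5]).any())
print(f"\ncumulative curve endpoint: {curve.observed[-1]:.1f} "
      f"(every shuffled curve ends here too)")
print(f"observed curve dips below the 2.5th-percentile null envelope: {dips}")
print("\nA strongly negative activated-group median with an early-diving curve")
print("says binding loss at the TSS tracks the magnitude of expression loss.")
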