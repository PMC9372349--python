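"""Classify peaks as common or genotype-unique and score binding differences.

A peak is *common* when it overlaps a peak of the other genotype and
*unique* otherwise; the sqrt-scaled CPM difference
d = sqrt(cpm_mut/mean_mut) - sqrt(cpm_wt/mean_wt) ranks how strongly each
peak loses (negative d) or gains (positive d) binding in the mutant.
"""

import chipxpress as cx

config = cx.SimulationConfig(n_genes=400, n_chroms=2, chrom_length_bp=800_000,
                             n_distal_peaks=100, seed=42)
landscape = cx.simulate_landscape(config, with_sequence=False)

result = cx.classify_peak_overlap(landscape.peaks_wt, landscape.peaks_mut)
print("peak classification:", result.counts())

classes = dict(result.labels_wt)
classes.update({p: c for p, c in result.labels_mut.items() if c == "unique_mut"})
scores = cx.sqrt_scaled_difference(landscape.counts, classes=classes)
scores.sort(key=lambda s: s.d)

print("\nfive strongest binding losses (most negative d):")
for s in scores[:5]:
    print(f"  {s.peak_id:20s} d={s.d:+.3f}  class={s.peak_class}")
print("\nNegative d marks binding lost in the mutant; the truly lost promoter")
print("peaks should dominate this tail and be labelled unique_wt.")
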