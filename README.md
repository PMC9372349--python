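# chipxpress

Integration of differential transcription-factor ChIP-seq binding with
differential gene expression.

## The problem

When a transcription factor is mutated, two genome-scale readouts change at
once: where the factor binds (ChIP-seq peaks) and which genes are expressed
(RNA-seq). This package implements the analysis that connects the two in a
regulatory-genomics study of a DNA-binding-domain mutant — for
bioinformaticians who have peak calls, per-peak read counts and per-gene
differential-expression statistics, and want to test whether binding loss
at promoters explains expression loss.

The components, in pipeline order:

1. **Peak classification.** A peak is *common* when it overlaps (≥ 1 bp by
   default) a peak of the other genotype and *unique* otherwise — the
   "all-or-nothing" view of binding loss.
2. **Binding-difference score.** Per peak,
   `d = sqrt(cpm_mut / mean(cpm_mut)) − sqrt(cpm_wt / mean(cpm_wt))`, with
   CPM replicate-averaged within genotype and means over all peaks. The
   mean scaling cancels depth differences; the square root stabilizes count
   variance. The most negative `d` peaks (binding lost in the mutant) and
   the top common peaks by caller score yield summit-centred 300-nt FASTA
   windows for motif discovery.
3. **Deregulated-gene filter.** Genes with CPM < 1 in all samples are
   removed; the rest are called activated/repressed when |fold change| > 3,
   Benjamini–Hochberg adjusted p < 0.05 and mean TPM > 5 in at least one
   condition, excluding immunoglobulin genes. A looser >2-fold activated
   set feeds the TSS analysis.
4. **TSS integration.** Peaks overlapping ± 500 bp of a TSS are assigned to
   the gene; per-gene binding is CPM summed over the de-duplicated peak
   set, compared between genotypes as `r = log2((cpm_mut + c)/(cpm_wt + c))`
   with pseudocount `c = 0.5`. Activated genes are compared with expressed
   nonregulated genes by group medians and a two-tailed Student's t test,
   and the cumulative sum of `r` over genes ranked by expression difference
   is contrasted with 100 random re-rankings (shuffle null): every shuffled
   curve ends at the observed endpoint, so an observed curve that dives
   below the null envelope early shows that binding loss tracks the
   *magnitude* of expression loss.
5. **Synthetic data.** A generator produces toy genomes, peak landscapes
   in which a fraction of wild-type promoter peaks collapses to background
   in the mutant, and negative-binomial expression counts in which exactly
   those genes are knocked down — with ground truth, so every claim above
   is testable end to end.

## Worked example

```bash
python examples/04_tss_integration.py
```

```
activated genes with a wt TSS peak:  44
nonregulated comparison genes:       419
median r activated:     -5.371
median r nonregulated:  -0.003
Student's t = -37.4, two-tailed p = 1.46e-141

cumulative curve endpoint: -231.1 (every shuffled curve ends here too)
observed curve dips below the 2.5th-percentile null envelope: True
```

On a synthetic dataset (2,000 genes, 30% TSS-bound, 25% of promoter peaks
lost in the mutant, ~4-fold knock-down of the affected genes) the activated
genes lose ~5.4 log2 units of promoter binding while nonregulated genes
lose none, and the cumulative curve leaves the shuffle-null envelope —
the signature the pipeline is built to detect. `examples/01–03` show the
generator, the peak classification/scoring and the gene filter separately.

The same analysis runs from the shell on files
(narrowPeak/BED6/TSV in, TSV/JSON plus a hash manifest out):

```bash
chipxpress simulate --outdir data --seed 42
chipxpress run --peaks-wt data/peaks_wt.narrowPeak --peaks-mut data/peaks_mut.narrowPeak \
  --chip-counts data/chip_counts.tsv --chip-samples data/chip_samples.tsv \
  --genes data/genes.bed --gene-stats data/gene_stats.tsv --outdir run --seed 42
chipxpress report --rundir run
```

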