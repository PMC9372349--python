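# Methods

## Coordinate and normalization conventions

All intervals are 0-based half-open `[start, end)` (BED/narrowPeak
convention); a TSS is `start` on the `+` strand and `end − 1` on the `−`
strand. CPM is `count / library_size × 1e6` against caller-supplied total
library sizes — per-peak tables cannot recover genome-wide totals, so
library sizes are explicit inputs, never inferred from column sums.
Whether libraries were depth-matched beforehand is the caller's decision;
the analysis takes the sizes as given.

## Peak classification and the binding-difference score

Classification is purely interval-based: a wt peak is `common` iff it
overlaps ≥ `min_overlap_bp` (default 1) of any mut peak, symmetrically for
mut; labels are exhaustive and exclusive, and all overlapping (wt, mut)
pairs are reported. Queries run on an interval tree and are checked against
an all-pairs oracle in the tests.

The score `d = sqrt(cpm_mut/mean_mut) − sqrt(cpm_wt/mean_wt)` first
averages replicate CPM within genotype, then scales each genotype by its
mean over all scored peaks. Two consequences are load-bearing and tested:
`d` is exactly invariant under independent positive rescaling of either
genotype's CPM vector, and exchanging genotype labels negates `d`
elementwise. A genotype whose CPM is zero at every peak leaves the score
undefined and raises a degenerate-normalization error.

For motif-discovery input, the *common* window set ranks common peaks by
caller score (−log10 p) descending and the *unique* set ranks all scored
peaks by most negative `d` — i.e. by binding lost in the mutant, matching
the phenomenon of interest; ranking by |d| would mix in gained sites. Ties
break by (chrom, start, peak_id) so outputs are deterministic. Windows are
`summit ± flank` (default 150 bp); windows clipped by a contig edge are
dropped, not padded, so every emitted sequence has identical length as
motif tools expect.

## Gene filtering

Benjamini–Hochberg is the standard step-up procedure,
`p_adj(j) = min_{k≥j} m·p_(k)/k` capped at 1, implemented directly (the
pipeline must be self-contained on synthetic data) and cross-checked in
tests against both a literal brute-force oracle and statsmodels.

The cascade: low-expression removal (CPM ≥ 1 in at least one sample),
then activated = {log2fc < −log2(3), p_adj < 0.05, max of the two
condition-mean TPMs > 5, not immunoglobulin}; repressed is symmetric. All
inequalities are strict, reading the thresholds as ">3-fold" etc. The
2-fold activated set used at the TSS inherits the p and TPM criteria
(switchable off), since it is described as the same significance machinery
at a looser fold cutoff. "TPM > 5 in at least one condition" compares the
two condition means, not individual samples. Immunoglobulin genes are
identified by a caller-supplied flag or by name prefixes (Igh/Igk/Igl/Igj
by default) — no authoritative list is bundled.

## TSS integration

Peaks are assigned to a gene when they overlap `tss ± 500 bp` (window
configurable; the choice brackets typical promoter-proximal binding).
Per-gene binding is the sum of replicate-averaged CPM over the
de-duplicated assigned peaks. This is a deliberate approximation of a
base-level union: with only per-peak counts, overlapping peaks cannot be
merged at base resolution, so each peak counts once. The ratio
`r = log2((cpm_mut + c)/(cpm_wt + c))` uses pseudocount `c = 0.5` CPM;
some pseudocount is mandatory because unique-wt promoters can have mutant
CPM of exactly 0, and 0.5 sits at the scale of one-to-few background reads
without compressing real signal.

The group comparison reports medians of `r` for activated vs nonregulated
genes (expressed > 5 TPM, within 2-fold, not immunoglobulin, carrying a wt
TSS peak — without a peak `r` is undefined) plus a two-tailed pooled-
variance Student's t test; Welch is available behind a flag but the
equal-variance form is the default to match the named test.

The cumulative curve ranks activated genes by expression difference
(−log2fc, most down-regulated first, gene-id tie-break) and accumulates
`r`. The null re-ranks the same genes uniformly at random (default 100
shuffles; permutations drawn as argsort of iid uniforms for speed), so
every null curve conserves the observed endpoint — an invariant checked to
1e−9. Two envelope summaries are computed:

- per-position 2.5/50/97.5 percentiles (the conventional display band);
- a *global* band from the null distributions of the curve minimum and
  maximum at α/2 each side.

The global band exists because a pointwise band has no family-wise
coverage: a null curve crosses a pointwise 95% band somewhere far more
often than 5% of the time, so "curve inside the envelope" is only a
calibrated statement for the global band. With 100 shuffles and rank-based
percentile estimation the expected per-side exceedance is ≈ 3/101, giving
≈ 94% coverage; the type-I tests assert against that expectation.

## Randomness and determinism

Every stage consumes a seed derived from one master seed (SHA-256 of
`"{seed}:{stage}"`, reduced below 2^31); the simulator spawns independent
child streams per component (sequence, layout, intensities, ChIP counts,
expression, flags), so e.g. skipping genome-sequence generation changes no
other draw. Identical config + seed yields byte-identical output files;
run manifests record config, seeds, version and SHA-256 of every output.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, with defaults
chosen once as the reference condition used by all sweeps:

| parameter | default | rationale |
|---|---|---|
| genes | 2,000 on 4 × 2.5 Mb | desk-scale stand-in for a transcriptome |
| TSS-bound fraction | 0.30 | a minority of promoters bound, as for a typical factor |
| TSS peaks lost in mutant | 0.25 | substantial but partial binding loss |
| peak intensity | lognormal, median 25 CPM, σ = 0.7 | right-skewed peak strengths over a 0.25-CPM background |
| coupling | −2 log2 at the typical intensity, graded | ~4-fold knock-down of affected genes |
| RNA replicates | 3 per genotype | power for the stand-in t test (2 mirrors the two-replicate study design; configurable) |
| NB dispersion | 0.05 | moderate biological variability |
| ChIP counts | Poisson around CPM × lib/1e6, 2 replicates | ChIP replicates are averaged before scoring, so NB overdispersion adds nothing the pipeline would see |

Binding loss is all-or-nothing: a lost promoter peak keeps its wild-type
intensity in wt, draws background-level mutant counts, and is absent from
the mutant peak file. Distal peaks are placed away from every TSS window
and shared between genotypes; a small mutant-only set mirrors gained
peaks.

**Graded coupling.** By default the knock-down of a gene losing its peak
scales with the (log) intensity of that peak —
`log2fc = coupling × log2(1 + cpm_peak) / log2(1 + median_intensity)` — so
strongly bound promoters lose more expression. This grading is what the
cumulative-curve statistic exists to detect: with a single constant effect
size, the expression ranking of affected genes would be pure replicate
noise, the observed curve would be exchangeable with its own shuffle null
by construction, and the curve test could never fire. `graded_coupling
= False` restores the constant-effect variant.

**The decoupled null.** Type-I control cannot be probed by setting the
coupling to zero: then no genes are deregulated, the activated set is
empty, and the group test is undefined. Instead `decouple_binding = True`
applies the same knock-down distribution to a random TSS-bound gene subset
drawn independently of which peaks are lost (grading intensities drawn
afresh, not from the genes' own peaks). Binding ratios are then
exchangeable between the activated and nonregulated groups — the null
hypothesis of the comparison — while the pipeline stays fully defined.
The literal coupling-zero regime is still tested for what it can show:
per-gene raw p-values are uniform at the 5% level.

**Expression stand-in.** Per-gene statistics come from a two-sample t test
on log2 TPM with BH adjustment — a deliberately simple stand-in for a
count-model DE fit, adequate because the pipeline only consumes plausible
(p, log2fc, TPM) triples. Counts are negative-binomial; "TPM" is treated
as count/library × 1e6 without gene-length normalization (all filters act
on thresholds, so a length factor would only relabel the axis).
Consequences, measured by Monte Carlo and frozen into the tests: at 4
replicates about 76% of knocked-down genes are recovered by the 2-fold
filter — bounded above by the TPM > 5 filter (≈ 14% of genes sit below
it under the lognormal baseline, median 20 TPM, σ = 1.3) and by BH power
at small n; at 3 replicates recovery is lower still, which is why the
detection-rate criteria are formulated on group medians (always detected)
rather than per-gene recovery.

## What passing tests do and do not show

The generator produces clean all-or-nothing structure: lost peaks are
absent from the mutant peak file, so classification recovery (~100%)
measures the interval logic, not peak-caller behaviour on noisy coverage.
Real data add caller-threshold effects near the significance boundary,
fragmented peaks, copy-number and mappability artefacts, and DE statistics
from a proper count model — none of which are emulated. Passing tests
therefore validate the integration arithmetic and its statistical
calibration, not robustness to upstream-caller noise.

## Other limitations

- The union-region CPM double-counts nothing but also cannot split reads
  shared by overlapping peaks (per-peak counts only).
- Density profiles hold whole chromosomes as per-base arrays; fine for
  the megabase-scale contigs used here, not for a full mammalian genome.
- The group t test assumes roughly comparable spread; the activated
  group's `r` distribution is strongly non-normal under real coupling.
  The reported medians, and the shuffle-based curve test, are the robust
  summaries; the t test is retained as the named comparison.
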