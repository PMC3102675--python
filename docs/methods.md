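# Methods

## The occupancy model

The ChIP-seq stage models background read placement as homogeneous
Poisson. Reads are reduced to their 5′ start coordinate plus strand (no
fragment extension or shift is applied — read starts alone carry enough
signal at the depths considered, and any extension length would be an
extra free parameter). Counts are taken in 1000 bp windows stepped every
50 bp, so each read contributes to 20 overlapping windows; the
non-overlapping 1 kb tiling (every 20th window) therefore conserves the
read total, which the caller exploits to recover the depth from a window
table alone.

The expected count λ is the condition's total reads divided by the number
of *mappable* non-overlapping 1 kb windows (mapability > 0.25). Restricting
the denominator to mappable windows avoids deflating λ — and hence
inflating significance — when part of the genome cannot contribute reads.
The per-window P-value is the exact Poisson upper tail `P(X ≥ k)`,
evaluated through the survival function so values far below 10⁻¹⁵ remain
accurate.

A window is significant when all of the following hold:

| filter | default | rationale |
|---|---|---|
| Poisson tail | P < 10⁻¹² | with ~2×10⁵ windows the expected false windows per genome are ~10⁻⁷ |
| mapability | > 0.25 | fraction of 32-mers in the window unique in the genome; low-mapability windows accumulate artefactual pile-ups |
| strand balance | \|+ − −\| / (+ + −) ≤ 0.30 | genuine protein binding yields reads on both strands; the boundary is inclusive ("within 30%") |

Runs of overlapping or grid-adjacent significant windows merge into one
peak; the summit is the start of the lowest-P window. Because windows
overlap 20-fold, merging is not optional — without it every site would be
reported ~20 times.

**The ×2 difference criterion.** The cross-condition criterion (depth-
normalized focal/other count ratio > 2) is applied when peaks are
*categorized*, not when they are called: enforcing it per window at call
time would make peaks present in both conditions (ratio ≈ 1) impossible,
contradicting the existence of a "Both" category. `apply_diff_at_call=True`
restores call-time enforcement for users who want strictly
condition-specific calling. "Difference" is read as a ratio rather than a
subtraction: a ratio is depth-invariant and matches the three-way
categorization semantics. The boundary is strict (>2). Condition-specific
peaks failing the ratio are reported with category `filtered` rather than
dropped silently.

**Categorization.** An On peak overlapping no Off peak (half-open
intervals; touching is not overlapping) is On-only, and symmetrically for
Off; reciprocally overlapping peaks become a single Both peak spanning
their union, carrying the better (smaller) best P.

**Gene association.** A gene is assigned every peak whose interval comes
within 10 kb of its TSS, measured TSS-to-nearest-peak-edge and inclusive
at the boundary ("within 10 kb"); summit distance is available but edge
distance matches the notion of "a peak within 10 kb". A peak near several
TSS counts for each gene. Genes are then partitioned by their *set* of
peak categories into the 7 regions of the three-set Venn; the partition
property (region counts sum to the number of genes with ≥1 peak) is
asserted in tests. miRNA loci use a 2 kb cutoff against both the TSS and
the locus interval extended by 2 kb.

**FDR by random reads.** The control places the same number of reads per
condition uniformly over the mappable genome (rejection sampling against
the mapability track) and re-runs the identical caller; FDR = control
peaks / real peaks, pooled over the two conditions. With ~6 reads expected
per window, `P(X ≥ k) < 10⁻¹²` requires k ≈ 40, so uniform controls
essentially never produce a peak and the estimate is 0 at desk scale.

**Overlap of gene lists** between platforms is tested with the
hypergeometric upper tail over a declared universe — a deliberate package
choice of test; several overlap fractions (per-list and min-denominator)
are exposed because the natural denominator is ambiguous.

## The tiling-array model

Each channel of each array is scaled by its array-wide median; this
cancels any global scale, which the scale-invariance test asserts. The replicate CV
(sd/mean, ddof = 1) is computed per probe per channel on *raw* signals;
a probe exceeding 0.30 in either channel is excluded and reported, never
silently dropped. Surviving replicates are averaged (and, when an `array`
column marks multiple experiments, averaged across arrays after per-array
normalization), and the per-probe statistic is log₂(On/Off).

Under the null the mean ratio `w` of `n` probes in a 250 bp window is
Normal(0, σ²/n); the nominal P-value is `½·erfc(w√n/(σ√2))`. The window
is the average sonication shear length and the step the probe size, so a
binding event spans ≥1 full window. σ is estimated by reflecting the
non-positive ratios about zero and taking the SD of the symmetrized set —
enrichment is one-sided, so the negative half-distribution is background
by construction; a plain SD is available (`sigma_method="plain"`).
Bonferroni correction multiplies by the number of windows tested across
the whole experiment (windows are confined within regions, as the array
tiles disjoint promoters), and a region is "bound" when any window's
corrected P falls below α = 0.01 — corrected-per-window, not a separate
familywise α. Regions whose every probe fails QC are reported untestable.

## miRNA differential expression

Signed fold change is ±(larger mean / smaller mean), negative when the
test condition is lower; this is the convention common in microarray
reports where down-regulation prints as a negative ratio, and it makes
|fold| ≥ 1 with antisymmetry under swapping groups. The triple filter is
|fold| > 1.5, absolute mean difference > 100 intensity units and P < 0.05,
all strict. The group-comparison test is Welch's two-sample t on log₂
intensities — a deliberate package choice (expression-summary pipelines
rarely document their internal test), with the thresholds kept exact.
Timecourse tables map the reference day to +1.00 and other days through
the same convention. qPCR normalization divides the target by a control
gene per sample (or computes 2^−ΔCt in cycle-threshold mode) before
averaging; samples lacking the control are excluded with a warning.

Two published fold cells disagree with the ratio of their own printed
group means in the second decimal (146.73 vs computed 146.70; −41.93 vs
−41.92), presumably because the printed means are themselves rounded;
these sit on a tolerance list (checked to ±0.05) rather than being forced.

## The synthetic generator

The generator emulates the data model every stage assumes, at desk scale:

* **Genome & annotation** — 2 chromosomes × 5 Mb, 120 genes placed on
  evenly spaced jittered slots (≥20 kb apart so neighbouring sites yield
  distinct peaks), each assigned exactly one class: 30 On-only, 30
  Off-only, 30 Both, 30 without a site. The binding-site center sits
  within ±1.5 kb of the TSS, the zone where real Re-ChIP reads
  concentrate.
* **Reads** — uniform background at 0.005 reads/bp/condition (λ ≈ 5 per
  1 kb window, matching the reported ~1 read/kb order at desk depth ×5
  for stable calling) plus exactly 200 reads per active site at
  Normal(center, 200 bp), strands 50/50. Background counts are
  deterministic (`round(rate × length)`) so binomial expectations are
  exact; site strand structure is symmetric — no bimodal strand-shift
  model — which suffices to exercise the strand-balance filter but means
  shift-based summit refinement cannot be studied on these data.
* **Mapability** — each grid window is independently forced below 0.25
  with probability 0.05, emulating repeat-masked windows.
* **Array** — 148 regions × 30 probes × 2 replicate spots on a flat
  nominal intensity of 1000 with log₂ channel noise SD 0.25; 20 regions
  carry a 5-probe contiguous sub-window elevated by 3 log₂ units. The
  flat baseline makes the zero-noise case exact; real arrays have
  probe-specific affinities that median scaling does not remove.
* **miRNA matrix** — 40 miRNAs, log-uniform baselines (200–20 000), 10
  up- and 10 down-regulated with folds drawn from [1.6, 4], multiplicative
  noise CV 0.1, 4 replicates per group, truth table returned.

These defaults are the fixed study conditions of the test-suite and the
acceptance run. What passing tests show is that the algorithms recover
known structure under their own model assumptions (Poisson background,
Gaussian probe noise, multiplicative expression noise); they do not show
robustness to chromatin-accessibility bias, GC effects, duplicate reads
or probe affinity variation, none of which the generator emulates.

## Numerical and design notes

* Coordinates are 0-based half-open internally; BED is native, GFF-like
  input is converted on read (1-based start/end; TSS = start for +, end
  for − strand features).
* Windows truncated at chromosome ends are dropped, not rescaled; reads
  beyond a chromosome (or on unknown chromosomes) are dropped with a
  reported count.
* Poisson and hypergeometric tails and the Gaussian erfc path are checked
  in tests against independent brute-force oracles (log-space pmf
  summation, exact rational pmf summation, Monte-Carlo).
* A window with zero reads has undefined strand balance and fails the
  filter; a cross-condition ratio with a zero denominator is +∞ (passes
  any threshold) when the focal count is positive.
* Problem sizes in tests (10 Mb genomes, 30-seed null batteries, 500-seed
  array null, 10-seed recovery medians) were chosen as the smallest runs
  at which the binomial/Poisson expectations quoted in each test are
  sharp enough to be meaningful.
* Known limitations: no local background model (a single genome-wide λ),
  no duplicate-read handling, no fragment-size estimation, single-end
  5′-anchored counting only, and the array stage starts from spot
  intensities (no image processing or dye-swap support).
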