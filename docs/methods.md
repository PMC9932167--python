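# Methods

This note documents the models, conventions and numerical choices behind
th17pipe, and what validation on synthetic data does and does not show.

## Coordinate and overlap conventions

All intervals are held 0-based half-open internally. GTF input (1-based,
closed) is converted on read (`start − 1`) and back on write; BED passes
through unchanged. The TSS of a minus-strand gene `[start, end)` is
`end − 1` and its TTS is `start`. Every overlap predicate — fragment
counting, peak-to-gene annotation, TSS-window membership — uses the
≥ 1 bp rule of `bedtools intersect`, so two intervals that merely abut
(`end == start`) do not overlap. Interval joins are delegated to pyranges;
the test suite checks them against quadratic all-pairs scans.

RPKM is `count / (length/10³) / (library/10⁶)`. Library size defaults to
the total number of placements in the sample's file; an externally
computed total (e.g. uniquely mapped read counts, whose exact definition
is upstream of this package) can be supplied instead and must be at least
the in-feature sum.

## Null-peak depth normalization

Peaks at promoters of strongly and stably expressed genes are assumed to
change between libraries only through sequencing depth. A gene qualifies
when, in **every** condition, its replicate mean RPKM exceeds 5 and its
unbiased replicate variance (ddof = 1; with two replicates this is
`(x₁−x₂)²/2`) is below 0.05 RPKM². Both comparisons are strict, so values
exactly at a threshold fail. A peak is a null peak when it overlaps
`[TSS − 500, TSS + 500 + 1)` of any qualifying gene — window *overlap*,
not point containment, because the peak "contains" the TSS region in the
interval-tool sense. Groups with a single replicate are rejected rather
than treated as zero-variance.

The scale factor of sample *s* is the sum of its null-peak counts divided
by the geometric mean of those sums across samples; the factor set
therefore has geometric mean 1 by construction (validated to 10⁻⁹).
"Weighting by the scale factor" divides each sample's peak RPKM by its
factor — a deeper library is scaled *down*; the opposite convention is
available via a flag. Pearson correlation of the weighted RPKM vectors
measures replicate agreement; a zero-variance sample has undefined
correlation and is reported as missing rather than imputed.

`apply_threshold_filter` consumes externally fitted differential tables
(the negative-binomial model fits themselves are deliberately out of
scope) and keeps features with `|fold-change| ≥ cutoff` and significance
`< α`, optionally intersected with a reliable-gene universe. Because
ratio-style tables encode down-regulation as values < 1, a `ratio=True`
mode keeps features with `fc ≥ cutoff` or `fc ≤ 1/cutoff` instead; the
literal absolute-value rule is the default.

## Reliable genes and target integration

The L1 universe keeps genes whose wild-type mRNA replicate mean RPKM
exceeds 1 **and** whose RPKM exceeds 1 in every IP-input library (strict
comparisons; genes absent from either table are excluded with a warning).
Binding (RIP) and methylation (MeRIP) target sets contain L1 genes whose
bodies are overlapped by at least one respective peak; the
transcription-factor target set is taken as given (a published gene list)
or annotated from ChIP peaks, and is not L1-restricted. Overlap fractions
are reported as percentages with all seven Venn region counts; an empty
denominator yields a missing value, never a division error.

GC enrichment compares per-peak GC fraction (G+C over all bases, N
counted in the denominator) with a length-preserving shuffled background:
each placement draws a chromosome with probability proportional to its
length among chromosomes that can hold the interval, then a uniform
in-bounds start. Shuffled intervals may overlap one another, matching
`shuffleBed` defaults. Observed and background distributions are compared
two-sided by rank-sum.

Tertile grouping sorts genes ascending by promoter signal — mean track
value over `[TSS − 3000, TSS + 3000 + 1)`, optionally divided by a sample
scale factor — with ties broken by gene id so the split is deterministic
under input permutation. When the gene count is not divisible by 3 the
remainder goes to the highest-signal group(s) (remainder 1 → high;
remainder 2 → mid and high). Group comparisons report median, quartiles
and whisker bounds at Q1 − 1.5·IQR / Q3 + 1.5·IQR plus pairwise two-sided
Mann–Whitney U tests: exact enumeration when both groups have ≤ 20
untied observations, otherwise the tie-corrected normal approximation.

Per-gene IP enrichment is the proxy
`max over the gene's peaks of log2((IP RPKM + ε)/(input RPKM + ε))`,
ε = 0.01. Peak-caller-derived enrichment statistics differ in detail; a
column of externally computed per-gene enrichment is accepted wherever the
proxy is used, and the proxy is not asserted to be equivalent.

Metagene profiles bin the ±3 kb flanks at fixed 50-bp resolution and the
gene body into 100 equal-fraction bins, strand-oriented so upstream always
precedes the TSS in transcription direction. Bin means are exact
length-weighted integrals over the run-length signal track (uncovered
bases count as 0), which makes the profile exactly linear in the track —
a tested invariant. Genes shorter than the body bin count, or whose flank
exits the chromosome start, are skipped with a warning; the profile is the
unweighted mean over used genes. Whether the track is input-normalized is
left to the caller.

Accessibility–expression strata take the `top_n` (default 15 000) most
expressed genes, split them low/mid/high by expression with the tertile
rules above, and report mean promoter ATAC RPKM and mean H3K4me3 signal
per stratum.

## mRNA decay

First-order decay `N(t) = N₀ e^(−kt)` is fitted on the log scale by OLS
with free intercept after dividing by the t = 0 value; `t½ = ln 2 / k`,
with `t½ = ∞` reported when the slope is non-negative. The free intercept
absorbs any residual normalization error at t = 0, and the t₀ division
makes the estimate invariant to rescaling the raw quantities — both
tested. Non-positive abundances cannot enter a log fit and are dropped
with a warning, never imputed; fits require ≥ 3 usable points. Nonlinear
least squares on the linear scale (seeded from the log-linear solution)
is available behind a flag for users who prefer unweighted linear-scale
residuals; on clean exponentials the two agree to high precision.

Condition comparison runs a two-sided unpaired t-test per non-zero
timepoint (≥ 2 replicates per arm; with identical degenerate arms p is
reported as 1) and the ratio of pooled-fit half-lives `t_a/t_b = k_b/k_a`
with a delta-method CI on the log scale:
`Var(ln ratio) ≈ se(k_a)²/k_a² + se(k_b)²/k_b²`. Internal-control
(e.g. *Gapdh*) normalization is assumed done upstream; a helper divides
target by control quantities when both are supplied. Reporter time courses
(0, 20, 40 min) use the same machinery.

## Composition and rescue classification

Frequencies divide each type's cell count by its group total. The log2
fold-change between two groups uses raw counts; when either count is 0, a
0.5-cell pseudocount is added to both counts and both totals for that type
before the frequencies are recomputed, keeping every fold-change finite.
A type is *altered* when `|log2FC(disease vs reference)| > 0.6` and
*rescued* when additionally `|log2FC(treated vs disease)| > 0.6` **and**
(by default) the two fold-changes have opposite signs — treatment must
move the frequency back toward the reference, not further away; the sign
requirement can be disabled. The upstream single-cell QC rule (cells with
500–4500 expressed genes inclusive and mitochondrial fraction < 20%) is a
simple table filter; clustering and doublet removal remain external.
Receptor flags mark a cell type when ≥ 10% of its cells have nonzero
expression of at least one receptor gene.

## Synthetic data: what it emulates and what it does not

The generator spawns independent child RNG streams from one global seed
(genome, annotation, counts, enrichment, decay, composition), so outputs
are bit-reproducible and adding one generator never shifts another.
Defaults describe a desk-scale study chosen to run in seconds on one CPU
while preserving the statistical structure each stage assumes:

* genome: 2 chromosomes × 500 kb of i.i.d. bases at 40% GC;
* 300 non-overlapping genes on both strands, of which 220 form a
  high (RPKM ≈ 20), near-constant housekeeping block (the recoverable
  null-peak genes), 40 more complete the reliable universe (RPKM 3–50),
  and the rest sit near RPKM 0.1 below every threshold;
* 400 ATAC peaks (every housekeeping TSS, a subset of other TSSs, plus
  intergenic background) with negative-binomial counts,
  `Var = μ + αμ²` via gamma-Poisson mixing, α = 0.05, and planted depth
  factors (0.5, 1.0, 2.0, 1.0) across 2 conditions × 2 replicates; α = 0
  degenerates to rounded means for noise-free planting;
* binding/methylation peak sets planted so that 73/90 = 81.1% of bound
  genes are methylated and 30/53 = 56.6% of TF targets are bound and
  methylated, all inside the reliable universe;
* a promoter ChIP track whose per-gene amplitude drives IP enrichment as
  `slope · log2(1 + amplitude) + N(0, 0.3)`;
* decay: half-lives 60 min (wild-type) vs 30 min (knockout), timepoints
  0/30/60/90/120 min, 3 replicates, 5% lognormal CV;
* composition: 15 colon cell types at realistic baseline frequencies,
  10⁴ cells per group, nine types shifted by |log2FC| ≈ 1.2–1.6 during
  disease, eight of them reversed under treatment (one altered type is
  deliberately left unrescued to exercise the classifier), drawn
  multinomially after renormalization.

Passing the recovery suite shows the *computations* are correct under the
model they assume — it does not show the model matches real sequencing
data. In particular the generator has no GC- or mappability-dependent
coverage bias, no fragment-length structure, no correlated peaks, no
batch effects, lognormal rather than count-based expression noise, and
its single-cell table carries only composition and one receptor column,
not an expression matrix. Conclusions about real data rest on the
upstream tools this package deliberately leaves external (aligners, peak
callers, differential-expression models, clustering).

## Numerical choices and degenerate inputs

* Geometric means are computed as `exp(mean(log(·)))`; zero sums abort
  with advice rather than silently pseudocounting.
* Strict inequalities at every published threshold (RPKM > 5, variance
  < 0.05, RPKM > 1, significance < α); only the fold-change cutoff is
  `≥`, matching its "cutoff = 2" phrasing.
* Rank-sum tests switch from exact enumeration to the tie-corrected
  normal approximation above 20 observations per group or in the
  presence of ties.
* Signal-track queries are exact integrals, so profile linearity holds to
  machine precision; empty query intervals are rejected.
* Determinism: every sort has an explicit tie-break (gene id,
  coordinate); JSON outputs are key-sorted; reruns with one seed are
  byte-identical (tested at study and pipeline level).

## Problem sizes used in validation

The recovery suite uses the default desk-scale study; the acceptance
script additionally runs 250 null peaks × 3 samples for factor recovery,
100 decay series for half-life bias, 10⁵ cells per group for rescue
classification, and 10⁴ shuffled placements for the GC background. These
sizes were chosen so each planted quantity's sampling error is comfortably
inside the tolerance being demonstrated (e.g. relative SD of a null-peak
sum ≈ 1.7% at 250 peaks, against a 5% recovery bound).
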