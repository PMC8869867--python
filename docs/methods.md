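# Methods

## Spectral-count processing

The quantification chain treats a TUBE pull-down experiment as a
protein × sample matrix of peptide-spectrum-match counts with explicit
sample metadata (condition, replicate, resin-control flag) and a
processing stage tag. Stages apply in a fixed order —
`raw → subtracted → floored → log2 → normalized` — and calling a stage
out of order raises. The steps:

1. **Aggregation.** Counts are summed over all peptide rows matching a
   protein in a sample. A peptide shared by several proteins counts
   toward every one of them by default (`shared_peptides="all"`); a
   unique-peptides-only mode discards shared peptides entirely.
   Protein inference and evidence grouping are out of scope.
2. **Background subtraction.** The per-protein mean over GST control
   samples is subtracted from every experimental column
   (`control_mode="mean"`); a paired mode subtracts control replicate
   *i* from experimental replicate *i*. Control columns are dropped
   from the working matrix but kept for audit. Values may go negative.
3. **Floor.** Every value below one is set to one. With integer counts
   this is exactly "negative and zero values set to one"; the wider
   interval also covers fractional values in (0, 1) produced by
   mean-control subtraction, keeping the floored stage ≥ 1 and the
   log2 stage ≥ 0 unconditionally.
4. **log2.**
5. **Quantile normalization** over experimental columns only
   (controls exist to define background, not to be normalized).
   Classical rank-mean: each column's ranked values are replaced by
   the across-column mean of the values at that rank; ties receive the
   mean of the reference values they span (the behavior of the
   standard microarray implementation). For tie-free data all columns
   share one multiset afterwards and the operation is idempotent to
   machine precision; with ties, tie-averaging can perturb the shared
   multiset slightly — inherent to the tie convention, not a bug.

Detection calls (the "specifically bound" sets) flag a protein in a
condition when its post-subtraction value is ≥ `min_value` (default 1)
in at least `min_replicates` replicates (default: all). The rule is
deliberately configurable: published set sizes of this kind depend on
the upstream database search and on an unstated threshold, so they are
not targets here.

## Differential filter

Per-replicate log2 differences (condition B − A) are taken replicate
*i* against replicate *i* (`by_index`, default) or over all ordered
pairs (`all_pairs`, strictly more stringent). A protein is
`enriched_in_B` iff **every** pair difference exceeds +1 log2 unit
(strictly, by default — a difference of exactly two-fold fails) and
`reduced_in_B` symmetrically. No multiple-testing correction is
applied because no p-value is computed; instead the planted-truth
recovery report (sensitivity, specificity, false-discovery proportion,
direction-aware) quantifies the rule's error rates in simulation.
Raising the threshold can only shrink the differential set, and
swapping condition labels exactly swaps enriched and reduced — both
properties are asserted on random matrices.

## Category summaries and enrichment

Per-protein condition means are averaged within user-supplied
categories (arithmetic mean; a protein annotated to several categories
contributes to each). The shipped annotation covers the proteasome
subcomplexes (20S α: PSMA1–7; 20S β: PSMB1–7; 19S base: PSMC1–6,
PSMD1/2/4, ADRM1; 19S lid: PSMD3/6–8/11–14) and three autophagy stages
(early signaling, autophagosome formation, lysosome fusion) with human
gene symbols. Enrichment of a category in the differential set uses
the two-sided Fisher's exact test on the 2×2 cross-classification
(conventional definition: sum of table probabilities at most that of
the observed table); the reported odds ratio applies the Haldane 0.5
correction when a cell is zero, the p-value never does. Heat-map row
scaling (`row_z`) centers each category row and divides by its sample
standard deviation (ddof = 1, the convention of R's `scale` and the
common heat-map packages); constant rows map to zeros rather than NaN.

## Co-localization

Puncta are detected in the reference (autophagy-marker) channel by
thresholding (Otsu or fixed), 8-connected component labeling and an
area filter; a flat image under Otsu yields an empty ROI set with a
warning. Manders coefficients are computed inside the ROI union:
M1 = Σ reference intensity on pixels where the partner channel exceeds
its threshold ÷ Σ reference intensity, M2 symmetrically. Thresholded
Manders (not Costes) is used; with a fixed threshold the coefficients
are invariant under joint rescaling of a channel and its threshold.
Per-ROI coefficients with zero denominator are reported as missing.
Line profiles are sampled by bilinear interpolation and each trace is
normalized to its own maximum (zero-max traces return as zeros).
Everything is 2-D; confocal planes are treated as single slices, and
images are assumed pre-cropped to one cell.

## Drug combination

The median-effect model fa/(1−fa) = (D/Dm)^m is fitted by ordinary
least squares on log10(fa/(1−fa)) vs log10 D (any log base gives the
same fit; base 10 is used for reproducibility). Rows with fa outside
the open unit interval are rejected with a warning, never clipped —
clipping is the generator's job. IC50 ≡ Dm. The combination index at
effect level fa splits the combination's equi-effective total dose
Dx,combo = Dm(fa/(1−fa))^(1/m) by the fixed mixing ratio r into
dA = Dx·r/(1+r), dB = Dx/(1+r) and sets CI = dA/DxA + dB/DxB (mutually
exclusive form, the CompuSyn default; the non-exclusive form adds
dA·dB/(DxA·DxB) and is available by flag). CI is exactly 1 for an
agent combined with itself at any (m, Dm) and invariant to the dose
units of either agent. When replicates are present, fits and CIs are
computed per replicate and summarized as mean ± SD, matching how CI is
conventionally reported with a spread. Apoptosis gating is a fixed
intensity threshold on annexin-V events; count and fraction are
reported together.

## Synthetic data: what it emulates, and what it does not

The count generator models two conditions × three replicates with
matched resin controls. Specific counts are gamma-Poisson
(negative-binomial) with var = μ + φμ²; defaults μ = 100, φ = 0.03
give a count CV ≈ 0.2 at baseline. Defaults plant 5% up + 5% down
at |log2 fc| = 2 in a universe of 1000 proteins, with a nonspecific
background mean of 5 added to all samples and appearing alone in
controls. Planted set sizes round half away from zero. An "up in B"
protein has elevated specific counts in condition B; a "down in B"
protein has elevated counts in condition A — a protein less abundant
in the resistant line is one that was abundant in the parental line.
With equal fractions the two conditions then share one marginal
distribution, which is the regime quantile normalization assumes (and
the reason it is a sensible step in the real protocol). Placing both
tails in one condition instead would violate that assumption and
deterministically compress planted fold changes by roughly a third.

The image generator renders Gaussian puncta (σ = 2 px, amplitude
1000, background 100, noise SD 5 on a 256² frame) with all centers —
both channels pooled — at least 3σ apart and 4σ from the borders via
rejection sampling. `round(overlap × n)` spots share centers across
channels; the partner channel receives its own distinct spots so both
channels carry n puncta. Ground-truth overlap = shared/reference
spots.

The dose-response generator draws fa from the median-effect model with
additive Gaussian noise, clipped to [0.005, 0.995] (the linearization
is undefined at 0/1). Combination rows at a constant ratio solve
dA/DxA(fa) + dB/DxB(fa) = α for fa (monotone; Brent's method, bracket
clamped at [1e−6, 1−1e−6] for extreme doses): α = 1 is exactly
Loewe-additive, α < 1 plants synergy, and CI decreases monotonically
as α drops. The flow generator draws a two-component Gaussian
intensity mixture (negative: 100 ± 25; positive: 1000 ± 200; gate at
400) with the positive count fixed exactly by rounding, 10⁴ events by
default.

None of the generators simulate raw spectra, retention times,
search-engine behavior, replicate-specific batch effects, 3-D image
stacks, optical aberrations, or cell-to-cell heterogeneity. Passing
tests therefore certify the *computational* contracts of each stage
and their behavior under controlled violations of their assumptions —
not performance on any particular real dataset, whose headline set
sizes additionally depend on upstream identification pipelines outside
this package's scope.

## Numerical and design choices

- Stage machine prevents out-of-order processing; errors name the
  offending stage.
- Quantile normalization requires ≥ 2 experimental columns; a single
  column is an error, not a no-op.
- The t-test is the pooled-variance (Student) variant by default, with
  Welch by flag; identical groups return t = 0, p = 1 exactly, and a
  zero pooled variance with unequal means reports the p → 0 limit with
  a warning instead of NaN.
- Simulation sizes in tests (1000-protein recovery over 20 seeds,
  256² images, margin-≤30 Fisher enumeration) keep the default suite
  under half a minute while leaving the guarantees sharp.
- The run report is canonical JSON (sorted keys, fixed layout) and is
  validated against a shipped schema; identical config + seed is
  byte-identical.

## Known limitations

- Shared-peptide double counting (the default, following the summation
  rule's literal reading) inflates correlated proteins; the
  unique-peptides mode is the conservative alternative.
- The two-fold reproducibility filter has no error-rate control; its
  planted-truth FDP is essentially zero at the default depth but rises
  at low counts or high dispersion.
- Manders coefficients depend on the threshold choice; Otsu on images
  whose foreground is a tiny pixel fraction can be unstable, which is
  why fixed thresholds are supported and used in the verification
  suite.
- The median-effect fit weights all points equally on the logit scale,
  so observations near fa = 0 or 1 carry amplified noise; dose series
  should bracket Dm (the verification suite uses 0.3–3 × Dm).
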