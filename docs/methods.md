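# Methods

This note records the models implemented in `mirutr`, the conventions and
defaults chosen where the underlying experimental literature leaves them
open, and what the synthetic-data tests do and do not demonstrate.

## Canonical seed-site model (`seedscan`)

A mature miRNA (stored 5′→3′, U mapped to T) defines four target-strand
patterns: 6mer = revcomp(p2–p7), 7mer-m8 = revcomp(p2–p8),
7mer-A1 = 6mer + "A", 8mer = 7mer-m8 + "A". The trailing "A" is the
target t1 adenosine and is required *regardless of the miRNA's own
position-1 nucleotide* (it is recognized by Argonaute, not paired). A
consequence worth knowing: a mimic whose position 1 is mutated still
produces the same target-centric classification of a wild-type reporter;
mimic naming conventions describe pairing geometry, not the target class.

Scanning anchors on occurrences of the 6mer core and classifies each
anchor by its flanking bases (m8 complement 5′ of the core, t1 A 3′ of
it) — linear-time and provably equivalent to testing every 6–8-nt window
with the priority rule full > 8mer > 7mer-m8 > 7mer-A1 > 6mer
(equivalence to the brute-force oracle is asserted in the tests on 1000+
random sequences). Distinct anchors may yield overlapping sites; one
anchor yields exactly one site, so repeated-site counting never
double-counts a physical seed match.

`full` sites: an 8mer whose upstream bases pair the miRNA's 3′ region
(positions 9…N) with **at most one mismatch** (`FULL_SITE_MAX_MISMATCH = 1`).
Published full-complementation reporter constructs mismatch the strict
reverse complement at the miRNA 3′-terminal base, so exact matching would
misclassify real constructs; one tolerated mismatch in the 3′-pairing
region is the minimal relaxation that accepts them while remaining
vanishingly improbable in random sequence.

Other conventions: sequences are sense-strand 5′→3′ only (minus-strand
conversion is the annotation reader's job); IUPAC ambiguity codes never
match; all reported coordinates are 1-based inclusive, converted to/from
0-based half-open exactly at the BED boundary. A site belongs to the
*extended* (long-isoform-only) region iff its start lies 3′ of the APA
breakpoint.

## APA / PDUI model (`apa`)

Coverage over an annotated 3′UTR is modelled as
`depth(i) = w_long + w_short · 1[i ≤ P]`: both isoforms contribute up to
the proximal poly(A) site `P`, only the long isoform beyond. One shared
`P` is fitted per transcript *jointly over all samples* by grid search at
single-base resolution on `[min_segment, L − min_segment]`
(`min_segment = 50` bases), minimizing total squared error with
closed-form per-sample segment means; `w_short` is clipped at zero (an
inverted step refits as flat) and ties break toward the smallest `P`.
Joint fitting keeps `P` stable at low depth and reflects the biology: the
poly(A) site is a property of the transcript, not of the sample.

`PDUI = w_long / (w_long + w_short)` ∈ [0, 1] (1 = long isoform only).
ΔPDUI = mean PDUI in group A − group B, with A = axon by convention so
"lengthened in axons" is positive; the labels are arguments, not
hard-coded. Significance: two-sided Welch t on per-sample PDUIs
(group sizes are small and PDUI is the thresholded quantity), BH-FDR
across transcripts, and status lengthened/shortened at FDR < 0.05 and
|ΔPDUI| ≥ 0.2 (both configurable). Transcripts with mean depth < 5× in
any sample, or zero coverage everywhere, are skipped with a logged
reason. Limitations: a single breakpoint (no >2-isoform models), no
internal-priming correction, no de novo 3′UTR annotation.

## FRAP quantification (`frap`)

Build-up is `100 · (F(t) − F(t₀)) / F_pre` with `t₀` the first
post-bleach frame — the curve starts at 0 and is invariant to camera
gain. The normalization denominator (pre-bleach intensity) is a choice;
normalizing to the bleach depth `F_pre − F(t₀)` instead would rescale
curves per cell. The pre-bleach denominator was chosen because it keeps
the percent scale comparable across cells with different bleach
efficiencies; it is an explicit argument of the trace record, not buried
in the math.

The synthesis-rate readout is the OLS slope of build-up vs frame index
over the inclusive window frames 5–20 (frames numbered 0…20 post-bleach;
21 frames at 30-s intervals is the default acquisition design): the first
frames mix residual recovery processes, the 5–20 stretch is the linear
regime. K_R50 = half of the maximum of the control condition's mean
build-up curve; crossing times are linearly interpolated between frames
and reported as absent when never reached. Groups are compared by one-way
ANOVA on per-cell slopes with pairwise two-sided Welch t-tests,
Holm-adjusted by default (`adjust="none"` reproduces raw pairwise tables).
No correction is made for photobleaching during acquisition — a known
limitation; slopes of slow conditions are biased slightly downward if
acquisition bleaching is non-negligible.

## Decay stratification (`kinetics`)

The module consumes an *already normalized* expression matrix (e.g.
median-of-ratios output of a DE pipeline) — no alignment, counting or
normalization is performed here. The ratio statistic is
`log2((mean_mir + 1) / (mean_control + 1))` per gene and time point; the
pseudocount of 1 stabilizes low counts and the t = 0 ratio is reported as
a sanity check (≈ 0 by design). Both the ratios and the per-stratum
summaries are emitted, since either absolute levels or ratios may be the
quantity of interest downstream.

Stratification: a gene's seed class is its *strongest* site type
(strata stay exclusive; `full` collapses into 8mer, endogenous full sites
being essentially nonexistent); site-count strata use the 0/1/2/>2
binning. Per time point, strata are compared by one-way ANOVA with
pairwise Welch tests (Holm-adjusted); strata with fewer than two genes
are dropped with a warning. ΔΔCt utility: fold change = 2^−ΔΔCt.

## Multiplicity enrichment (`enrichment`)

Each panel miRNA is scanned over the lengthened-UTR set and transcripts
are binned 0/1/2/>2 by site count. Percentages are reported against two
denominators — all lengthened UTRs, and that miRNA's targets only —
because both readings are informative and the choice materially changes
the numbers. Panels are compared by Pearson chi-square (no continuity
correction; df from the table shape) on the pooled class counts, with a
warning when an expected count drops below 5. Panel membership is always
user-supplied; no miRNA list is hard-coded.

## Synthetic data (`synthetic_data`)

All generators fan a single master seed out through
`SeedSequence.spawn`, one stream per entity, so outputs are reproducible
and extending a cohort never perturbs earlier entities.

* **UTRs**: requested sites are planted at random non-overlapping
  positions; flanks are rejection-sampled (retry cap 200) to contain no
  seed-core occurrence, and the assembled sequence is re-validated by
  direct string checks (core count, flanking bases, no accidental
  full-site upgrade) that are deliberately independent of the scanner, so
  planted-site recovery tests are not circular.
* **Coverage**: expected depth `depth · (pdui + (1 − pdui) · 1[i ≤ P])`,
  Poisson or noiseless. Default study conditions for recovery tests:
  PDUI 0.6, 100× depth, 50 transcripts; the compartment contrast uses
  axon 0.8 vs soma 0.4 (ΔPDUI +0.4) with 3 samples per group.
* **Decay**: miRNA-condition means decay as `base · exp(−λ_gene t)` at
  t = 0/2/4 h with `λ_gene = λ_class + (n_sites − 1) · λ_site`; control
  stays flat; negative-binomial sampling (variance μ + αμ², default
  α = 0.05, three replicates per condition×time). Default class rates
  0.5/0.35/0.2/0.08 h⁻¹ (8mer/7mer-m8/7mer-A1/6mer) give 4-h log2 ratios
  of roughly −2.9 to −0.5 — the magnitude range seen in overexpression
  time courses — and λ_site = 0.2 h⁻¹ per additional site.
* **FRAP**: intensity = floor + slope·frame + Gaussian noise, floor at
  20 % of pre-bleach (incomplete bleaching), noise 0.3–0.5 % of
  pre-bleach per frame, 21 frames at 30 s. The six-condition design
  plants slopes 0.4/0.8/1.1/1.2/1.6/2.0 %/frame for
  full/8mer/7mer-A1/7mer-m8/6mer/control, encoding the expected
  seed-strength ordering with 7mer classes nearly tied.

What the generators do *not* emulate: read-level artifacts (mappability,
internal priming, GC bias) in coverage; genuine biological variance
structure and normalization error in expression; acquisition
photobleaching, focus drift and segmentation error in FRAP traces; and
sequence composition biases of real 3′UTRs. Passing recovery tests
therefore demonstrates correctness of the estimators under their own
model assumptions, not robustness to every artifact of real data.

## Problem sizes and numerical choices

Recovery and calibration suites run at deliberately modest sizes chosen
as sufficient for their statistical claims: 1000 random UTRs (50–5000 nt)
for scanner/oracle equivalence, 50 transcripts for PDUI recovery, 130
transcripts for caller sensitivity/specificity, 200 traces for slope
unbiasedness, 20 replicates for ordering claims, and 500 replicates for
the type-I-error band [0.025, 0.075] at nominal 0.05 (the band is the
99.9 % binomial envelope, roughly, at n = 500). Ties in the APA grid
break toward the smallest breakpoint; degenerate zero-variance groups in
Welch tests return p = 1 when means agree and p = 0 otherwise; PDUI is
undefined (sample excluded) when both isoform weights are zero.
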