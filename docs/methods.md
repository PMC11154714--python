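# Methods

## Problem and model

`irsplit` quantifies intron retention (IR) in bulk RNA-seq by splitting every
annotated transcript's signal into an exonic part (mature mRNA) and an
intronic part (pre-mRNA / retained introns), the exon–intron split idea. For
each transcript *t* and sample *s* the IR statistic is the ratio of summed
TPM abundances

    R_ts = (TPM_intron(t,s) + ε) / (TPM_exon(t,s) + ε),

with pseudocount ε (default 0.01 TPM) guarding zero denominators. Between a
case group (e.g. CLL B cells) and a control group (e.g. normal B cells) the
per-transcript effect is `log2( median_case(R) / median_control(R) )`. The
ratio is a surrogate for alternative-splicing activity: boundary-straddling
and intron-internal reads are exactly the signal that distinguishes a
retained intron from a spliced one.

TPM is computed per feature class over that class's own universe:
`TPM_f = 1e6 (r_f/L_f) / Σ_g (r_g/L_g)` with `r_f` the read count and `L_f`
the feature length, so each sample's exonic TPMs sum to 1e6 over exonic
features, intronic over intronic features, and whole-transcript over
transcripts. A shared-universe variant would change only a per-sample
constant within each class and hence no rank test; the three-universe layout
keeps each class interpretable on its own scale.

## Annotation handling

Coordinates are 1-based inclusive internally (`length = end − start + 1`),
matching browser-style coordinate text; BED export converts to 0-based
half-open at the file boundary. Overlapping or book-ended exon records of
one transcript are unioned before introns are derived as the exact gaps
between consecutive exons (so no intron can have length < 1, and exonic +
intronic length always equals the span length). Intron-less transcripts are
removed: they carry no IR signal and would only dilute the intronic TPM
universe. Introns are per-transcript by default — positions covered by exons
of *other* isoforms are retained; an optional masking mode subtracts them
for users who prefer the stricter definition used by some IR callers. Strand
is carried but not used in counting by default (library strandedness is
often unknown); `fr`/`rf` modes are available.

## Counting policy

A read (or properly paired fragment) increments every feature it overlaps by
at least `min_overlap` (default 1) aligned bases, using the aligned blocks,
so spliced (`N`-gap) reads do not count toward the introns they jump over,
while exon/intron boundary-straddling reads count toward both features.
Reads with MAPQ < 1 are skipped, which removes multi-mappers under the
common MAPQ-0 convention; no multi-mapping rescue or isoform-level
EM assignment is attempted. Counts are order-invariant and deterministic.

## Expression filter and classification

Only transcripts with TPM > 0 in at least 60% of the samples of **each**
group (inclusive boundary) enter the analysis; the filter is applied to
whole-transcript TPM.

Two one-sided Wilcoxon rank-sum (Mann–Whitney) screens on intronic TPM —
one per direction — are each Benjamini–Hochberg adjusted at the 5% level
across all filtered transcripts. Rejections define set-I (higher intronic
signal in group 1) and set-II (higher in group 2); the two directional
screens cannot both reject one transcript at any level below 0.5, so the
sets are disjoint. Within either set the expression subset is assigned from
whole-transcript TPM screens, directions expressed case-relative:

* **A** — over-expressed in group 1 (directional screen rejected, BH at 5%
  by default; a raw `p < α` mode exists because either reading of
  "p < 0.05; FDR = 5%" is defensible),
* **B** — under-expressed in group 1 (mirror direction),
* **C** — non-differential: two-sided expression p > α **raw** (the subset
  asks for absence of evidence; adjusting it would enlarge C arbitrarily
  with the number of tests),
* **unassigned** — an IR-set member fitting none of the three rules
  (e.g. two-sided p < α but neither directional screen survives BH). These
  are reported, never silently forced into C.

The rank test uses exact enumeration when the pooled sample size is ≤ 12
with no ties, and the normal approximation with mid-ranks, tie-corrected
variance and continuity correction otherwise. The 97-vs-9 design always
takes the asymptotic branch; the exact branch is validated against full
labeling enumeration in the test suite.

Association between IR direction and expression direction is summarized by
a Pearson chi-square (no continuity correction) on the
{set-I, set-II} × {A, B, C} table and by Fisher's exact test with the sample
cross-product odds ratio `ad/bc` on the {A, B} columns (Haldane–Anscombe
+0.5 on any zero cell, flagged). Subset percentages are rounded half-up to
integers.

## Association products

* **Top-N selection** (default N = 200) ranks a set's members by its own
  directional intronic-screen p-value, breaking ties by larger \|log2
  ratio\| and then transcript id. The source defaults to set-I, with
  subset sources (e.g. set-IA) available — both readings of the original
  description are supported.
* **Heatmaps** are per-row Z scores (sample sd, n−1; constant rows map to
  zero) with columns in the fixed block order: controls, then the low-risk
  (mutated-IGHV-like) case block, then the high-risk block. No clustering.
* **Volcano** coordinates: x is the between-group log2 IR-ratio effect; two
  ordinates are emitted because the source description of the y axis is
  self-contradictory — `y_p = −log10 p` from a two-sided rank test on the
  per-sample ratios (the plotted ordinate) and `y_expr = log10` expression
  fold change (used for the quadrant interpretation).
* **Quadrants / identity line**: counts of transcripts whose group-1 summary
  ratio is strictly above, on, or below the group-2 summary — the "diagonal
  where IR is equal in both groups" is the identity line by its own
  definition; an auxiliary OLS fit is reported but not used for counting.

## Over-representation analysis

The genes of the top 25% of ranked high-IR transcripts (ceiling, symbols
de-duplicated) are tested per gene set with the one-sided hypergeometric
tail P(X ≥ k), Bonferroni-corrected over the sets tested. The background
universe defaults to the genes surviving the expression filter — the null
should match the population that could have been selected — not the whole
annotation; it is configurable. Gene sets come from local GMT files; no
network service is ever contacted.

## Synthetic cohorts

The simulator emulates the study design the pipeline targets: 97 case
samples (41 high-risk-like + 56 low-risk-like) vs 9 controls. Per
transcript, a baseline abundance is drawn log-normal (meanlog 2.0, sdlog
1.2 — a heavy right tail like real TPM), with an intronic fraction
log-normal around 0.15. Planted effects are multiplicative, matching the
ratio statistic: set-I transcripts get intronic abundance × δ_ir in cases
(set-II: in controls), subset A/B transcripts get exonic and
whole-transcript abundance ×/÷ δ_expr in cases; IR and expression effects
are deliberately decoupled so the planted truth is unambiguous. Every cell
then receives independent log-normal noise of sd σ. Default planted
fractions follow the proportions reported for the emulated cohort (47%
set-I, 19% set-II; subsets 87/2/11 within set-I, mirrored for set-II);
default effects are δ_ir = 4, δ_expr = 3, σ = 0.5.

Matrices are emitted on a TPM-like scale **without** per-sample
renormalization to 1e6: renormalizing a cohort with planted effects would
couple every null transcript to the planted fraction through the
library-size sum (a compositional artifact), so the planted labels would no
longer be the truth of the emitted data. Renormalization is the
quantifier's job and is exercised on the count path (`emit="counts"` draws
negative-binomial counts, gamma–Poisson with `var = μ + 0.1 μ²`, from the
same means). Consequences for interpretation: passing recovery tests shows
the screens detect multiplicative location shifts under heavy-tailed
independent noise; they say nothing about compositional distortion,
transcript-length biases, correlated noise between intron and exon of one
transcript, batch structure, or alignment artifacts, none of which the
generator models.

All draws flow from one seeded NumPy generator; a fixed config is bitwise
reproducible.

## Calibration and verification

The test suite checks, among others: exact interval arithmetic against
printed PCR amplicon coordinates; TPM column sums of 1e6 and count-scale
invariance; group-swap antisymmetry of the log2 effect; rank-test, Fisher
and hypergeometric p-values against brute-force enumeration oracles on
small instances; recovery of ≥ 90% of planted six-set labels at the default
effect sizes on a 2,000-transcript cohort; and a 200-cohort complete-null
calibration in which the mean false-discovery proportion of directional
IR-set calls under BH at 5% must stay within Monte-Carlo error of at most
the nominal level. On a complete null the realized FDR sits well below 5%:
the one-sided asymptotic tail with continuity correction is conservative in
the extreme tails that survive BH with thousands of tests, because the
bounded rank-sum statistic has lighter tails than its normal approximation.
Problem sizes used in the automated runs (2,000 transcripts, 200 null
cohorts, 300–400-transcript unit fixtures) were chosen as the smallest
sizes at which the screens operate in their asymptotic regime and
Monte-Carlo error is small relative to the quantities asserted.

## Known limitations

* No isoform deconvolution: reads overlapping several transcripts' features
  count toward each (union counting). Shared exons inflate both transcripts
  equally and cancel in ranks within a transcript, but cross-isoform
  leakage is not corrected.
* The intronic universe is annotation-defined; unannotated retained introns
  or cryptic splice sites are invisible.
* The pipeline assumes two groups; subgroup labels are used only for
  heatmap column blocking, not for stratified testing.
* Ratio pseudocounts make lowly expressed transcripts shrink toward R = 1;
  transcripts with exonic TPM = 0 in > 40% of samples are flagged rather
  than dropped.
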