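# Methods

## Study design being modelled

The analysis targets replicated small-RNA-seq profiles of a single
tissue under a 2×2 diet design: perinatal diet × adult diet, each
balanced (C) or high-fat (HF), giving groups C-C, C-HF, HF-C and HF-HF
with six biological replicates each. The scientific questions are
(i) which miRNAs vary unusually strongly *within* a group
(hypervariability), and (ii) which miRNAs respond to the perinatal
and/or adult environment *between* groups, with responses validated
through partner strands and gene clusters rather than through external
replication.

## Read processing

Reads are `insert + 11-nt barcode + common 3′-adapter tail`. A read is
assigned to the library whose barcode occurs in it (leftmost occurrence
wins; equal-length distinct barcodes cannot tie at one position);
unmatched reads go to an `undetermined` bin, so assignment partitions
the input. Trimming cuts at the leftmost exact occurrence of the first
min(10, len) nt of the library's full adapter (barcode + tail); an
unmatched read is kept whole and flagged, which makes trimming
idempotent. Inserts shorter than `min_len` are discarded and survivors
collapsed to unique sequences with multiplicities.

*Length cut-off.* Descriptions of this protocol variously put the lower
bound at 15, 16 or 18 nt; `min_len` is configurable with default 16,
matching the gel-purified 16–36-nt fraction.

*Quantification.* A unique sequence counts toward a mature miRNA iff it
equals the mature sequence or is a 3′-end variant within 2 nt (trimmed
or extended). This deliberately replaces external miRBase-alignment
tooling with a transparent exact-match rule: mismatch-tolerant alignment
and novel-miRNA discovery are out of scope, and the ±2-nt rule captures
the dominant 3′ isomiR variation that matters for counting. A sequence
matching two matures indicates a malformed reference and is an error,
not a silent double-count. Stage accounting
(assigned + unassigned + discarded = input) is asserted at run time.

## Normalization

Size factors are the classical median-of-ratios:
s_j = median over rows i of k_ij / (∏_v k_iv)^(1/m), restricted to rows
with strictly positive counts in every library (rows containing any zero
are excluded from the geometric-mean reference). The geometric mean of
the factors is not constrained to 1. Normalized values are k_ij / s_j,
kept alongside the raw counts because the exact NB test consumes raw
counts plus factors.

Note a consequence of the definition: multiplying one library's counts
by c scales its factor by c^((m−1)/m) and every other factor by
c^(−1/m) — the geometric-mean reference also moves — while all
normalized profiles keep their mutual ratios. The median over an even
number of reference rows is the arithmetic mean of the two central
ratios (medians are taken on the ratio scale, not the log scale).

Two scopes are provided: `group` (each group's six profiles normalized
together — used for the within-group variability screen) and `global`
(all libraries together — used for between-group comparisons). The
expression filter keeps a miRNA in a group when its mean normalized
expression is ≥ 10 (closed boundary). The tested set of a two-group
comparison defaults to the union of the two expressed sets (the most
inclusive choice; intersection is available).

## Variability screen

Per miRNA and group: MAX/MIN of the six normalized values (∞, flagged,
if the minimum is 0 — normally prevented by the expression filter) and
CV with the sample (n−1) standard deviation. The hypervariability
threshold is mean + 2·STD of the MAX/MIN distribution in a designated
reference group (the control group by default) and is applied to all
groups with strict `>`; per-group thresholds are available via flag.
Flagged percentages are reported to one decimal.

Cluster co-variation is summarized as the mean pairwise Pearson
correlation of members' relative-expression vectors (each replicate's
value divided by the group mean). This score is a statistic defined by
this package — the phenomenon is usually shown graphically — and pairs
with a zero-variance member are skipped and counted.

## Differential expression

FCE is the ratio of mean normalized expression, treatment over
reference (medians via flag). Two exact tests:

* **Mann–Whitney (`mw`)** — full enumeration of the rank-sum
  permutation distribution with mid-ranks for ties; two-sided
  p = 2·min(tails), capped at 1. With 6 vs 6 the smallest attainable
  two-sided p is 2/924 ≈ 2.2·10⁻³, so after BH adjustment over ~400
  tests this test cannot produce the very small padj values a count
  model can; it is kept as the distribution-free reference and for
  phenotype-style measurements.
* **Conditional NB exact test (`nb`, default)** — group sums K_A, K_B
  are modelled as NB with mean q₀·Σs_j and variance
  q₀·Σs_j + α·q₀²·Σs_j², q₀ the pooled mean of normalized counts. The
  p-value is the conditional probability, given K_A + K_B, of splits at
  most as likely as the observed one (with a 10⁻⁷ relative tolerance on
  the probability comparison to protect ties from floating-point
  rounding). α = 0 reduces exactly to the binomial-conditioned Poisson
  split, which is the independent oracle used in the tests. For totals
  above 5·10⁴ the summation is restricted to a ±50-SD window around the
  two marginal means; the excluded tail mass is far below double
  precision, leaving small-total results bit-identical to the full sum.

*Dispersion.* Per miRNA, a method-of-moments estimate
(var − mean·E[1/s]) / mean² of the normalized counts is computed within
each of the two groups (so real between-group signal does not inflate
it) and averaged; a trend α(μ) = a₀/μ + a₁ is fitted by non-negative
least squares over positive raw estimates; the working value is
max(raw, trend, 10⁻⁸). Taking the max is deliberately conservative:
with six replicates the raw estimates are extremely noisy and
underestimated dispersions inflate false positives, which matters more
here than power.

BH adjustment is applied per comparison over the tested set only.
Significance tiers: padj < 1·10⁻² (primary) and < 5·10⁻² (secondary,
used for partner confirmation), both strict.

## Concordance and repeated impact

Each tier-1 miRNA with an expressed partner strand contributes one row
(miRNA FCE/padj, partner FCE/padj, hairpin); strands without an
expressed partner are listed separately. Pair-level concordance is the
squared Pearson correlation of the two FCE columns. A hairpin is
*confirmed* when the partner's padj < 5·10⁻² (strict; one published
borderline case sits at 5.2·10⁻², which the `alpha_secondary` option
accommodates). Cluster co-transcription checks report FCE/padj and a
same-direction indicator for cross-hairpin strand pairs within a
cluster when at least one member is tier-1.

The *repeated-impact* subset intersects two comparisons sharing the
reference group: candidates are both strands of every confirmed hairpin
plus clustered strands meeting the secondary threshold in the first
comparison; members are candidates that also reach padj < 5·10⁻² in the
second comparison, and failures are reported as dropped. The
cross-comparison R² is computed over all candidate rows present in both
tables by default (matching how the published 13-row value of 0.98
reproduces), with a members-only mode available.

## Synthetic-data generator

The generator emulates the cohort structure, not sequencing physics:

* **Reference** — `n_hairpins` hairpins, each emitting a -5p and -3p
  mature strand of random 20–24-nt sequence (optionally single-strand);
  clusters assigned by index, singletons otherwise. Sequences are drawn
  to be pairwise distinct even under the ±2-nt isomiR rule and to avoid
  adapter/barcode motifs, so the read-level round trip is exact by
  construction for every seed.
* **Counts** — expectation = baseline × library depth × cluster factor
  × planted FCE; counts are NB with variance μ + αμ². Baselines are
  lognormal (median 150, log-sd 1.5 — giving ~440 of 460 strands above
  the expression filter, the scale of the profiled populations); depths
  are lognormal with log-sd 0.25; α defaults to 0.03, chosen so that
  simulated CVs average ≈ 0.22–0.28 across the abundance distribution,
  the homogeneity level the screen assumes. α = 0 is the noise-free
  limit (counts = rounded expectations), used for exactness tests.
  Members of a hypervariable cluster share one mean-one lognormal
  factor per library (log-sd 1.0 by default), the minimal mechanism
  producing within-profile co-variation.
* **Planted effects** — a fold-change on one strand in the affected
  groups; the partner receives FCE^attenuation (1 = concordant arms,
  0 = untouched partner, mimicking the discordant published set). The
  default study scenario plants six hairpins spanning FCE 0.4–4.8 on
  the perinatal groups (HF-C, HF-HF), placed on hairpins whose two arms
  both sit above the median baseline — reported impacted miRNAs are
  comfortably expressed, and planting on barely detectable hairpins
  would test the expression filter, not the repeated-impact logic.
* **Reads** — insert + barcode + adapter tail with constant quality
  `I`; a configurable fraction of 5–14-nt junk inserts exercises the
  length filter. No sequencing error, quality decay or ligation bias is
  simulated; the adapter and barcodes are arbitrary configurable
  placeholder strings.

All stages draw from independent children of a single `SeedSequence`,
so one integer seed fixes every output byte and the count layer is
unchanged whether or not reads are generated.

What passing synthetic tests does *not* show: robustness to mapping
ambiguity, sequence-dependent ligation bias, contamination, or
cross-mapping between paralogous miRNAs — real-data effects the
generator deliberately omits.

## Calibration results and run sizes

The experiments module measures, on repeated seeded cohorts: the
partner-concordance R² contrast (attenuation 1 vs 0), the empirical FDR
under a global null (2 × 6 design, 400 strands; FDR compared to the
nominal level plus two Monte-Carlo SE), and repeated-impact recovery of
the planted strands (sensitivity and false members). Default run sizes
(50 cohorts for contrast/recovery, 200 for the null, scaled-down
variants in the analysis scripts) keep the full suite in the
few-minute range while leaving Monte-Carlo error well inside the
asserted margins; the problem sizes used are recorded next to each
reported value.

## Known limitations

* The NB test's dispersion trend is a two-parameter curve; no empirical
  Bayes shrinkage of per-miRNA dispersions or fold-changes.
* No paired or multi-factor designs, covariates, or batch correction.
* Barcode matching is exact (no error correction), and quantification
  tolerates only 3′-end shifts — appropriate for synthetic data and a
  documented simplification for real libraries.
* The published summary tables bundled for cross-checks contain rounded
  values; statistics recomputed from them (e.g. pair-level R²) can
  differ in the second decimal from values computed on unrounded data.
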