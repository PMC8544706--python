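# Methods

This note records the models and conventions `isomirkit` implements, the
defaults it chooses where several reasonable options exist, and what its
synthetic-data tests do and do not demonstrate.

## Coordinates, offsets, and the isomiR identity

All sequences are stored internally as DNA (`ACGT`); RNA input is accepted
everywhere and user-facing output renders U. Hairpin coordinates are 0-based
half-open. An isomiR identity is the tuple *(mature name, 5' offset, 3'
offset, 3' NTA string, 5' NTA string)* relative to the canonical arm
interval. The sign convention for both offsets is: 0 = same terminus as the
canonical form, positive = shifted toward the hairpin's 3' end, negative =
toward 5'. Hence `+1|+1` is a one-base slide ("shifted" when lengths match),
`0|-1` a 3' trimming, `0|+1` a templated 3' extension.

**Templated precedence.** A terminal base that matches the hairpin at the
corresponding position is always interpreted as a templated extension and
never as a non-templated addition. Identity inference therefore maximises
the templated 3' extent first (fewest 3' NTA bases), then the templated 5'
extent. This rule also constrains enumeration: an NTA variant is only
emitted when its template-adjacent base differs from the hairpin base it
would otherwise copy, which guarantees that no sequence is simultaneously a
pure templated window and an NTA variant of the same arm.

**Label dialect.** `name|start|end` with explicit signs, followed by
`(+nX)` for a homopolymeric 3' NTA, `(+XY)` base-by-base for heterogeneous
NTAs, and `(5p+nX)` for a 5' NTA. The heterogeneous and 5' forms are this
package's own syntax (no printed precedent exists); both round-trip through
the parser. The parser additionally accepts the Unicode minus that
typeset tables tend to contain; rendering always emits ASCII.

**Classification.** Exactly one class per identity: canonical (all-zero),
start-site, end-site, shifted (equal non-zero offsets, no NTA), 3'/5'
non-templated addition, or mixed (two or more deviations, with the detail
set retained; an equal-offset slide inside a compound variant contributes
"shifted" to the detail rather than separate start/end entries).

## Enumeration bounds

Defaults: 5' and 3' offsets within ±5, window length 18–26 nt, NTA length
≤ 3 from alphabet {U, A}, 5' NTAs off (length ≤ 2 when enabled). The length
window matches standard small-RNA read filtering; the offset and NTA bounds
cover every label observed in the melanoma tables bundled with the package
(max |offset| 4, max NTA 2 bases, U additions dominant) with one unit of
margin. All bounds are configurable; the lookup table is a pure function of
(reference, bounds) and is rebuilt rather than cached.

## Quantification

Reads are length-filtered (18–26 nt inclusive; non-ACGU reads are counted
and dropped, not fatal), then matched exactly. Multi-mapping reads are
split equally: a read matching *k* identities adds 1/*k* to each, so the
assigned mass equals the matched-read count exactly (integer tallies;
fractional counts agree to floating precision). RPM uses the matched-read
total as denominator by default — reproducible without knowing upstream
library content — with the filtered total available as an alternative.
A feature is "detected" in a cohort when its mean RPM is ≥ 1 and it is
non-zero in ≥ 25% of samples; both thresholds are arguments everywhere the
rule is used.

## Ratios, orphans, census

IsomiR/canonical ratios are computed on cohort-mean RPM (mean first, then
one ratio per isomiR), not as averaged per-sample ratios; the ratio is
scale-invariant by construction. IsomiRs whose canonical form fails the
detection rule ("orphans") and canonical forms themselves are excluded.
The reporting filter keeps mean > 20 RPM and ratio > 1, both strict, which
reproduces the published 39-row table from its own printed columns. The
census counts canonical miRNAs with/without isomiRs, isomiRs with/without a
detectable canonical form, and the per-class breakdown of classified
isomiRs with the mixed class split by deviation combination; percentages
are reported to one decimal over each block.

## Differential contrasts

All tests operate on `log2(RPM + 0.5)`. Three engines share one result
schema (log2 fold change, t, df, p, BH-adjusted p, regulation):

* **Moderated t** — empirical-Bayes variance shrinkage. Per-feature pooled
  variances s² with d = n_A + n_B − 2 residual df are modelled as scaled F
  draws around a prior (d₀, s₀²) estimated by matching the mean and variance
  of log s² (digamma/trigamma inversion, Newton solve for the trigamma
  inverse). Shrunk variance s̃² = (d₀s₀² + d·s²)/(d₀ + d); reference
  distribution t with d₀ + d df. When the dispersion of log s² does not
  exceed what d explains, d₀ = ∞ and s₀² is the bias-corrected geometric
  mean variance (all features then share one variance and a normal
  reference). d₀ = 0 reduces exactly to the pooled two-sample t-test; the
  implementation is verified against Bioconductor limma to ~1e-14.
* **Student t** — the d₀ = 0 limit, exposed directly.
* **Welch t** — unequal variances with Welch–Satterthwaite df.

Degenerate features (zero variance): equal means give t = 0, p = 1;
unequal means give |t| = ∞, p = 0. BH adjustment is the step-up
definition (computed per contrast, never pooled across contrasts), and the
fold-change gate applies to the linear ratio of group means with a 0.5 RPM
pseudocount: a record passes when |log2 FC| > log2(threshold) and
p_adj < alpha, both strict. Mutation contrasts (NF1/BRAF/NRAS-style) are
the Welch engine driven by `<gene>_status` sample-sheet columns, with a
default alpha of 0.1 for the NF1-style low-power contrast and 0.05
otherwise.

One reporting nuance: the bundled differential table prints adjusted
p-values with two significant digits, and one row prints exactly 5.0E-02.
When *recomputing from the printed table*, a row whose printed value rounds
to exactly the gate is retained, since its unrounded value is consistent
with being below it; the strict inequality remains the contract for values
the package computes itself.

## Typology

Candidates are miRNAs with at least one isoform that is simultaneously
differentially expressed and more expressed than its canonical form (the
same isoform must satisfy both — the intersection, not the pair of
independent conditions, which would admit one extra miRNA on the bundled
tables). Each candidate is classified on two axes:

* **Trend concordance** — "similar" when all significant mature forms of
  the miRNA share one regulation sign (a single significant form is similar
  by definition). Published per-form statements sometimes encode more than
  the significance table shows — e.g. a canonical form described as flat
  while an isomiR falls, or extra forms called changed only in per-form
  plots. For such cases the function accepts an explicit per-form trend map
  (up/down/flat) with an option to count a flat form alongside a changed one
  as discordant. The bundled reproduction fixture uses that encoding, which
  is what recovers the published class-c (miR-141-3p) and class-d
  (miR-203a-3p) calls; with the significance table alone those two miRNAs
  would read as trend-similar.
* **Abundance concordance** — "similar" when the arg-max mature form by
  group-mean RPM is the same label in both groups. The top form is the
  decidable surrogate for comparing whole within-miRNA abundance
  distributions, and it is the quantity the published per-class examples
  cite. Ties break lexicographically with a logged warning.

Classes: a = similar/similar, b = similar/different, c = opposite/similar,
d = opposite/different.

## Synthetic data generator

The generator emulates the data model the pipeline consumes, not any
particular tissue: random hairpins of 60–110 nt (uniform base composition)
carry one or two non-overlapping arms of 20–23 nt. Within an arm, default
isoform shares are canonical 0.30; end-site −1/+1/−2/+2 at
0.20/0.10/0.10/0.06; 3' uridylation 0.15 (split over +1U of the canonical
and of the −1 trim); start-site 0.06; shifted 0.03 — end-site variants
dominate and uridylation is the prevailing NTA, mirroring the qualitative
census shape real cohorts show. Candidate identities that collide with the
template (e.g. a uridylation where the next hairpin base is U) are dropped
and the rest renormalised, keeping the truth table consistent with what
exact matching can see. Parent abundances are log-normal (meanlog 5,
sdlog 1.5, giving the several-orders-of-magnitude spread typical of miRNA
libraries); each sample multiplies each parent by a log-normal factor
(sdlog 0.4) for biological variability; reads are drawn multinomially at
fixed depth. Group effects act on proportions on the log2 scale and are
renormalised, so planted effects are compositional: the truth table stores
the realised (post-renormalisation) per-group proportions and log2 effects,
and large planted mass shifts visibly dampen the rest of the library —
which is faithful to RPM semantics. Reads are emitted error-free because
the quantification contract is exact matching; an optional substitution
rate exists to exercise the unmatched tally. Everything is deterministic
given the design seed.

What passing synthetic tests do **not** show: robustness to sequencing
error and quality variation, ligation bias, FFPE degradation, adapter
artefacts, or genome-level multi-mapping outside the enumerated isomiR
space. The generator's reads are drawn from the exact space the lookup
enumerates, so unmatched-read behaviour in real data is exercised only via
the substitution-error option.

## Problem sizes used in the checked examples

The bundled-table recomputations are closed-form and instantaneous. The
simulation suites use: 20 hairpins × (10+10) samples × 1e5 reads for
differential power on planted |log2 FC| = 2 effects; 5 hairpins × (10+10)
× 2e4 reads × 200 replicates for the null family-wise discovery fraction;
30 hairpins × (8+8) × 1e5 reads for planted typology classes (the four
planted parents are chosen among minor-share parents so compositional
renormalisation barely perturbs the planted effects). These sizes give
stable verdicts across seeds while keeping the whole suite in seconds.

## Known limitations

* The enumeration bounds are a superset of the labels the bundled tables
  print; other tools' internal search spaces may differ at the margins.
* 5' and 3' NTAs are not combined on a single read (no printed label of
  that kind exists; the identity type can represent it, the enumerator does
  not emit it).
* Equal fractional splitting of multi-mapped reads is a convention chosen
  for count conservation; a count-to-all alternative would inflate totals.
* The scale of "normalized expression" in the bundled tables is not fully
  specified by their source; the package therefore treats ratio-based and
  count-based quantities — which are scale-invariant — as the reproducible
  surface.
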