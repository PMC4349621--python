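# Methods

`mirhd` re-implements, as a tested and reusable pipeline, a small-RNA
sequencing analysis of Huntington's disease (HD) prefrontal cortex: raw
reads are filtered and trimmed, assigned to mature miRNAs with a
5′-anchored isomiR-tolerant counting rule, normalized and
batch-adjusted, and then related to disease status, Vonsattel grade and
CAG-adjusted clinical features. Because the human cohort itself is not
shipped, every input is produced by a seeded synthetic-data generator
with planted truth; this note records the models, the defaults and the
reasoning behind the open design choices.

## Read-level processing

Reads are Phred+33, fixed 51 nt with 3′ adapter read-through. The stage
order is fixed and load-bearing: **quality → adapter trim → length →
collapse**.

* **Quality filter** — a read survives iff at least 80% of its bases
  reach Phred ≥ 20 (both comparisons inclusive, matching the FASTX
  `-q 20 -p 80` semantics). Bases called `N` count toward the
  denominator but never the numerator; the data are silent on this and
  the conservative reading was chosen.
* **Adapter trimming** — the TruSeq small-RNA 3′ adapter
  `TGGAATTCTCGGGTGCCAAGG` is removed with cutadapt-style semantics:
  candidate start positions are scanned 5′→3′ and the first position
  whose overlap (full adapter, or a prefix reaching the read end, at
  least `min_overlap = 3` nt) matches with at most
  `floor(0.1 · overlap)` mismatches wins, which selects the longest
  admissible occurrence. One consequence is documented rather than
  hidden: trimming is not strictly idempotent, because a correctly
  trimmed read can by chance end in a 3-nt adapter prefix that a second
  pass would remove. The quality and length filters are idempotent.
* **Length filter** — inserts shorter than 15 nt are discarded (applied
  after trimming, per the stated order).
* **Collapse** — identical sequences are merged with multiplicities,
  ordered by multiplicity descending then sequence, so downstream output
  is deterministic for any input order.

## 5′-anchored quantification

Alignments are assumed ungapped and mismatch-free (the emulated study
aligned with zero mismatches, making indels impossible; gapped or
clipped records are rejected with a warning as our own convention).
Coordinates are 1-based inclusive everywhere; BED is converted at the
I/O boundary.

For each alignment, a mature miRNA is *hit* when (i) chromosome and
strand match, (ii) the intervals overlap by ≥ 1 base, and (iii) the
read's 5′ end lies within ±4 nt (inclusive) of the annotated mature 5′
end — the window that tolerates 5′ isomiRs. Requiring overlap *and*
window membership mirrors the two-step intersect-then-window procedure;
whether the original window rule implicitly required overlap cannot be
determined from the text, so the stricter conjunction was chosen and is
covered by tests. Per collapsed read:

* length > 27 nt → removed;
* hit sets are unioned across all of the read's alignment loci:
  exactly one distinct mature id → counted **once** (multi-locus
  mappings of one mature collapse); two or more distinct matures →
  discarded; none → unassigned.

Reads hitting the 5p and 3p arms of one precursor fall under the
multi-mature discard; the aligner-side multimap cap is exposed as
`max_loci` (default unlimited). Counts are sums of collapsed-read
multiplicities; the four outcome classes partition the reads exactly.

## Normalization

Order: mean-count filter → size factors → VST → batch adjustment, with
**all** samples (controls, grade 0, symptomatic) included throughout.

* **Filter** — miRNAs with mean raw count < 2 across all samples are
  removed (mean exactly 2 survives).
* **Size factors** — median-of-ratios over miRNAs positive in every
  sample, then log-centered to geometric mean 1 (centering preserves
  all ratios; it makes factors comparable across runs). When no miRNA
  is positive everywhere, a positive-subset fallback is used with a
  warning. A caveat worth knowing: on small panels with a large,
  direction-biased DE fraction (≳ 15%), the median itself is
  contaminated and all null features inherit a small condition effect.
  The synthetic study therefore uses panels with ≤ 8% planted DE,
  matching the emulated study's proportions (75 of 938).
* **Dispersion trend** — per-miRNA method-of-moments dispersions are
  regressed onto `α(μ) = α0 + α1/μ` (asymptotic plus extra-Poisson
  term) by gamma-style IRLS on the positive estimates with one
  outlier-trimming pass. The parametric closed form was preferred over
  a spline trend because it is analytically testable.
* **VST** — the closed-form antiderivative of `1/√v(μ)` for
  `v(μ) = μ(1+α1) + α0μ²`, calibrated to the log2 asymptote:
  `vst(q) = log2((1 + α1 + 2α0 q + 2√(α0 q (1 + α1 + α0 q))) / (4α0))`.
  Strictly monotone; equals `log2 q` for `q ≫ 1/α0`. This also means
  fold changes of weakly expressed features are shrunk toward zero on
  the VST scale — parameter-recovery tests therefore plant effects on
  well-expressed features.
* **Batch adjustment** — parametric empirical-Bayes location/scale
  adjustment (ComBat) with an intercept-only covariate model, matching
  the cited tool's defaults: per-feature standardization against the
  batch design, normal prior on batch locations, inverse-gamma prior on
  batch scales, priors by method of moments, posterior means by
  iterated conditional expectations. Batches come from the metadata
  `batch` column and are never guessed; a batch with < 2 samples is an
  error. Noise-free degenerate inputs (zero pooled variance) fall back
  to point estimates so a pure location shift is removed exactly. The
  implementation is cross-checked against `sva::ComBat` in the test
  suite; agreement is ≈ 1e-3 on typical matrices.

## Differential expression

Symptomatic HD (grades 2–4) versus controls — grade-0 brains are
excluded from this contrast — with age at death as the only covariate.
Per-miRNA OLS on `[1, condition, age_death]`; residual variances are
moderated by empirical Bayes: the prior degrees of freedom `d0` and
prior variance `s0²` are estimated by matching moments of `log s²`
(digamma/trigamma equations, trigamma-inverse by Newton iteration), and
the moderated `t = β̂ /(s_post √v)` is referred to `t(d0 + d_res)`.
With no excess spread among variances the fit returns `d0 = ∞` and the
plain pooled variance. Forcing `d0 = 0` recovers the ordinary t-test;
the implementation matches `limma::eBayes` to ≈ 1e-5 in the test suite.
Q-values are Benjamini–Hochberg over all quantified miRNAs, ties broken
by stable input order.

## Grade, features, clustering

* **Grade (dual ANOVA)** — for each differentially expressed miRNA, one
  fixed-effects one-way ANOVA across grades 0–4 *plus* controls as a
  sixth group, and one restricted to HD brains; a miRNA is
  grade-associated when BH-q < 0.05 in **both** runs. The FDR family
  for both runs is the DE set (the alternative, 75-vs-65, is ambiguous
  in the source and the full DE family is the default, configurable).
  Pairwise contrasts use Tukey–Kramer studentized-range p-values
  (Bonferroni available as an option) and are summarized by an
  insert-and-absorb compact letter display whose validity predicate
  (share a letter ⟺ not significantly different) is checked
  exhaustively in tests. The pipeline's grade stage drops groups with
  fewer than 2 samples before testing (small synthetic cohorts can
  produce singleton grades); the statistical routine itself refuses
  such groups.
* **CAG residualization** — onset is modeled as `ln(onset) = a + b·CAG`
  (the published coefficient values are not recoverable from the
  source, so the model family is refitted on the supplied reference
  cohort); duration, death age and the Hadzi-Vonsattel striatal and
  cortical scores are linear in CAG. Fits use every sample with
  present CAG ≤ 55; higher or missing CAG is excluded and flagged. The
  fitting cohort (n = 346 by default) is larger than the analysis set,
  as in the emulated study, and residuals are orthogonal to CAG within
  it by construction.
* **Feature regressions** — per-miRNA simple OLS of expression on each
  CAG-adjusted feature in symptomatic HD brains only, deliberately with
  no further covariates; BH over the DE set. A multivariate variant
  reports the striatal partial slope adjusted for cortical score,
  erroring if the two residual features are collinear (|r| > 0.999).
* **ROC/AUC** — Mann–Whitney with half-weight ties, equal to
  trapezoidal ROC integration; 95% CI from the DeLong placement
  variance, clipped to [0, 1].
* **Clustering** — Pearson correlations of DE-miRNA expression to the
  five CAG-adjusted features (symptomatic HD only); rows with at least
  one nominal p < 0.05 are kept and rows/columns are clustered
  independently with Euclidean distance and complete linkage.

## Synthetic data: what it emulates and what it does not

The generator is first-class, seeded code; one `numpy` generator drives
a whole run, so identical config + seed gives byte-identical outputs.

* **Genome/annotation** — mature sequences are planted in a small
  random genome on both strands, including multi-locus matures
  (identical sequence at two loci) and overlapping locus pairs (two
  distinct matures whose ±4 windows can both capture one read); the
  generator verifies by exhaustive string search that every mature
  occurs at exactly its annotated loci and errors otherwise.
* **Reads** — each read is a mature sequence with a 5′ offset (discrete
  Gaussian of sd 1.2 nt truncated to ±4, plus a configurable fraction
  at ±5–6), the full adapter, and random padding to 51 nt; planted
  quality failures violate the 80%-Q20 rule deterministically; decoys
  are substrings of unannotated genome. Per-read truth records the
  offset, locus count, hit set and whether the read should be counted.
* **Cohort** — counts are negative-binomial with trend
  `α(μ) = 0.05 + 2/μ`, base means `2^U(2,8)`, library sizes
  `U(0.7, 1.4)` on the log scale, a two-batch structure (log2 shift
  0.35, dispersion ×1.4), and planted condition log2 fold changes
  (|lfc| ∈ [1, 3], 60% up). Clinical structure follows the emulated
  cohort's Table-1 shape: 26 symptomatic HD, 2 asymptomatic grade-0
  gene carriers (CAG 42, no onset or H-V scores), 36 controls; CAG
  ≈ 44.6 ± 2.9; `ln(onset) = 6.47 − 0.06·CAG + ε` with σ = 0.18 chosen
  to give onset ≈ 44.5 ± 12 y at the cohort CAG distribution; striatal
  score 2.70-centered with a CAG slope and a latent per-brain severity
  scale; cortical score coupled to striatal; grade derived by binning
  the striatal score (mirroring the r ≈ 0.9 grade–striatal coupling).
  The severity latent couples planted-DE expression to earlier onset
  and higher striatal score, reproducing the sign structure that the
  correlation-clustering stage should recover.
* **Not emulated** — sequencing substitution errors beyond quality
  draws, PCR duplicates, realistic genome content or miRNA families,
  cell-type composition, and any batch–condition confounding. Passing
  tests therefore demonstrate correctness of the pipeline's logic and
  calibration of its statistics under the stated models, not robustness
  to artifacts absent from the generator.

## Problem sizes and numerical choices

The test suite runs read-level checks at 4,000–20,000 reads and
count-level statistics at up to 938 features × 60 samples × 10 seeds;
the end-to-end acceptance run uses the full 64-sample cohort with a
300-miRNA panel (~1.4 M reads), sizes chosen as good desk-scale
statistical practice for a reproducible artifact. Tolerances: exact
identities (BH, AUC-vs-integration, F = t², Tukey k = 2) are asserted
at 1e-8–1e-12; cross-implementation checks against R (limma, sva,
DESeq2) at 1e-3–1e-5; simulation-based recoveries at the spread
expected from their replicate counts. Dispersion fits clamp `α0` to a
small positive value when degenerate; ComBat clamps zero variances; BH
breaks ties by stable input order.
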