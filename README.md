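# mirhd

Small-RNA sequencing analysis for Huntington's disease (HD) brain: from
raw reads to miRNA counts with a 5′-anchored, isomiR-tolerant
quantifier, through variance-stabilized and batch-adjusted expression,
to the association of miRNA expression with disease status, Vonsattel
grade, and CAG-adjusted clinical features (age of onset, disease
duration, age at death, Hadzi-Vonsattel striatal and cortical scores).

It is written for computational biologists who want a transparent,
fully tested re-implementation of this analysis style — every stage is
a plain Python function over pandas objects, every input can be
generated synthetically with planted truth, and the whole chain is
deterministic given a seed.

## What it computes

**Quantification.** Collapsed reads with ungapped, mismatch-free
alignments are assigned to mature miRNAs when they overlap the
annotated interval and their 5′ end lies within ±4 nt of the annotated
mature 5′ start (tolerating 5′ isomiRs). Reads > 27 nt are removed;
reads mapping to several loci of a *single* mature count once; reads
hitting two or more distinct matures are discarded.

**Normalization.** miRNAs with mean raw count < 2 are dropped;
median-of-ratios size factors; a closed-form variance-stabilizing
transform for negative-binomial counts with dispersion trend
α(μ) = α₀ + α₁/μ,

    vst(q) = log2( (1 + α₁ + 2α₀q + 2√(α₀q(1 + α₁ + α₀q))) / 4α₀ ),

which approaches log₂ q at high counts; then parametric empirical-Bayes
location/scale batch adjustment (ComBat-style, intercept-only model).

**Inference.** Moderated t-statistics with empirical-Bayes variance
shrinkage (prior df by trigamma moment matching, as in limma) for HD
grades 2–4 vs control adjusting for age at death, with
Benjamini–Hochberg q-values; dual ANOVA across Vonsattel grades (with
and without controls) with Tukey–Kramer pairwise tests and a compact
letter display; ROC/AUC with DeLong confidence intervals; clinical
features residualized on CAG repeat length (ln-onset model for onset,
linear otherwise, samples with CAG > 55 excluded) before per-miRNA
regressions; and Pearson-correlation clustering of miRNA–feature
relationships (Euclidean distance, complete linkage).

The moderated t, ComBat and size-factor implementations are
cross-checked in the test suite against `limma`, `sva::ComBat` and
`DESeq2` through Rscript.

## Worked example

Simulate a small cohort (12 HD, 2 asymptomatic grade-0, 12 control
brains; 40 miRNAs, 8 of them with planted fold changes) and run every
stage:

```yaml
# run.yaml
seed: 7
simulate:
  n_mirnas: 40
  n_hd: 12
  n_grade0: 2
  n_control: 12
  n_de: 8
  base_log2_mean_range: [2.0, 7.0]
```

```text
$ mirhd run-all --config run.yaml --outdir example_run
simulate: samples=26, mirnas=40, reads=52360
preprocess: input_reads=52360, surviving_reads=50787
quantify: mirnas=40, samples=26, assigned_mass=42630
normalize: mirnas_after_filter=38, alpha0=0.12815717, alpha1=2.06030104
de: tested=38, significant=9
grade: tested=9, significant_both=0
features: tested=9, significant=1
cluster: mirnas=1
manifest: example_run/manifest.json
```

Reading the log: 52,360 simulated 51-nt reads survive quality/adapter/
length filtering almost intact (50,787), of which 42,630 read copies
are assigned to a unique mature miRNA (the rest are too long, hit two
matures, fail the ±4 nt window, or are decoys). Two miRNAs fall below
the mean-count-2 filter, the fitted dispersion trend is
α(μ) ≈ 0.13 + 2.06/μ, and 9 of 38 tested miRNAs come out differentially
expressed at q < 0.05 — the 8 planted ones plus one false call at this
small sample size. The top of `example_run/de_results.tsv`:

```text
miRNA            average_expression  log2_fold_change  p_value  q_value
hsa-miR-1005-3p              3.7749           -1.5481      0.0      0.0
hsa-miR-1019-3p              6.9062            1.5602      0.0      0.0
hsa-miR-1028-5p              7.3990            1.2739      0.0      0.0
```

All three are planted effects (true log2 fold changes −2.10, 1.89 and
1.64; the smaller estimates reflect VST shrinkage at moderate counts).
Every stage can also be (re)run individually — `mirhd de --outdir
example_run` — and resumes from the files on disk; two runs with the
same config and seed are byte-identical.

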