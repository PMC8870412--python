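# Methods

## The screening model

The screen looks for transcripts whose induction in tumor cells is
plausibly *caused* by promoter DNA demethylation, rather than merely
co-occurring with it.  The operational definition has three parts:

1. **Repressed ground state.**  In normal lung tissue and in alveolar
   type II (AT2) cells — the presumed cell of origin of lung
   adenocarcinoma — the transcript is silent (TPM < 1) and its promoter is
   methylated (mean CpG beta ≥ 0.60 over TSS ± 400 bp).
2. **Ectopic activation.**  Across a panel of tumor cell lines the
   transcript is repressed in at least two lines (10th expression
   percentile ≤ 0.1 TPM, and ≥ 2 lines individually ≤ 0.1 TPM) yet reaches
   ≥ 2 TPM in at least one; its promoter methylation spans the full range
   (minimum < 0.40, maximum > 0.60).
3. **Inverse coupling.**  Pearson correlation between log2(TPM+1)
   expression and promoter beta across lines satisfies r ≤ −0.4 with
   p < 0.05 over at least 7 complete pairs.

Transcripts passing all three are DDIC.  The control class (non-DDIC) is
selected from single-transcript genes that satisfy the repression and
activation criteria on expression but show *no* methylation coupling
(−0.1 ≤ r ≤ 0.1); genes in between belong to neither class, so the two
sets are disjoint by construction.

Promoter methylation is the unweighted mean beta of CpGs in the symmetric
TSS ± 400 bp window (strand is used only to pick the 5′-most reference TSS
when start sites < 50 bp apart are merged and their expression summed).
CpGs need coverage ≥ 2 where coverage information exists; windows with
fewer than 3 qualifying CpGs yield MISSING, and MISSING propagates by
pairwise deletion everywhere except the normal-reference filter, where it
fails conservatively (an unmeasurable promoter cannot be shown to be
methylated).

### Two readings worth recording

* "Repressed in at least 2/26 cell lines (expression quantile 10
  ≤ 0.1 TPM)" is implemented as the conjunction of both printed numbers:
  the per-transcript q10 (linear interpolation between order statistics)
  must be ≤ 0.1 TPM *and* at least two lines must individually be
  ≤ 0.1 TPM, since with 26 samples the quantile condition alone does not
  guarantee two repressed lines.
* The correlation gate uses the raw p < 0.05 by default;
  Benjamini–Hochberg-adjusted values over all groups reaching the gate are
  always reported alongside, and `ScreenConfig.p_gate="bh"` switches the
  gate to the adjusted value.

## Tissue programs

Genes surviving the screen are profiled as median TPM per normal tissue,
clustered by Ward linkage on Euclidean distances of log2(TPM+1) profiles,
and labelled by marker-tissue argmax of each cluster's mean profile:
CG = testis; GI = small intestine, colon; SE = esophagus, skin, vagina;
everything else Other.  `Low` (maximum median < 2 TPM in every tissue) is
decided gene-by-gene before any clustering and overrides cluster labels.
The log2 transform is a deliberate choice — raw TPM lets a single
high-expression gene dominate the metric — and is switchable
(`transform="raw"`).  The number of clusters is an analysis parameter
(`--k`, default 8 in the CLI); with disjoint marker sets, over-cutting is
harmless because several clusters may share a program label.

## Tumor-cohort validation

Activation groups per gene use expression quantiles over tumors
(non-activating < q20, activating > q80, linear interpolation); when q80
< 1 TPM the quantiles are uninformative and a fallback applies
(activating = TPM ≥ 1).  Promoter methylation in tumors comes from array
probes within TSS ± 400 bp (genes without in-window probes are MISSING,
not zero).  The global-methylation proxy is the per-sample mean beta over
autosomal probes constitutively methylated in normal samples; "higher
than 0.7 in all normal lung samples" is read as per-sample strict
exceedance (`rule="each"`), with the cross-sample-mean reading available
as `rule="mean"`.  A tumor is called hypomethylated when its proxy falls
below the 25th percentile of the normal-sample proxies.  The
promoter-vs-global association compares proxy means between
promoter-methylated (≥ q80) and promoter-demethylated (≤ q20) tumor
subgroups with Welch's t-test (the unequal-variance form is the safer
default for a "Student's t-test" with unstated variance assumption;
`equal_var=True` restores the pooled form), signed so that
demethylation-coincides-with-hypomethylation is positive.

## Clinical association

Grade uses a chi-squared test on the activating × harmonized-grade
contingency table (grades 1.5 → 1, 2.5 → 2; levels empty in both groups
dropped; no continuity correction).  Survival uses the log-rank test with
a log2 ratio of Kaplan–Meier medians as effect size; the median is the
product-limit convention implemented in lifelines (the earliest observed
time at which the estimate falls below 0.5), and a curve that never
reaches 0.5 contributes the study length instead.  Both tests require at
least 15 tumors per group and otherwise return a non-evaluable record
with a reason.  Induction frequencies under a demethylating agent are
compared per program against the non-DDIC class with Fisher's exact test;
differential-expression calling itself is upstream input, not part of
this package.  Benjamini–Hochberg adjustment is applied within each test
family (all grade tests together, all survival tests together, all
induction tests together), with NaN (untested) entries passed through.

## The synthetic cohorts

The generator fabricates every input with known truth so each stage is
testable offline.  Its defaults are the study conditions: 26 cell lines,
a 300-tumor cohort with 32 normals, and a normal panel of 11 tissues with
4 samples each.

* **Methylation states** are Beta distributed: methylated ~ Beta(17, 3)
  (mean 0.85), demethylated ~ Beta(3, 17) (mean 0.15), drawn per CpG or
  per probe.  Constitutively methylated background probes use a tighter
  Beta(136, 24) (mean 0.85, sd ≈ 0.03): the dispersion is kept small so
  that selecting probes on the normal samples induces negligible
  selection bias, and tumors with no planted demethylation are
  statistically indistinguishable from normals on the proxy.
* **Expression** is lognormal: active median 20 TPM, silent median
  0.05 TPM, σ = 1 on the log2 scale; sequencing coverage is Poisson
  (mean 30) + 1.
* **Cell-line coupling.**  Each planted DDIC gene is silent + methylated
  in a random 8–20 of the 26 lines and active + demethylated in the rest.
  Planted non-DDIC genes toggle expression on the same pattern while
  promoters stay methylated; their per-line promoter means are then
  residualized against log-expression so the *sample* correlation is
  planted at zero — with n = 26 the null sampling sd of r is ≈ 0.2, so
  merely independent draws would land inside the |r| ≤ 0.1 band only
  ~40 % of the time, which would say nothing about the selection logic
  under test.
* **Tumor demethylation** is a step model: tumor-wide factor
  h ~ Uniform(0, 0.4) is subtracted from background betas, and a gene's
  promoter flips to the demethylated state when h × sensitivity exceeds a
  gene-specific threshold drawn from Uniform(0.05, 0.15) — attainable for
  every gene within the h range, so the sidecar's "demethylation-driven"
  label is always realized in some tumors.  Germline-program genes get
  sensitivity 0.5 and somatic programs 0.85–0.9, reproducing the ordering
  in which somatic-program promoters demethylate already at intermediate
  genome-wide hypomethylation.  No claim is made about the real
  functional form of this coupling, which is unknown.
* **Transcription-factor gating.**  A simulated factor is expressed in
  30 % of tumors; gated genes require it in addition to promoter
  demethylation, producing the demethylated-but-silent tumor subset and
  attenuated per-gene correlation.
* **Clinical covariates.**  Grade is logistic (base probability 0.45 of a
  high grade, odds multiplied by a gene's planted odds ratio in tumors in
  that gene's upper expression half, so exposure groups are balanced);
  survival is exponential with the hazard multiplied by planted hazard
  ratios, administratively censored at 4 000 days.

What the generator does **not** emulate: read-level data, probe
cross-hybridization and batch effects, tumor purity, correlated noise
between neighboring CpGs, multi-transcript genes (every simulated gene
has one transcript; extra TSS for merge tests are constructed directly in
the unit tests), and continuous (rather than two-state) promoter
methylation in tumors.  Passing tests therefore demonstrate the
correctness of the selection logic and statistics under the stated noise
model, not performance on real bisulfite or array data.

## Numerical choices

Coordinates are 0-based half-open throughout; 1-based probe manifests are
converted on read; Bismark-coverage positions are taken as written.
Forward/reverse calls at complementary CpG positions (p, p+1) are merged
on read by coverage-weighted average onto p, greedily from the left, so
re-reading a merged track is a no-op.  Betas are stored as fractions;
percent thresholds compare as fractions (60 % = 0.60).  Quantiles use
linear interpolation between order statistics.  Undefined correlations
(n < 3 or a constant vector) are NaN, never an exception; a degenerate
t-test between two zero-variance groups with equal means returns t = 0,
p = 1.  Tracks are written with `%.17g` so float round-trips are exact.

## Problem sizes

Tests and the acceptance script run the screen on 200 genes × 26 lines,
program recovery on 103 genes × 11 tissues, the tumor analyses on 300
tumors + 32 normals with ~5 000 background probes, and clinical
calibration on 200 null genes plus planted effect genes — sizes chosen so
the whole suite completes in well under a minute while keeping the
binomial noise on measured rates (sensitivity, type-I error) small enough
for the stated bands to be meaningful.

## Known limitations

The automated structural check is a weak surrogate for manual
genome-browser curation: it only catches expression calls with no mapped
body signal.  Cluster-to-program labelling assumes marker tissues are
present in the profile and that marker sets are disjoint.  The BH family
scoping (per test type) is a convention; scoping across families would
give different adjusted values.  No purity deconvolution, batch
correction, Cox modelling or multivariate adjustment is attempted.
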