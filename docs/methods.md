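# Methods

## Scope and data model

`methylstab` analyses probe-level methylation beta values (fractions in
[0, 1]) from paired-timepoint studies: each cohort supplies a probes ×
samples beta matrix, an aligned detection p-value matrix, and a design
pairing every subject to exactly one sample per timepoint (technical
replicates allowed). Cohorts measured on different array generations are
merged by probe-ID intersection; intensity-level processing (IDAT
parsing, probe-type normalization, batch correction) is out of scope and
inputs are assumed already batch-corrected — the pipeline records an
attestation flag for provenance rather than correcting batches itself.

## Pipeline order and filtering

Stages run in a fixed order: harmonize probes → detection filter →
quantile normalization (per cohort) → stability metrics → gap calling →
genetic-influence union → thresholds → classification. Filtering is
two-stage. The probe stage defaults to the strict *any-sample* rule: a
probe is removed everywhere if any sample in any cohort has detection
p > 0.01. The phrase "p above cut in any dataset" is ambiguous between
this reading and an aggregate per-dataset rule, so a `max_fraction`
alternative (remove a probe when more than a chosen fraction of samples
fail) is provided and the rule in force is echoed in the report. The
sample stage removes samples whose mean detection p over retained probes
exceeds 0.01; under the any-sample probe rule this stage can never fire
(every retained cell is ≤ 0.01, so no mean can exceed it), which is why
it only bites with `max_fraction`. Removal reports satisfy
retained + removed = input at every stage.

Quantile normalization is classic column QN on beta values within a
cohort: replace each value by the across-sample mean of the order
statistics at its rank; ties receive the mean of the values they span,
so sorted columns are exactly identical afterwards. Missing cells are
imputed by the probe median for ranking and restored afterwards. QN on
betas (rather than intensities) is the documented choice; note that QN's
effect depends on grid density — on very small probe panels (hundreds)
the coarse order-statistic grid can dominate genuine within-subject
noise, so the unit-test fixtures that isolate the metric logic disable
it, while realistic panels (thousands to hundreds of thousands of
probes) are unaffected.

## Stability metrics

Per probe and cohort, on subjects with complete pairs (missing values
removed pairwise; technical replicates averaged per (subject, timepoint)
first — a `drop_replicates` option keeps only the first instead, since
source studies rarely state their convention):

* MAD = mean |β₂ − β₁|; cross-cohort aggregate MMAD = max.
* ICC(A,1) from the two-way ANOVA mean squares,
  ICC = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)) with k = 2; the
  95 % CI uses the standard F-based interval with Satterthwaite
  denominator df. Cross-cohort aggregate: min. ICC is undefined (NaN)
  when total variance is zero (up to a 1e−20 sum-of-squares rounding
  guard) and when a cohort has fewer than 3 complete pairs; NaN
  propagates through min/max aggregation and is excluded from
  percentile computations.
* Paired t-test p (two-sided) on β₂ − β₁. Degenerate inputs: zero
  variance with nonzero mean is reported as p = 0 (the infinite-t
  limit); zero variance with zero mean is undefined (NaN).
* Pearson r of β₁ vs β₂ (NaN if either vector is constant).
* SD per cohort pools all the cohort's samples, both timepoints and
  replicates included (the source convention does not separate
  timepoints); mean SD averages cohorts, and MMAD/mean SD is reported
  with a NaN sentinel at mean SD = 0.

Aggregation (max/min) always acts on unrounded values; rounding happens
only at serialization (≥ 6 significant digits in the TSV). This is why a
printed minimum can be one unit in the last decimal below the minimum of
the printed per-cohort values.

## Gap calling

Sorted beta values of a probe (all samples of a cohort, timepoints
pooled) are segmented: a new group opens where consecutive sorted values
differ by ≥ `gap_threshold` (default 0.05; "≥" makes ties
deterministic). A call with ≥ 2 groups is *outlier-driven* when the
samples outside the largest group number < ⌈`out_cutoff`·n⌉ (default
out_cutoff 0.01; ceil with strict "<" is the pinned boundary
convention), and outlier-driven calls are suppressed by default. These
defaults follow the published gap-hunting method. Known limitation
inherited from that method: sensitivity is limited among highly stable
probes, and no algorithmic remedy is attempted — visual review remains
advisable for candidate hyperstable probes.

## Classification

Genetic influence = manifest SNP flag OR gap call in any cohort; the
summary reports |SNP|, per-cohort gap counts, the gap union, the overlap
and the union, which obey inclusion–exclusion exactly. Any non-empty
value in the configured manifest SNP column (default `Probe_SNPs`) sets
the flag; SNP distance/allele detail is not modelled, and the column
name is configuration because manifests differ.

Percentile cuts use linear interpolation between order statistics
(`numpy.quantile` default) over probes with defined metrics, computed on
the final filtered table with genetic probes included; the genetic
exclusion applies after thresholding (the published counts — 239 meeting
both criteria, 172 after genetic exclusion — imply this order). Fixed
cuts (0.01 / 0.74) override the percentiles when supplied. Hyperstable
requires strict inequalities (MMAD < cut, min ICC > cut); probes exactly
at a cut are excluded, and the same cuts define the four MMAD × ICC
quadrants. "Invariant" has no published operational definition; the
flag implemented here is mean SD < 0.1 (the SD dichotomy at 0.1
separates genotype-driven from quiet probes), with an optional
refinement to extreme mean methylation (< 0.2 or > 0.8) that is off by
default.

## Synthetic studies

The generator emulates the structure of multi-cohort paired blood
methylome studies; per-probe class labels, logit means, SNP flags and
minor-allele frequencies are shared across cohorts while subjects,
genotypes and noise are cohort-specific. Nongenetic probe j, subject i:
latent u_ij ~ N(μ_j, σ_b,j); measurement t = expit(u_ij + drift·1[t=2]
+ e_ijt), e_ijt ~ N(0, σ_w,j) — the logit-normal model reproduces the
heteroscedasticity of beta values towards the extremes. With drift = 0
(the default) the population agreement ICC on the logit scale equals
σ_b²/(σ_b² + σ_w²) exactly, which the truth table records; nonzero
drift exists to exercise paired-t sensitivity. Genetic probe j: genotype
g_i ~ Binomial(2, maf_j) (Hardy–Weinberg), both timepoints at
`cluster_means[g_i]` (default 0.1/0.5/0.9) plus beta-scale N(0, 0.02)
noise clipped to [0.001, 0.999]; genotypes are germline and identical at
both timepoints. Detection p-values are U(0, 0.005) for passes and
U(0.011, 0.5) for sporadic failures (rate 2×10⁻⁴). Everything is
deterministic given (seed, cohort index).

Default conditions (3 cohorts × 60 subjects × 20,000 probes — desk
scale) and class parameters, chosen to mirror the magnitudes seen in
real blood 450k/EPIC stability data:

| class | fraction | μ range (logit) | σ_b | σ_w | rationale |
|---|---|---|---|---|---|
| invariant | 0.15 | ±(2.5, 4.5) | 0.10 | 0.10 | extreme methylation, tiny beta-scale SD |
| dynamic | 0.55 | (−3, 3) | 0.07 | 0.20 | true logit ICC ≈ 0.11, worst-cohort MAD ≈ 0.02–0.04 — matches the dominant low-agreement bulk |
| stable_nongenetic | 0.10 | (−1.5, 1.5) | 0.18 | 0.022 | beta SD ≈ 0.03 and MAD ≈ 0.006–0.008, i.e. clear of the 0.01/0.74 cuts while staying unimodal for gap calling, like real hyperstable probes (MAD/SD ≈ 0.3) |
| genetic | 0.20 | — | — | — | with the 0.66 SNP-flag rate on genetic probes and 0.05 on others, the flagged-or-gapped share approaches the ~28 % genetic fraction of the real array |

What the generator does **not** emulate: batch/plate effects, cell-type
composition shifts, probe cross-hybridisation, array-generation
differences beyond probe-set size, and age-dependent drift. Passing
recovery tests therefore demonstrates the correctness and calibration of
the statistics under the stated generative model, not robustness to
those real-data artefacts.

## Verification strategy and problem sizes

The ICC implementation is checked two ways: against a brute-force
sums-of-squares ANOVA oracle (500 random n×2 tables, n ∈ [3, 50],
agreement 1e−10) and against an independent library implementation of
the agreement ICC (point estimates to 1e−10; CI bounds to the oracle's
printed precision). Parameter recovery runs 200 probes per true ICC
level {0.2, 0.5, 0.8} at n = 120 subjects (tolerance ±0.05, with the
σ_total = 0.25 scale keeping the logit→beta mapping near-linear so the
beta-scale estimate tracks the logit-scale truth), and the E[MAD] =
2σ/√π identity is checked on beta-scale Gaussian-noise probes (10 %
relative tolerance). Gap calling is assessed at n = 120 samples with
cluster separation 0.4 and maf ∈ [0.2, 0.5] (≥ 95 % sensitivity,
≤ 5 % false positives on quiet unimodal probes). The end-to-end
determinism and conservation checks run the full default 3 × 60 ×
20,000 study twice and compare outputs byte for byte; the acceptance
script uses a 3 × 60 × 4,000 study for its pipeline-level quantities,
a size at which every reported rate is stable across seeds.

## Known limitations

* ICC confidence intervals use one specific F-based construction;
  variants differing in the denominator df exist, and only the point
  estimate feeds classification.
* The any-sample detection rule is aggressive on large cohorts (a single
  failing cell removes a probe everywhere); use `max_fraction` when that
  is unacceptable.
* Gap calling inherits the limited sensitivity of the gap-hunting
  approach for subtle genotype effects; the genetic-influence flag is a
  lower bound on genetic involvement.
* The hyperstable set depends on percentile cuts computed from whatever
  probe universe survives filtering; with small synthetic panels the
  5th/95th percentiles land elsewhere than on a full array, which is why
  fixed cuts are used in recovery experiments.
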