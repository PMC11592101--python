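# methylstab

Longitudinal stability of blood DNA methylation probes measured on
Illumina Infinium arrays (450k/EPIC).

Whole-blood methylation levels drift considerably over periods of a year
or more, yet biomarker panels, epigenetic scores and studies of early
epigenetic programming all implicitly assume that the probes they use
report something stable about a person. `methylstab` quantifies that
assumption probe by probe, for studies in which the same subjects were
sampled at two timepoints in one or more cohorts, and separates genuinely
stable biology from stability that merely reflects germline genotype.

## The statistics

For each probe, in each cohort, over the n subjects with complete pairs
of beta values (β ∈ [0, 1], second timepoint minus first):

* **MAD** — mean absolute difference, `MAD = (1/n) Σ |β_i2 − β_i1|`, the
  absolute-error facet of stability. Across cohorts the worst case is
  kept: **MMAD = max(MAD)**.
* **ICC(A,1)** — two-way, absolute-agreement, single-measure intraclass
  correlation, the trend-preservation facet. With MSR, MSC, MSE the
  between-subject, between-timepoint and residual mean squares of the
  two-way ANOVA and k = 2,

  `ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))`,

  with the F-based 95 % confidence interval (Satterthwaite denominator
  degrees of freedom). Across cohorts the worst case is kept:
  **min ICC**.
* Paired *t*-test p-value, Pearson r, per-cohort SD of all beta values
  (timepoints pooled) and the ratio MMAD / mean SD complete the record.

Downstream classification:

* **genetic**: the manifest flags a SNP near the probe, or *gap calling*
  (sorted beta values split into clusters separated by gaps ≥ 0.05, not
  driven by < ⌈0.01·n⌉ outlying samples) fires in any cohort.
* **hyperstable**: MMAD below the 5th-percentile cut and min ICC above
  the 95th-percentile cut (strict inequalities; fixed cuts 0.01 / 0.74
  can be supplied instead), with the non-genetic subset reported
  separately.
* **quadrants**: the same two cuts split probes into low/high MMAD ×
  low/high ICC; **invariant** flags probes whose mean SD is below 0.1.

A synthetic-study generator (logit-normal between/within-subject
hierarchy, Hardy–Weinberg trimodal genotype probes, invariant extreme
probes, sporadic detection failures) provides ground truth for every
stage.

## Worked example

```python
import methylstab as ms

spec = ms.SyntheticSpec(n_cohorts=3, n_subjects=60, n_probes=2000, seed=1)
ms.generate_study(spec, "study")

model = ms.StabilityModel.from_study_dir(
    "study",
    classification=ms.ClassificationConfig(fixed_mmad_cut=0.01,
                                           fixed_icc_cut=0.74),
)
results = model.fit()
print(results.summary())
```

prints

```
Longitudinal methylation stability — fit summary
====================================================
cohorts: cohort1, cohort2, cohort3
probes analysed: 1868
MMAD cut: 0.01   min-ICC cut: 0.74

metric                median        IQR
MMAD                 0.0243       [0.0113, 0.0396]
min ICC              0.1299       [0.0016, 0.9685]
r(MMAD, min ICC) = -0.447

genetic (SNP or gap): 463  (SNP 306, gap union 396, overlap 239)
hyperstable: 187   nongenetic: 168   invariant flag: 1493
quadrants: lowMMAD_highICC=187, lowMMAD_lowICC=273, highMMAD_highICC=376, highMMAD_lowICC=1032
```

Reading this: of 2000 simulated probes, 1868 survive detection-p
filtering. The typical probe moves by ~0.024 in beta between timepoints
in its worst cohort and shows essentially no between-timepoint agreement
(median min ICC 0.13) — the methylome is dynamic. 187 probes clear both
the MMAD < 0.01 and min ICC > 0.74 bars; removing the 463 probes tied to
genotype (SNP-flagged or gap-called, union by inclusion–exclusion)
leaves 168 hyperstable probes not explained by genetics.
`results.full_table` holds the per-probe resource; `results.save(dir)`
writes it as TSV together with gap calls and a JSON summary.

The same analysis is scriptable from the shell:

```bash
methylstab simulate --out-dir study --seed 1
methylstab run --study-dir study --out-dir results_dir
```

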