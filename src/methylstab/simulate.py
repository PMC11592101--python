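"""Synthetic multi-cohort paired-timepoint methylation studies.

The generator emulates the structure of longitudinal whole-blood array
studies: several cohorts, each subject measured at two timepoints more
than a year apart, probe-wise beta values in (0, 1). Nongenetic probes
follow a logit-normal hierarchy — a subject-level latent value
``u_ij ~ N(mu_j, sigma_b_j)`` plus within-subject longitudinal noise
``e_ijt ~ N(0, sigma_w_j)``, mapped through the inverse logit — which
reproduces the heteroscedasticity of beta values towards the extremes.
Genotype-driven probes place both timepoints at one of three genotype
cluster means under Hardy–Weinberg proportions, with small beta-scale
noise; the genotype is germline and identical at both timepoints.
Invariant probes draw their means from the extreme logit range with
small variances, yielding near-constant, fully (un)methylated signals.
Detection p-values are near zero except for sporadic failures.

Probe classes:

``invariant``
    extreme mean methylation, tiny between- and within-subject variance.
``dynamic``
    ordinary probes with longitudinal noise dominating the small stable
    between-subject signal (low agreement ICC — the bulk of the array).
``stable_nongenetic``
    large between-subject, small within-subject variance: low MAD and
    high ICC without genetic influence (hyperstable-by-construction).
``genetic``
    trimodal genotype clusters, highly stable within subject.

With ``drift = 0`` the population agreement ICC of a nongenetic probe on
the logit scale equals sigma_b^2 / (sigma_b^2 + sigma_w^2) exactly, which
the truth table records for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SpecError
from .io import BetaMatrix, StudyDesign, write_beta_matrix

CLASSES = ("invariant", "dynamic", "stable_nongenetic", "genetic")


def _default_class_fractions():
    return {
        "invariant": 0.15,
        "dynamic": 0.55,
        "stable_nongenetic": 0.10,
        "genetic": 0.20,
    }


def _default_mu_range():
    # logit-scale mean interval per nongenetic class; the invariant
    # interval is mirrored to the negative side with probability 1/2
    return {
        "invariant": (2.5, 4.5),
        "dynamic": (-3.0, 3.0),
        "stable_nongenetic": (-1.5, 1.5),
    }


def _default_sigma_between():
    return {"invariant": 0.10, "dynamic": 0.07, "stable_nongenetic": 0.18}


def _default_sigma_within():
    return {"invariant": 0.10, "dynamic": 0.20, "stable_nongenetic": 0.022}


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic multi-cohort study.

    Defaults describe a desk-scale study: 3 cohorts x 60 subjects x
    20,000 probes with a probe-class mix whose genetic share (~20% plus
    SNP-only flags) approaches the ~28% genetically influenced fraction
    reported for blood 450k data, and whose dynamic class dominates, as
    on the real array.
    """

    n_cohorts: int = 3
    n_subjects: int = 60
    n_probes: int = 20_000
    class_fractions: dict = field(default_factory=_default_class_fractions)
    mu_range: dict = field(default_factory=_default_mu_range)
    sigma_between: dict = field(default_factory=_default_sigma_between)
    sigma_within: dict = field(default_factory=_default_sigma_within)
    drift: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    cluster_means: tuple[float, float, float] = (0.1, 0.5, 0.9)
    cluster_noise_sd: float = 0.02
    detection_fail_rate: float = 2e-4
    snp_flag_rate_genetic: float = 0.66
    snp_flag_rate_other: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.get(c, 0.0) for c in CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"class fractions sum to {total}, expected 1")
        if not all(0.0 <= self.class_fractions.get(c, 0.0) for c in CLASSES):
            raise SpecError("class fractions must be nonnegative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SpecError("maf_range must be a subset of (0, 0.5]")
        cm = self.cluster_means
        if not (0.0 <= cm[0] < cm[1] < cm[2] <= 1.0):
            raise SpecError("cluster_means must be strictly increasing in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated cohort.

    Probe-level fields (class, true ICC, SNP flag, minor-allele
    frequency) are shared across cohorts; genotypes are cohort-specific.
    """

    classes: pd.Series
    true_icc: pd.Series
    snp_flag: pd.Series
    maf: pd.Series
    genotypes: pd.DataFrame  # subjects x genetic probes, values {0,1,2}

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.classes,
                "true_icc": self.true_icc,
                "snp_flag": self.snp_flag.astype(int),
                "maf": self.maf,
            }
        )


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _probe_params(spec: SyntheticSpec):
    """Probe-level structure shared by all cohorts (seed-deterministic)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    probes = pd.Index(
        [f"cgs{i:06d}" for i in range(spec.n_probes)], name="probe_id"
    )
    counts = {c: int(round(spec.class_fractions.get(c, 0.0) * spec.n_probes))
              for c in CLASSES}
    # adjust the largest class so counts sum exactly to n_probes
    drift_n = spec.n_probes - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift_n
    labels = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(labels)
    classes = pd.Series(labels, index=probes, name="class")

    mu = np.zeros(spec.n_probes)
    sigma_b = np.zeros(spec.n_probes)
    sigma_w = np.zeros(spec.n_probes)
    for cls in ("invariant", "dynamic", "stable_nongenetic"):
        mask = (classes == cls).to_numpy()
        lo, hi = spec.mu_range[cls]
        draw = rng.uniform(lo, hi, mask.sum())
        if cls == "invariant":
            draw *= rng.choice([-1.0, 1.0], mask.sum())
        mu[mask] = draw
        sigma_b[mask] = spec.sigma_between[cls]
        sigma_w[mask] = spec.sigma_within[cls]

    genetic = (classes == "genetic").to_numpy()
    maf = pd.Series(np.nan, index=probes, name="maf")
    maf[genetic] = rng.uniform(*spec.maf_range, genetic.sum())

    snp_p = np.where(genetic, spec.snp_flag_rate_genetic,
                     spec.snp_flag_rate_other)
    snp_flag = pd.Series(rng.random(spec.n_probes) < snp_p, index=probes,
                         name="snp_flag")

    with np.errstate(invalid="ignore"):
        icc = sigma_b**2 / (sigma_b**2 + sigma_w**2)
    true_icc = pd.Series(np.where(genetic, np.nan, icc), index=probes,
                         name="true_icc")
    return probes, classes, mu, sigma_b, sigma_w, maf, snp_flag, true_icc


def generate_cohort(spec: SyntheticSpec, cohort_index: int):
    """Generate one cohort's beta matrix, design and ground truth.

    Deterministic given ``spec.seed`` and ``cohort_index``; probe-level
    structure (classes, means, SNP flags, MAFs) is shared across cohorts
    while subjects, genotypes and noise are cohort-specific.
    """
    (probes, classes, mu, sigma_b, sigma_w, maf, snp_flag,
     true_icc) = _probe_params(spec)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 1 + cohort_index])
    )
    n, p = spec.n_subjects, spec.n_probes
    cid = f"cohort{cohort_index + 1}"
    subjects = [f"{cid}_subj{i:03d}" for i in range(n)]
    s1 = [f"{cid}_s{i:03d}_t1" for i in range(n)]
    s2 = [f"{cid}_s{i:03d}_t2" for i in range(n)]

    nongenetic = (classes != "genetic").to_numpy()
    values = np.empty((p, 2 * n))

    # nongenetic: latent subject level + per-timepoint noise, logit scale
    u = rng.normal(mu[:, None], sigma_b[:, None], (p, n))
    e1 = rng.normal(0.0, sigma_w[:, None], (p, n))
    e2 = rng.normal(0.0, sigma_w[:, None], (p, n))
    values[:, :n] = _expit(u + e1)
    values[:, n:] = _expit(u + spec.drift + e2)

    # genetic: Hardy–Weinberg genotype, same at both timepoints
    gen_idx = np.flatnonzero(~nongenetic)
    geno = rng.binomial(2, maf.to_numpy()[gen_idx][:, None], (len(gen_idx), n))
    cm = np.asarray(spec.cluster_means)
    base = cm[geno]
    noise1 = rng.normal(0.0, spec.cluster_noise_sd, base.shape)
    noise2 = rng.normal(0.0, spec.cluster_noise_sd, base.shape)
    values[gen_idx, :n] = np.clip(base + noise1, 0.001, 0.999)
    values[gen_idx, n:] = np.clip(base + noise2, 0.001, 0.999)

    # detection p-values: sporadic failures, near-zero passes
    fails = rng.random((p, 2 * n)) < spec.detection_fail_rate
    detp = rng.uniform(0.0, 0.005, (p, 2 * n))
    detp[fails] = rng.uniform(0.011, 0.5, int(fails.sum()))

    columns = s1 + s2
    beta = BetaMatrix(
        pd.DataFrame(values, index=probes, columns=columns),
        pd.DataFrame(detp, index=probes, columns=columns),
    )
    design = StudyDesign(
        cid, [(subj, a, b) for subj, a, b in zip(subjects, s1, s2)]
    )
    genotypes = pd.DataFrame(
        geno.T, index=pd.Index(subjects, name="subject_id"),
        columns=probes[gen_idx],
    )
    truth = SyntheticTruth(classes, true_icc, snp_flag, maf, genotypes)
    return beta, design, truth


_REFGENE_CHOICES = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "")


def synthetic_manifest(spec: SyntheticSpec) -> pd.DataFrame:
    """Illumina-manifest-style table for the synthetic probes.

    Chromosome, coordinate, gene and RefGene group are decorative but
    well-formed; the SNP column carries an rs-style token exactly for
    probes whose truth SNP flag is set.
    """
    probes, classes, *_rest, snp_flag, _icc = _probe_params(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 10_000]))
    p = spec.n_probes
    chrom = rng.choice([str(c) for c in range(1, 23)] + ["X"], p)
    coord = rng.integers(10_000, 100_000_000, p)
    genes = np.where(rng.random(p) < 0.7,
                     [f"GENE{i % 2500:04d}" for i in range(p)], "")
    groups = rng.choice(_REFGENE_CHOICES, p)
    design_type = rng.choice(["I", "II"], p, p=[0.28, 0.72])
    snp = np.where(snp_flag.to_numpy(), [f"rs{100000 + i}" for i in range(p)], "")
    return pd.DataFrame(
        {
            "IlmnID": probes,
            "CHR": chrom,
            "MAPINFO": coord,
            "UCSC_RefGene_Name": genes,
            "UCSC_RefGene_Group": groups,
            "Infinium_Design_Type": design_type,
            "Probe_SNPs": snp,
        }
    )


def generate_study(spec: SyntheticSpec, out_dir) -> dict:
    """Write a full synthetic study to disk and return the file manifest.

    Emits per-cohort beta and detection TSVs, a combined sample sheet,
    a manifest CSV and a probe-level truth TSV (all io_formats layouts).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, object] = {"beta": [], "detection": []}
    sheet_rows = []
    truth_frame = None
    for ci in range(spec.n_cohorts):
        beta, design, truth = generate_cohort(spec, ci)
        bpath = out / f"{design.cohort_id}_beta.tsv"
        dpath = out / f"{design.cohort_id}_detp.tsv"
        write_beta_matrix(beta, bpath, dpath)
        files["beta"].append(str(bpath))
        files["detection"].append(str(dpath))
        for subj, s1, s2 in design.pairs:
            sheet_rows.append((design.cohort_id, subj, s1, 1))
            sheet_rows.append((design.cohort_id, subj, s2, 2))
        truth_frame = truth.frame()

    sheet = pd.DataFrame(
        sheet_rows, columns=["cohort_id", "subject_id", "sample_id", "timepoint"]
    )
    sheet_path = out / "sample_sheet.csv"
    sheet.to_csv(sheet_path, index=False)
    files["sample_sheet"] = str(sheet_path)

    manifest_path = out / "manifest.csv"
    synthetic_manifest(spec).to_csv(manifest_path, index=False)
    files["manifest"] = str(manifest_path)

    truth_path = out / "truth.tsv"
    truth_frame.to_csv(truth_path, sep="\t", na_rep="NA", index_label="probe_id")
    files["truth"] = str(truth_path)

    with open(out / "study.json", "w") as fh:
        json.dump(files, fh, indent=2)
    files["study"] = str(out / "study.json")
    return files
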