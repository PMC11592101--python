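"""Pre-processing stages and end-to-end orchestration.

Stages run in a fixed order: probe harmonization across cohorts,
detection p-value filtering (probe level, then sample level), optional
per-cohort quantile normalization, stability metrics, per-cohort gap
calling, genetic-influence combination, threshold computation and probe
classification. Each stage contributes a removal report whose counts
satisfy retained + removed = input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassificationConfig
from .exceptions import ConfigError, InsufficientDataError, StageError
from .io import BetaMatrix, StudyDesign, read_beta_matrix, read_manifest, read_sample_sheet

logger = logging.getLogger(__name__)


def harmonize_probes(matrices: list[BetaMatrix]):
    """Restrict all cohort matrices to their sorted common probe set.

    Models the merge of 450k and EPIC arrays by probe-ID intersection
    (extra EPIC probes are stripped).
    """
    if not matrices:
        raise InsufficientDataError("no cohorts to harmonize")
    common = matrices[0].probe_ids
    for m in matrices[1:]:
        common = common.intersection(m.probe_ids)
    if len(common) == 0:
        raise InsufficientDataError("cohorts share no probes")
    common = common.sort_values()
    report = {
        "n_common": int(len(common)),
        "dropped_per_cohort": [int(len(m.probe_ids) - len(common)) for m in matrices],
        "input_per_cohort": [int(len(m.probe_ids)) for m in matrices],
    }
    return [m.subset(probes=common) for m in matrices], report


def filter_by_detection(
    cohorts: list[tuple[BetaMatrix, StudyDesign]],
    detection_p_cut: float = 0.01,
    probe_fail_rule: str = "any_sample",
    max_fail_fraction: float | None = None,
    sample_mean_p_cut: float = 0.01,
):
    """Two-stage detection p-value filter across harmonized cohorts.

    Stage 1 (probes): under ``any_sample``, a probe fails a cohort when
    any of its samples has detection p above the cut; under
    ``max_fraction`` it fails when the failing-sample fraction exceeds
    ``max_fail_fraction``. A probe failing in any cohort is removed from
    all. Stage 2 (samples): a sample whose mean detection p over the
    retained probes exceeds ``sample_mean_p_cut`` is removed, and a
    subject losing a timepoint loses its pair.
    """
    if probe_fail_rule not in ("any_sample", "max_fraction"):
        raise ConfigError(f"unknown probe_fail_rule {probe_fail_rule!r}")
    if probe_fail_rule == "max_fraction" and max_fail_fraction is None:
        raise ConfigError("max_fraction rule needs max_fail_fraction")
    for beta, design in cohorts:
        if beta.detection_p is None:
            raise ConfigError(
                f"cohort {design.cohort_id}: detection filtering requested "
                "but no detection p-value matrix present"
            )

    n_input = len(cohorts[0][0].probe_ids)
    bad_probes = pd.Index([])
    per_cohort_fail = {}
    for beta, design in cohorts:
        dp = beta.detection_p.to_numpy(dtype=float)
        failing = dp > detection_p_cut
        if probe_fail_rule == "any_sample":
            probe_fails = failing.any(axis=1)
        else:
            probe_fails = failing.mean(axis=1) > max_fail_fraction
        flagged = beta.probe_ids[probe_fails]
        per_cohort_fail[design.cohort_id] = int(len(flagged))
        bad_probes = bad_probes.union(flagged)

    keep_probes = cohorts[0][0].probe_ids.difference(bad_probes).sort_values()
    stage1 = [(beta.subset(probes=keep_probes), design) for beta, design in cohorts]

    out = []
    sample_report = {}
    for beta, design in stage1:
        dp = beta.detection_p
        mean_p = dp.mean(axis=0)
        bad_samples = set(mean_p.index[mean_p > sample_mean_p_cut])
        n_in = len(beta.sample_ids)
        new_design = design.drop_samples(bad_samples) if bad_samples else design
        kept_cols = [c for c in beta.sample_ids if c not in bad_samples]
        out.append((beta.subset(samples=pd.Index(kept_cols)), new_design))
        sample_report[design.cohort_id] = {
            "input_samples": n_in,
            "removed_samples": len(bad_samples),
            "retained_samples": n_in - len(bad_samples),
            "input_pairs": design.n_subjects,
            "retained_pairs": new_design.n_subjects,
        }

    report = {
        "probe_stage": {
            "input_probes": int(n_input),
            "failed_per_cohort": per_cohort_fail,
            "removed_probes": int(len(bad_probes)),
            "retained_probes": int(len(keep_probes)),
        },
        "sample_stage": sample_report,
    }
    return out, report


def quantile_normalize(beta: BetaMatrix) -> BetaMatrix:
    """Classic column quantile normalization within a cohort.

    Every sample's values are replaced by the across-sample mean of the
    order statistics at their rank; ties get the mean of the values they
    span, so after normalization all sorted columns are identical.
    Missing cells are imputed by the probe median for the ranking and
    restored as missing afterwards.
    """
    if beta.shape[1] < 2:
        raise InsufficientDataError("quantile normalization needs >= 2 samples")
    values = beta.values.to_numpy(dtype=float)
    missing = np.isnan(values)
    work = values.copy()
    if missing.any():
        med = np.nanmedian(work, axis=1)
        work[missing] = np.broadcast_to(med[:, None], work.shape)[missing]

    order = np.argsort(work, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n_probes, n_samples = work.shape
    rows = np.arange(n_probes)
    for j in range(n_samples):
        ranks[order[:, j], j] = rows
    sorted_vals = np.take_along_axis(work, order, axis=0)
    target = sorted_vals.mean(axis=1)

    normalized = target[ranks]
    # ties within a column receive the mean target over their rank span
    for j in range(n_samples):
        col = work[:, j]
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) == n_probes:
            continue
        sums = np.bincount(inv, weights=normalized[:, j])
        normalized[:, j] = sums[inv] / counts[inv]

    normalized[missing] = np.nan
    frame = pd.DataFrame(normalized, index=beta.probe_ids, columns=beta.sample_ids)
    return BetaMatrix(frame.clip(0.0, 1.0), beta.detection_p)


@dataclass
class CohortFiles:
    """Paths of one cohort's input matrices."""

    cohort_id: str
    beta: str
    detection: str | None = None


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (YAML/JSON serializable)."""

    cohorts: list[CohortFiles]
    sample_sheet: str
    manifest: str | None = None
    snp_column: str = "Probe_SNPs"
    detection_p_cut: float = 0.01
    probe_fail_rule: str = "any_sample"
    max_fail_fraction: float | None = None
    sample_mean_p_cut: float = 0.01
    quantile_normalize: bool = True
    gap_threshold: float = 0.05
    out_cutoff: float = 0.01
    drop_outlier_probes: bool = True
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    drop_replicates: bool = False
    batch_corrected: bool = True  # provenance attestation, echoed in report
    out_dir: str = "methylstab_out"
    seed: int = 0

    def __post_init__(self) -> None:
        for cut in (self.detection_p_cut, self.sample_mean_p_cut):
            if not 0.0 < cut < 1.0:
                raise ConfigError(f"detection cut {cut} outside (0, 1)")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        cohorts = [CohortFiles(**c) for c in raw.pop("cohorts")]
        cls_cfg = raw.pop("classification", None)
        config = cls(cohorts=cohorts, **raw)
        if cls_cfg:
            config.classification = ClassificationConfig(**cls_cfg)
        return config

    @classmethod
    def from_study_dir(cls, study_dir, **overrides) -> "PipelineConfig":
        """Configuration for a directory written by ``generate_study``."""
        study = Path(study_dir)
        with open(study / "study.json") as fh:
            files = json.load(fh)
        cohorts = [
            CohortFiles(Path(b).name.replace("_beta.tsv", ""), b, d)
            for b, d in zip(files["beta"], files["detection"])
        ]
        return cls(
            cohorts=cohorts,
            sample_sheet=files["sample_sheet"],
            manifest=files.get("manifest"),
            **overrides,
        )


def load_cohorts(config: PipelineConfig):
    """Read every cohort's matrices and pair them with their designs."""
    designs = {d.cohort_id: d for d in read_sample_sheet(config.sample_sheet)}
    cohorts = []
    for entry in config.cohorts:
        if entry.cohort_id not in designs:
            raise ConfigError(
                f"cohort {entry.cohort_id!r} absent from sample sheet"
            )
        beta = read_beta_matrix(entry.beta, entry.detection)
        cohorts.append((beta, designs[entry.cohort_id]))
    return cohorts


def run_pipeline(config: PipelineConfig):
    """Execute the full analysis and write all outputs to disk.

    Returns the fitted :class:`~methylstab.model.StabilityResults`.
    On any stage failure, partial outputs are removed and a
    :class:`StageError` naming the stage is raised.
    """
    from .model import StabilityModel

    try:
        cohorts = load_cohorts(config)
    except Exception as exc:
        raise StageError(f"stage 'load': {exc}") from exc
    annotation = None
    if config.manifest is not None:
        try:
            annotation = read_manifest(config.manifest, config.snp_column)
        except Exception as exc:
            raise StageError(f"stage 'annotation': {exc}") from exc
    model = StabilityModel(
        cohorts,
        annotation=annotation,
        detection_p_cut=config.detection_p_cut,
        probe_fail_rule=config.probe_fail_rule,
        max_fail_fraction=config.max_fail_fraction,
        sample_mean_p_cut=config.sample_mean_p_cut,
        quantile_normalize=config.quantile_normalize,
        gap_threshold=config.gap_threshold,
        out_cutoff=config.out_cutoff,
        drop_outlier_probes=config.drop_outlier_probes,
        classification=config.classification,
        drop_replicates=config.drop_replicates,
    )
    results = model.fit()
    results.stage_report["batch_corrected_attestation"] = config.batch_corrected
    results.stage_report["probe_fail_rule"] = config.probe_fail_rule

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        written = results.save(out_dir)
    except Exception as exc:
        # remove partial outputs of this run only
        for name in ("stability_table.tsv", "summary.json", "pipeline.log"):
            (out_dir / name).unlink(missing_ok=True)
        for path in out_dir.glob("gap_calls_*.tsv"):
            path.unlink(missing_ok=True)
        raise StageError(f"stage 'write': {exc}") from exc
    logger.info("pipeline outputs written: %s", sorted(written))
    return results

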