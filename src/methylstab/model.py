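"""Model/Results interface over the stability analysis.

``StabilityModel`` holds the cohort data and analysis options;
``fit()`` runs harmonization, filtering, normalization, metric
computation, gap calling and classification, and returns a
``StabilityResults`` carrying the per-probe table, the thresholds, the
category counts and a ``summary()`` view, in the spirit of statsmodels'
model/results split.
"""

from __future__ import annotations

import json
import logging
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import pipeline as pl
from .classify import (
    ClassificationConfig,
    classification_summary,
    classify_probes,
    genetic_influence,
    percentile_thresholds,
)
from .gaphunter import gap_call_cohort, write_gap_calls
from .io import BetaMatrix, ProbeAnnotation, StudyDesign, write_stability_table
from .metrics import compute_stability_table, metric_correlation

logger = logging.getLogger(__name__)


class StabilityModel:
    """Longitudinal probe-stability model for paired-timepoint cohorts.

    Parameters
    ----------
    cohorts : list of (BetaMatrix, StudyDesign)
        One entry per cohort; matrices need not share probe order —
        they are harmonized to the common probe set at fit time.
    annotation : ProbeAnnotation, optional
        Manifest-derived probe metadata; without it no probe can carry a
        SNP flag and genetic influence rests on gap calls alone.
    detection_p_cut, probe_fail_rule, max_fail_fraction, sample_mean_p_cut
        Detection-based filtering; set ``detection_p_cut`` to None to
        skip filtering (e.g. when no detection matrices exist).
    quantile_normalize : bool
        Apply per-cohort column quantile normalization before metrics.
    gap_threshold, out_cutoff, drop_outlier_probes
        Gap-calling parameters.
    classification : ClassificationConfig
        Thresholds for hyperstability/quadrants/invariance.
    drop_replicates : bool
        Use only the first sample per (subject, timepoint) instead of
        averaging technical replicates.
    """

    def __init__(
        self,
        cohorts: list[tuple[BetaMatrix, StudyDesign]],
        annotation: ProbeAnnotation | None = None,
        *,
        detection_p_cut: float | None = 0.01,
        probe_fail_rule: str = "any_sample",
        max_fail_fraction: float | None = None,
        sample_mean_p_cut: float = 0.01,
        quantile_normalize: bool = True,
        gap_threshold: float = 0.05,
        out_cutoff: float = 0.01,
        drop_outlier_probes: bool = True,
        classification: ClassificationConfig | None = None,
        drop_replicates: bool = False,
    ) -> None:
        self.cohorts = cohorts
        self.annotation = annotation
        self.detection_p_cut = detection_p_cut
        self.probe_fail_rule = probe_fail_rule
        self.max_fail_fraction = max_fail_fraction
        self.sample_mean_p_cut = sample_mean_p_cut
        self.quantile_normalize = quantile_normalize
        self.gap_threshold = gap_threshold
        self.out_cutoff = out_cutoff
        self.drop_outlier_probes = drop_outlier_probes
        self.classification = classification or ClassificationConfig()
        self.drop_replicates = drop_replicates

    @classmethod
    def from_study_dir(cls, study_dir, **kwargs) -> "StabilityModel":
        """Build a model from a directory written by
        :func:`methylstab.simulate.generate_study` (or laid out the same
        way)."""
        from .io import read_beta_matrix, read_manifest, read_sample_sheet

        config = pl.PipelineConfig.from_study_dir(study_dir)
        designs = {d.cohort_id: d for d in read_sample_sheet(config.sample_sheet)}
        cohorts = [
            (read_beta_matrix(c.beta, c.detection), designs[c.cohort_id])
            for c in config.cohorts
        ]
        annotation = (
            read_manifest(config.manifest, config.snp_column)
            if config.manifest
            else None
        )
        return cls(cohorts, annotation=annotation, **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "StabilityResults":
        """Run the full analysis and return the results object."""
        report: dict = {}

        matrices, harm_report = pl.harmonize_probes([b for b, _ in self.cohorts])
        cohorts = [(m, d) for m, (_, d) in zip(matrices, self.cohorts)]
        report["harmonize"] = harm_report

        if self.detection_p_cut is not None and all(
            b.detection_p is not None for b, _ in cohorts
        ):
            cohorts, det_report = pl.filter_by_detection(
                cohorts,
                detection_p_cut=self.detection_p_cut,
                probe_fail_rule=self.probe_fail_rule,
                max_fail_fraction=self.max_fail_fraction,
                sample_mean_p_cut=self.sample_mean_p_cut,
            )
            report["detection_filter"] = det_report

        if self.quantile_normalize:
            cohorts = [(pl.quantile_normalize(b), d) for b, d in cohorts]
            report["quantile_normalize"] = True

        table = compute_stability_table(cohorts, self.drop_replicates)

        gap_calls = {
            d.cohort_id: gap_call_cohort(
                b, self.gap_threshold, self.out_cutoff, self.drop_outlier_probes
            )
            for b, d in cohorts
        }

        if self.annotation is not None:
            annotation = self._aligned_annotation(table.index)
            genetic, genetic_summary = genetic_influence(annotation, gap_calls)
            genetic = genetic.reindex(table.index).fillna(False)
        else:
            gap_union = pd.Index([])
            for calls in gap_calls.values():
                gap_union = gap_union.union(
                    calls.index[calls["has_gap"].astype(bool)]
                )
            genetic = pd.Series(table.index.isin(gap_union), index=table.index)
            genetic_summary = {
                "n_snp": 0,
                "gap_per_cohort": {
                    cid: int(c["has_gap"].sum()) for cid, c in gap_calls.items()
                },
                "n_gap_union": int(len(gap_union)),
                "n_snp_gap_overlap": 0,
                "n_genetic_union": int(genetic.sum()),
            }

        cuts = percentile_thresholds(table, self.classification)
        categories = classify_probes(table, genetic, cuts, self.classification)

        return StabilityResults(
            model=self,
            table=table,
            categories=categories,
            gap_calls=gap_calls,
            thresholds={"mmad_cut": cuts[0], "icc_cut": cuts[1]},
            genetic_summary=genetic_summary,
            stage_report=report,
            cohort_ids=[d.cohort_id for _, d in cohorts],
        )

    def _aligned_annotation(self, probes: pd.Index) -> ProbeAnnotation:
        """Annotation restricted/extended to the analysed probe set;
        probes missing from the manifest get no SNP flag."""
        tbl = self.annotation.table
        aligned = tbl.reindex(probes)
        aligned["snp_flag"] = aligned["snp_flag"].fillna(False).astype(bool)
        aligned["refgene_group"] = aligned["refgene_group"].fillna("none")
        return ProbeAnnotation(aligned)


class StabilityResults:
    """Fitted per-probe stability estimates and classifications.

    Attributes
    ----------
    table : pandas.DataFrame
        Per-probe metrics: per-cohort MAD/ICC (+CI)/Pearson/paired-t
        p/SD, and the aggregates mmad, min_icc, min_t_p, mean_sd,
        mad_sd_ratio.
    categories : pandas.DataFrame
        genetic, hyperstable, hyperstable_nongenetic, quadrant, invariant.
    gap_calls : dict
        Per-cohort gap-call frames.
    thresholds : dict
        The MMAD and min-ICC cuts actually used.
    """

    def __init__(
        self, model, table, categories, gap_calls, thresholds,
        genetic_summary, stage_report, cohort_ids,
    ) -> None:
        self.model = model
        self.table = table
        self.categories = categories
        self.gap_calls = gap_calls
        self.thresholds = thresholds
        self.genetic_summary = genetic_summary
        self.stage_report = stage_report
        self.cohort_ids = cohort_ids

    # -- derived quantities ------------------------------------------------

    @property
    def full_table(self) -> pd.DataFrame:
        """Metrics and category flags in one frame."""
        return self.table.join(self.categories)

    def metric_summary(self) -> dict:
        """Median and IQR of the two headline aggregates plus their
        correlation."""
        out = {}
        for name in ("mmad", "min_icc"):
            vals = self.table[name].dropna()
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out[name] = {"median": float(med), "iqr": [float(q1), float(q3)]}
        out["mmad_min_icc_r"] = metric_correlation(
            self.table["mmad"], self.table["min_icc"]
        )
        return out

    def cross_cohort_correlations(self, metric: str = "icc") -> dict:
        """Pearson correlation of a per-cohort metric between every
        cohort pair (e.g. how similar ICC estimates are across
        cohorts)."""
        out = {}
        for a, b in combinations(self.cohort_ids, 2):
            out[f"{a}|{b}"] = metric_correlation(
                self.table[f"{metric}_{a}"], self.table[f"{metric}_{b}"]
            )
        return out

    def summary_dict(self) -> dict:
        summary = {
            "cohorts": self.cohort_ids,
            "stages": self.stage_report,
            "thresholds": self.thresholds,
            "metrics": self.metric_summary(),
            "genetic": self.genetic_summary,
            "categories": classification_summary(self.categories),
            "cross_cohort_correlations": {
                m: self.cross_cohort_correlations(m) for m in ("icc", "mad")
            },
        }
        return summary

    def summary(self) -> str:
        """Human-readable run summary."""
        s = self.summary_dict()
        lines = [
            "Longitudinal methylation stability — fit summary",
            "=" * 52,
            f"cohorts: {', '.join(s['cohorts'])}",
            f"probes analysed: {len(self.table)}",
            f"MMAD cut: {s['thresholds']['mmad_cut']:.6g}   "
            f"min-ICC cut: {s['thresholds']['icc_cut']:.6g}",
            "",
            "metric                median        IQR",
            f"MMAD                 {s['metrics']['mmad']['median']:.4f}"
            f"       [{s['metrics']['mmad']['iqr'][0]:.4f}, "
            f"{s['metrics']['mmad']['iqr'][1]:.4f}]",
            f"min ICC              {s['metrics']['min_icc']['median']:.4f}"
            f"       [{s['metrics']['min_icc']['iqr'][0]:.4f}, "
            f"{s['metrics']['min_icc']['iqr'][1]:.4f}]",
            f"r(MMAD, min ICC) = {s['metrics']['mmad_min_icc_r']:.3f}",
            "",
            f"genetic (SNP or gap): {s['genetic']['n_genetic_union']}"
            f"  (SNP {s['genetic']['n_snp']}, gap union "
            f"{s['genetic']['n_gap_union']}, overlap "
            f"{s['genetic']['n_snp_gap_overlap']})",
            f"hyperstable: {s['categories']['n_hyperstable']}   "
            f"nongenetic: {s['categories']['n_hyperstable_nongenetic']}   "
            f"invariant flag: {s['categories']['n_invariant']}",
            "quadrants: "
            + ", ".join(
                f"{q}={n}" for q, n in s["categories"]["quadrants"].items()
            ),
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, out_dir) -> list[str]:
        """Write the stability table, gap calls, JSON summary and log.

        Returns the list of file names written.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        table_path = out / "stability_table.tsv"
        write_stability_table(self.full_table, table_path)
        written.append(table_path.name)
        for cid, calls in self.gap_calls.items():
            path = out / f"gap_calls_{cid}.tsv"
            write_gap_calls(calls, path)
            written.append(path.name)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
        written.append("summary.json")
        with open(out / "pipeline.log", "w") as fh:
            fh.write(self.summary() + "\n")
        written.append("pipeline.log")
        return written

    # -- plotting ----------------------------------------------------------

    def plot_quadrants(self, ax=None, max_points: int = 20_000):
        """Scatter of MMAD vs min ICC with the classification cuts."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        tbl = self.full_table.dropna(subset=["mmad", "min_icc"])
        if len(tbl) > max_points:
            tbl = tbl.sample(max_points, random_state=0)
        colors = np.where(tbl["genetic"], "tab:blue", "tab:red")
        ax.scatter(tbl["mmad"], tbl["min_icc"], s=4, c=colors, alpha=0.4)
        ax.axvline(self.thresholds["mmad_cut"], ls="--", c="k", lw=0.8)
        ax.axhline(self.thresholds["icc_cut"], ls="--", c="k", lw=0.8)
        ax.set_xlabel("MMAD (max mean absolute difference)")
        ax.set_ylabel("min ICC(A,1)")
        return ax
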