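"""Probe categories: genetic influence, hyperstability, quadrants,
invariance.

A probe is *genetically influenced* when the array manifest flags a SNP
near its target site or when gap calling detects discrete beta clusters
in any cohort. *Hyperstable* probes sit below the MMAD cut (default: 5th
percentile) and above the min-ICC cut (default: 95th percentile), with
strict inequalities at the cuts; the nongenetic subset additionally
excludes genetically influenced probes. The same two cuts define the four
MMAD x ICC quadrants. The *invariant* flag marks probes whose
between-subject variability is very low (mean SD below a cut, default
0.1), optionally refined to extreme mean methylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, MethylStabError
from .io import ProbeAnnotation

QUADRANTS = (
    "lowMMAD_highICC",
    "lowMMAD_lowICC",
    "highMMAD_highICC",
    "highMMAD_lowICC",
)


@dataclass
class ClassificationConfig:
    """Thresholds for probe classification.

    Percentiles are probabilities in (0, 1); when a fixed cut is supplied
    it overrides the percentile computation (the published cuts are MMAD
    0.01 and min ICC 0.74).
    """

    mmad_percentile: float = 0.05
    icc_percentile: float = 0.95
    fixed_mmad_cut: float | None = None
    fixed_icc_cut: float | None = None
    invariance_sd_cut: float = 0.1
    invariance_extreme_mean: bool = False
    exclude_genetic: bool = True

    def __post_init__(self) -> None:
        for p in (self.mmad_percentile, self.icc_percentile):
            if not 0.0 < p < 1.0:
                raise MethylStabError(f"percentile {p} outside (0, 1)")


def genetic_influence(
    annotation: ProbeAnnotation, gap_calls: dict[str, pd.DataFrame]
):
    """Combine SNP flags and per-cohort gap calls into one boolean.

    A probe is genetic when its manifest SNP flag is set OR any cohort's
    gap call flags it. The summary reports the set sizes — SNP count,
    per-cohort gap counts, the gap union, the SNP/gap overlap and the
    final union — which obey inclusion–exclusion exactly.
    """
    probes = annotation.probe_ids
    gap_union: pd.Index = pd.Index([])
    per_cohort = {}
    for cid, calls in gap_calls.items():
        missing = calls.index.difference(probes)
        if len(missing) > 0:
            raise MethylStabError(
                f"cohort {cid}: {len(missing)} gap-called probe(s) absent "
                f"from annotation (first: {missing[0]!r})"
            )
        flagged = calls.index[calls["has_gap"].astype(bool)]
        per_cohort[cid] = int(len(flagged))
        gap_union = gap_union.union(flagged)

    snp = annotation.snp_flag.astype(bool)
    is_gap = pd.Series(probes.isin(gap_union), index=probes)
    genetic = snp | is_gap
    n_snp = int(snp.sum())
    n_gap = int(len(gap_union))
    n_overlap = int((snp & is_gap).sum())
    summary = {
        "n_snp": n_snp,
        "gap_per_cohort": per_cohort,
        "n_gap_union": n_gap,
        "n_snp_gap_overlap": n_overlap,
        "n_genetic_union": int(genetic.sum()),
    }
    assert summary["n_genetic_union"] == n_snp + n_gap - n_overlap
    return genetic, summary


def percentile_thresholds(table: pd.DataFrame, config: ClassificationConfig):
    """(mmad_cut, icc_cut) from empirical quantiles, or the fixed cuts.

    Quantiles use linear interpolation between order statistics; NaN
    sentinel metrics are excluded.
    """
    mmad = table["mmad"].dropna()
    icc = table["min_icc"].dropna()
    if config.fixed_mmad_cut is not None:
        mmad_cut = float(config.fixed_mmad_cut)
    else:
        if mmad.empty:
            raise InsufficientDataError("all MMAD values undefined")
        mmad_cut = float(np.quantile(mmad, config.mmad_percentile))
    if config.fixed_icc_cut is not None:
        icc_cut = float(config.fixed_icc_cut)
    else:
        if icc.empty:
            raise InsufficientDataError("all min-ICC values undefined")
        icc_cut = float(np.quantile(icc, config.icc_percentile))
    return mmad_cut, icc_cut


def classify_probes(
    table: pd.DataFrame,
    genetic: pd.Series,
    cuts: tuple[float, float],
    config: ClassificationConfig | None = None,
) -> pd.DataFrame:
    """Assign per-probe categories from the stability table and cuts.

    hyperstable = (mmad < mmad_cut) AND (min_icc > icc_cut), strict at
    the cuts; hyperstable_nongenetic additionally requires genetic=false.
    Probes with sentinel MMAD or min ICC receive no quadrant and are
    never hyperstable.
    """
    config = config or ClassificationConfig()
    mmad_cut, icc_cut = cuts
    mmad = table["mmad"]
    icc = table["min_icc"]
    defined = ~(mmad.isna() | icc.isna())
    genetic = genetic.reindex(table.index).fillna(False).astype(bool)

    low_mmad = mmad < mmad_cut
    high_icc = icc > icc_cut
    hyper = defined & low_mmad & high_icc
    quadrant = pd.Series(pd.NA, index=table.index, dtype="object")
    quadrant[defined & low_mmad & high_icc] = "lowMMAD_highICC"
    quadrant[defined & low_mmad & ~high_icc] = "lowMMAD_lowICC"
    quadrant[defined & ~low_mmad & high_icc] = "highMMAD_highICC"
    quadrant[defined & ~low_mmad & ~high_icc] = "highMMAD_lowICC"

    invariant = table["mean_sd"] < config.invariance_sd_cut
    if config.invariance_extreme_mean and "mean_beta" in table.columns:
        # optional refinement: only probes near fully (un)methylated
        mb = table["mean_beta"]
        invariant &= (mb < 0.2) | (mb > 0.8)

    out = pd.DataFrame(
        {
            "genetic": genetic,
            "hyperstable": hyper,
            "hyperstable_nongenetic": hyper & ~genetic,
            "quadrant": quadrant,
            "invariant": invariant.fillna(False),
        },
        index=table.index,
    )
    return out


def classification_summary(categories: pd.DataFrame) -> dict:
    """Counts of each category over the classified probes."""
    quad_counts = categories["quadrant"].value_counts(dropna=True).to_dict()
    return {
        "n_probes": int(len(categories)),
        "n_genetic": int(categories["genetic"].sum()),
        "n_hyperstable": int(categories["hyperstable"].sum()),
        "n_hyperstable_nongenetic": int(
            categories["hyperstable_nongenetic"].sum()
        ),
        "n_invariant": int(categories["invariant"].sum()),
        "quadrants": {q: int(quad_counts.get(q, 0)) for q in QUADRANTS},
    }
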