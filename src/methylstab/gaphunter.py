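"""Gap-signal detection for genotype-driven methylation probes.

A probe whose beta values split into discrete clusters separated by gaps
usually reflects an underlying germline variant (three genotype classes
give up to three beta clusters). Detection is by sorting a probe's beta
values and opening a new group wherever consecutive sorted values differ
by at least ``gap_threshold``. A multi-group call driven by fewer than
``ceil(out_cutoff * n)`` samples outside the largest group is treated as
outlier-driven and, by default, not reported as a gap.

Defaults (gap_threshold 0.05, out_cutoff 0.01, outlier-driven calls
dropped) follow the published gap-hunting method's defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError
from .io import BetaMatrix


@dataclass
class GapCall:
    """Result of gap detection on one probe."""

    probe_id: str
    has_gap: bool
    n_groups: int
    group_sizes: tuple[int, ...]
    outlier_driven: bool


def segment_by_gaps(values, gap_threshold: float = 0.05) -> tuple[int, ...]:
    """Sizes of contiguous value groups, in ascending-value order.

    Values are sorted ascending; a new group starts whenever the
    difference between consecutive sorted values is >= ``gap_threshold``
    (ties at exactly the threshold open a group).
    """
    if not 0.0 < gap_threshold < 1.0:
        raise ValueError("gap_threshold must lie in (0, 1)")
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise InsufficientDataError("gap segmentation needs >= 2 values")
    s = np.sort(values)
    breaks = np.diff(s) >= gap_threshold
    sizes: list[int] = []
    count = 1
    for brk in breaks:
        if brk:
            sizes.append(count)
            count = 1
        else:
            count += 1
    sizes.append(count)
    return tuple(sizes)


def gap_call_probe(
    values,
    gap_threshold: float = 0.05,
    out_cutoff: float = 0.01,
    drop_outlier_probes: bool = True,
    probe_id: str = "",
) -> GapCall:
    """Call gap status for one probe's beta values.

    ``outlier_driven`` is true when the samples outside the largest group
    together number fewer than ``ceil(out_cutoff * n)``; such calls are
    suppressed when ``drop_outlier_probes``.
    """
    sizes = segment_by_gaps(values, gap_threshold)
    n = sum(sizes)
    n_groups = len(sizes)
    outside = n - max(sizes)
    outlier_driven = outside < math.ceil(out_cutoff * n)
    has_gap = n_groups >= 2 and not (outlier_driven and drop_outlier_probes)
    return GapCall(probe_id, has_gap, n_groups, sizes, outlier_driven)


def gap_call_cohort(
    beta: BetaMatrix,
    gap_threshold: float = 0.05,
    out_cutoff: float = 0.01,
    drop_outlier_probes: bool = True,
) -> pd.DataFrame:
    """Apply gap calling to every probe of a cohort matrix.

    All samples of the cohort (both timepoints pooled) enter each call.
    Returns a DataFrame indexed by probe with columns has_gap, n_groups,
    group_sizes (comma-joined) and outlier_driven; the flagged probe set
    is ``frame.index[frame.has_gap]``.
    """
    if beta.shape[1] < 2:
        raise InsufficientDataError("gap calling needs >= 2 samples")
    mat = beta.values.to_numpy(dtype=float)
    records = []
    for i, pid in enumerate(beta.probe_ids):
        call = gap_call_probe(
            mat[i], gap_threshold, out_cutoff, drop_outlier_probes, str(pid)
        )
        records.append(
            (call.has_gap, call.n_groups,
             ",".join(map(str, call.group_sizes)), call.outlier_driven)
        )
    return pd.DataFrame(
        records,
        index=beta.probe_ids,
        columns=["has_gap", "n_groups", "group_sizes", "outlier_driven"],
    )


def write_gap_calls(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    for col in ("has_gap", "outlier_driven"):
        out[col] = out[col].astype(int)
    out.sort_index().to_csv(path, sep="\t", index_label="probe_id")
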