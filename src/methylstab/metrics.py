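"""Per-probe longitudinal stability statistics.

Two complementary metrics drive the analysis: the mean absolute difference
(MAD) of beta values between the two timepoints — an absolute-error facet —
and the two-way absolute-agreement single-measure intraclass correlation
ICC(A,1) — a trend-preservation facet. Per cohort values are aggregated
worst-case across cohorts: the maximum MAD (MMAD) and the minimum ICC, so a
probe only scores as stable if it is stable in every cohort. A paired
t-test p-value, Pearson's r, the pooled per-cohort SD of beta values and
the MMAD/SD ratio complete the per-probe record.

Undefined statistics (zero variance, too few complete pairs) are reported
as NaN sentinels, which propagate through the min/max aggregations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .io import BetaMatrix, StudyDesign


@dataclass
class PairedProbeValues:
    """Pairwise-complete beta values of one probe at the two timepoints."""

    t1: np.ndarray
    t2: np.ndarray

    def __post_init__(self) -> None:
        self.t1 = np.asarray(self.t1, dtype=float)
        self.t2 = np.asarray(self.t2, dtype=float)
        if self.t1.shape != self.t2.shape:
            raise InsufficientDataError("timepoint vectors differ in length")
        keep = ~(np.isnan(self.t1) | np.isnan(self.t2))
        self.t1, self.t2 = self.t1[keep], self.t2[keep]

    @property
    def n(self) -> int:
        return self.t1.size


def probe_mad(v: PairedProbeValues) -> float:
    """Mean over subjects of |t2 - t1| (beta fraction units)."""
    if v.n < 1:
        raise InsufficientDataError("MAD needs at least one complete pair")
    return float(np.mean(np.abs(v.t2 - v.t1)))


def aggregate_mmad(mads) -> float:
    """Worst-case (maximum) MAD across cohorts."""
    mads = np.asarray(mads, dtype=float)
    if mads.size == 0:
        raise InsufficientDataError("no per-cohort MAD values")
    return float(np.max(mads))


def icc_a1(v: PairedProbeValues, alpha: float = 0.05):
    """ICC(A,1): two-way, absolute-agreement, single-rater coefficient.

    Computed from the two-way ANOVA mean squares — MSR (between subjects),
    MSC (between timepoints), MSE (residual) — as

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with k = 2 timepoints and n subjects, plus the standard F-based
    95% confidence interval for this coefficient (two-way agreement,
    single measure).

    Returns
    -------
    (icc, ci_low, ci_high) : tuple of float
        NaN sentinels when the total variance is zero or n < 3 for the
        interval.
    """
    if v.n < 2:
        raise InsufficientDataError("ICC needs at least two complete pairs")
    data = np.column_stack([v.t1, v.t2])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    sst = float(((data - grand) ** 2).sum())
    ssr = float(k * ((row_means - grand) ** 2).sum())
    ssc = float(n * ((col_means - grand) ** 2).sum())
    sse = sst - ssr - ssc
    # zero total variance up to accumulated rounding noise
    if sst <= 1e-20:
        return (math.nan, math.nan, math.nan)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        return (math.nan, math.nan, math.nan)
    icc = (msr - mse) / denom
    if n < 3:
        return (icc, math.nan, math.nan)
    low, high = _icc_a1_ci(icc, msr, msc, mse, n, k, alpha)
    return (icc, low, high)


def _icc_a1_ci(icc, msr, msc, mse, n, k, alpha):
    # F-based interval with Satterthwaite denominator df (McGraw & Wong).
    if not math.isfinite(icc) or icc >= 1.0 or mse == 0.0 and msc == 0.0:
        return (math.nan, math.nan)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    if den <= 0.0 or not math.isfinite(num):
        return (math.nan, math.nan)
    v_df = num / den
    fl = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v_df)
    fu = stats.f.ppf(1.0 - alpha / 2.0, v_df, n - 1.0)
    common = k * msc + (k * n - k - n) * mse
    low = n * (msr - fl * mse) / (fl * common + n * msr)
    high = n * (fu * msr - mse) / (common + n * fu * msr)
    return (float(low), float(high))


def aggregate_min_icc(iccs) -> float:
    """Worst-case (minimum) ICC across cohorts; NaN sentinels propagate."""
    iccs = np.asarray(iccs, dtype=float)
    if iccs.size == 0:
        raise InsufficientDataError("no per-cohort ICC values")
    return float(np.min(iccs))  # np.min propagates NaN


def paired_t_p(v: PairedProbeValues) -> float:
    """Two-sided paired t-test p-value on (t2 - t1).

    Zero-variance differences: a nonzero constant shift yields p = 0
    (the infinite-t limit); an all-zero difference is undefined (NaN).
    """
    if v.n < 2:
        raise InsufficientDataError("paired t-test needs n >= 2")
    d = v.t2 - v.t1
    sd = d.std(ddof=1)
    if sd == 0.0:
        return 0.0 if d.mean() != 0.0 else math.nan
    t = d.mean() / (sd / math.sqrt(v.n))
    return float(2.0 * stats.t.sf(abs(t), v.n - 1))


def aggregate_min_p(ps) -> float:
    """Minimum paired-t p across cohorts; NaN sentinels propagate."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise InsufficientDataError("no per-cohort p-values")
    return float(np.min(ps))


def pearson_paired(v: PairedProbeValues) -> float:
    """Sample Pearson correlation of t1 vs t2; NaN when either vector is
    constant."""
    if v.n < 3:
        raise InsufficientDataError("Pearson r needs n >= 3")
    if v.t1.std() == 0.0 or v.t2.std() == 0.0:
        return math.nan
    return float(np.corrcoef(v.t1, v.t2)[0, 1])


def probe_sd(values) -> float:
    """Sample SD (n-1 denominator) of one probe's beta values over all
    samples of a cohort, both timepoints pooled."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise InsufficientDataError("SD needs at least two values")
    return float(values.std(ddof=1))


def mad_sd_ratio(mmad: float, mean_sd: float) -> float:
    """MMAD divided by the across-cohort mean SD; NaN when mean_sd is 0."""
    if mean_sd == 0.0 or np.isnan(mean_sd):
        return math.nan
    return float(mmad / mean_sd)


def metric_correlation(a, b) -> float:
    """Pearson correlation between two per-probe metric vectors over
    pairwise-complete probes (e.g. ICC in one cohort vs another)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InsufficientDataError("metric vectors differ in length")
    keep = ~(np.isnan(a) | np.isnan(b))
    if keep.sum() < 3:
        raise InsufficientDataError("fewer than 3 complete probe pairs")
    return float(np.corrcoef(a[keep], b[keep])[0, 1])


# ---------------------------------------------------------------------------
# Whole-table computation (vectorized across probes)

def paired_matrices(
    beta: BetaMatrix, design: StudyDesign, drop_replicates: bool = False
):
    """Build (probes x subjects) T1 and T2 matrices from a cohort.

    Technical replicates for a (subject, timepoint) are averaged before
    pairing (or discarded beyond the first when ``drop_replicates``).
    """
    t_cols = {1: [], 2: []}
    for subj, s1, s2 in design.pairs:
        for tp, primary in ((1, s1), (2, s2)):
            ids = design.replicates.get((subj, tp), [primary])
            if drop_replicates:
                ids = ids[:1]
            t_cols[tp].append(beta.values[ids].mean(axis=1, skipna=True))
    subjects = [p[0] for p in design.pairs]
    t1 = pd.concat(t_cols[1], axis=1)
    t2 = pd.concat(t_cols[2], axis=1)
    t1.columns = t2.columns = subjects
    return t1, t2


def _icc_a1_vectorized(t1: np.ndarray, t2: np.ndarray):
    """ICC(A,1) + CI per probe row for k=2, NaN-aware.

    Rows with fewer than 3 complete pairs get NaN.
    """
    pair_ok = ~(np.isnan(t1) | np.isnan(t2))
    x1 = np.where(pair_ok, t1, np.nan)
    x2 = np.where(pair_ok, t2, np.nan)
    n = pair_ok.sum(axis=1).astype(float)
    k = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        row_means = (x1 + x2) / 2.0  # per (probe, subject)
        grand = np.nanmean(np.concatenate([x1, x2], axis=1), axis=1, keepdims=True)
        ssr = k * np.nansum((row_means - grand) ** 2, axis=1)
        c1 = np.nanmean(x1, axis=1)
        c2 = np.nanmean(x2, axis=1)
        g = grand[:, 0]
        ssc = n * ((c1 - g) ** 2 + (c2 - g) ** 2)
        sst = np.nansum((x1 - grand) ** 2, axis=1) + np.nansum(
            (x2 - grand) ** 2, axis=1
        )
        sse = sst - ssr - ssc
        msr = ssr / (n - 1.0)
        msc = ssc / (k - 1.0)
        mse = sse / ((n - 1.0) * (k - 1.0))
        denom = msr + (k - 1.0) * mse + (k / n) * (msc - mse)
        icc = (msr - mse) / denom

        bad = (n < 3) | (sst <= 1e-20) | (denom == 0.0)
        icc = np.where(bad, np.nan, icc)

        # F-based CI (Satterthwaite df), vectorized
        one_m = 1.0 - icc
        a = (k * icc) / (n * one_m)
        b = 1.0 + (k * icc * (n - 1.0)) / (n * one_m)
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / (
            (n - 1.0) * (k - 1.0)
        )
        v_df = num / den
        ci_bad = bad | ~np.isfinite(v_df) | (v_df <= 0.0) | (one_m <= 0.0)
        v_safe = np.where(ci_bad, 1.0, v_df)
        n_safe = np.where(n > 1, n, 2.0)
        fl = stats.f.ppf(0.975, n_safe - 1.0, v_safe)
        fu = stats.f.ppf(0.975, v_safe, n_safe - 1.0)
        common = k * msc + (k * n - k - n) * mse
        low = n * (msr - fl * mse) / (fl * common + n * msr)
        high = n * (fu * msr - mse) / (common + n * fu * msr)
        low = np.where(ci_bad, np.nan, low)
        high = np.where(ci_bad, np.nan, high)
    return icc, low, high


def _cohort_metrics(beta, design, drop_replicates=False) -> pd.DataFrame:
    t1_df, t2_df = paired_matrices(beta, design, drop_replicates)
    t1 = t1_df.to_numpy(dtype=float)
    t2 = t2_df.to_numpy(dtype=float)
    pair_ok = ~(np.isnan(t1) | np.isnan(t2))
    n = pair_ok.sum(axis=1).astype(float)
    d = np.where(pair_ok, t2 - t1, np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        mad = np.nanmean(np.abs(d), axis=1)
        mad = np.where(n >= 1, mad, np.nan)

        # paired t
        d_mean = np.nanmean(d, axis=1)
        d_sd = np.sqrt(np.nansum((d - d_mean[:, None]) ** 2, axis=1) /
                       np.maximum(n - 1.0, 1.0))
        t_stat = d_mean / (d_sd / np.sqrt(n))
        t_p = 2.0 * stats.t.sf(np.abs(t_stat), np.maximum(n - 1.0, 1.0))
        t_p = np.where(n >= 2, t_p, np.nan)
        t_p = np.where((d_sd == 0.0) & (n >= 2),
                       np.where(d_mean != 0.0, 0.0, np.nan), t_p)

        # Pearson r over complete pairs
        x1 = np.where(pair_ok, t1, np.nan)
        x2 = np.where(pair_ok, t2, np.nan)
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
        z1 = x1 - m1[:, None]
        z2 = x2 - m2[:, None]
        cov = np.nansum(z1 * z2, axis=1)
        s1 = np.sqrt(np.nansum(z1 ** 2, axis=1))
        s2 = np.sqrt(np.nansum(z2 ** 2, axis=1))
        r = cov / (s1 * s2)
        r = np.where((n >= 3) & (s1 > 0) & (s2 > 0), r, np.nan)

    icc, low, high = _icc_a1_vectorized(t1, t2)

    # SD pools every sample of the cohort (replicates included)
    all_cols = design.all_sample_ids()
    pooled = beta.values[all_cols].to_numpy(dtype=float)
    n_obs = (~np.isnan(pooled)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(pooled, axis=1, ddof=1)
    sd = np.where(n_obs >= 2, sd, np.nan)

    return pd.DataFrame(
        {"mad": mad, "icc": icc, "icc_low": low, "icc_high": high,
         "pearson": r, "t_p": t_p, "sd": sd, "n_pairs": n.astype(int)},
        index=beta.probe_ids,
    )


def compute_stability_table(
    cohorts: list[tuple[BetaMatrix, StudyDesign]],
    drop_replicates: bool = False,
) -> pd.DataFrame:
    """Compute the full per-probe stability table across cohorts.

    Probes are taken as the intersection of the cohorts' probe sets
    (typically already harmonized upstream). Per probe and cohort the
    table holds MAD, ICC with its 95% CI, Pearson r, the paired-t p and
    the pooled SD, plus the cross-cohort aggregates MMAD, min ICC,
    min p, mean SD and MMAD / mean SD.
    """
    if not cohorts:
        raise InsufficientDataError("no cohorts supplied")
    common = cohorts[0][0].probe_ids
    for beta, _ in cohorts[1:]:
        common = common.intersection(beta.probe_ids)
    if len(common) == 0:
        raise InsufficientDataError("cohorts share no probes")
    common = common.sort_values()

    parts = {}
    for beta, design in cohorts:
        sub = beta.subset(probes=common)
        parts[design.cohort_id] = _cohort_metrics(sub, design, drop_replicates)

    table = pd.DataFrame(index=common)
    for cid, cm in parts.items():
        for col in ("mad", "icc", "icc_low", "icc_high", "pearson", "t_p", "sd"):
            table[f"{col}_{cid}"] = cm[col]
    mads = np.column_stack([parts[cid]["mad"] for cid in parts])
    iccs = np.column_stack([parts[cid]["icc"] for cid in parts])
    tps = np.column_stack([parts[cid]["t_p"] for cid in parts])
    sds = np.column_stack([parts[cid]["sd"] for cid in parts])
    table["mmad"] = mads.max(axis=1)           # NaN propagates: worst case undefined
    table["min_icc"] = iccs.min(axis=1)
    table["min_t_p"] = tps.min(axis=1)
    table["mean_sd"] = sds.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = table["mmad"] / table["mean_sd"]
    table["mad_sd_ratio"] = np.where(table["mean_sd"] > 0, ratio, np.nan)
    table.index.name = "probe_id"
    return table
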