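"""Stability metrics against hand computations and independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylstab import (
    BetaMatrix,
    PairedProbeValues,
    StudyDesign,
    aggregate_min_icc,
    aggregate_min_p,
    aggregate_mmad,
    compute_stability_table,
    icc_a1,
    mad_sd_ratio,
    metric_correlation,
    paired_t_p,
    pearson_paired,
    probe_mad,
    probe_sd,
)
from methylstab.exceptions import InsufficientDataError


def icc_agreement_oracle(t1, t2):
    """Brute-force two-way ANOVA decomposition, written independently of
    the implementation: explicit double loops over the n x 2 table."""
    data = [[a, b] for a, b in zip(t1, t2)]
    n, k = len(data), 2
    flat = [x for row in data for x in row]
    grand = sum(flat) / (n * k)
    ss_total = sum((x - grand) ** 2 for x in flat)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestProbeMad:
    def test_identity_is_zero(self):
        v = PairedProbeValues([0.2, 0.4], [0.2, 0.4])
        assert probe_mad(v) == 0.0

    def test_hand_computation(self):
        v = PairedProbeValues([0.1, 0.2, 0.3], [0.2, 0.1, 0.5])
        assert probe_mad(v) == pytest.approx((0.1 + 0.1 + 0.2) / 3, abs=1e-12)

    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)),
                    min_size=1, max_size=20))
    @settings(deadline=None)
    def test_symmetric_under_timepoint_swap(self, pairs):
        t1 = [p[0] for p in pairs]
        t2 = [p[1] for p in pairs]
        assert probe_mad(PairedProbeValues(t1, t2)) == pytest.approx(
            probe_mad(PairedProbeValues(t2, t1)), abs=1e-15
        )

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            probe_mad(PairedProbeValues([], []))

    def test_missing_pairs_excluded(self):
        v = PairedProbeValues([0.1, np.nan, 0.3], [0.2, 0.5, np.nan])
        assert v.n == 1
        assert probe_mad(v) == pytest.approx(0.1)


class TestAggregations:
    @pytest.mark.parametrize(
        "values,expected",
        [
            # worst-case per-cohort mean absolute differences, top probes
            ((0.00941, 0.00841, 0.00689), 0.00941),
            ((0.00825, 0.00916, 0.00942), 0.00942),
            ((0.5,), 0.5),
        ],
    )
    def test_mmad_is_max(self, values, expected):
        assert aggregate_mmad(values) == expected

    @pytest.mark.parametrize(
        "values,expected",
        [((0.917, 0.923, 0.958), 0.917), ((0.4,), 0.4)],
    )
    def test_min_icc(self, values, expected):
        assert aggregate_min_icc(values) == expected

    @pytest.mark.parametrize(
        "values,expected",
        [((0.270, 0.208, 0.0701), 0.0701), ((0.214, 0.129, 0.260), 0.129)],
    )
    def test_min_p(self, values, expected):
        assert aggregate_min_p(values) == expected

    def test_sentinel_propagates(self):
        assert math.isnan(aggregate_min_icc([0.5, math.nan]))
        assert math.isnan(aggregate_mmad([0.1, math.nan]))

    def test_empty_raises(self):
        for fn in (aggregate_mmad, aggregate_min_icc, aggregate_min_p):
            with pytest.raises(InsufficientDataError):
                fn([])


class TestIccA1:
    def test_perfect_agreement(self):
        v = PairedProbeValues([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        icc, lo, hi = icc_a1(v)
        assert icc == pytest.approx(1.0)

    def test_all_equal_is_sentinel(self):
        icc, lo, hi = icc_a1(PairedProbeValues([0.3] * 5, [0.3] * 5))
        assert math.isnan(icc)

    def test_swap_columns_invariance(self, rng):
        t1, t2 = rng.random(12), rng.random(12)
        a = icc_a1(PairedProbeValues(t1, t2))[0]
        b = icc_a1(PairedProbeValues(t2, t1))[0]
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 51))
            t1, t2 = rng.random(n), rng.random(n)
            icc = icc_a1(PairedProbeValues(t1, t2))[0]
            assert icc == pytest.approx(icc_agreement_oracle(t1, t2), abs=1e-10)

    def test_matches_pingouin_agreement_icc(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(15):
            n = int(rng.integers(4, 40))
            t1, t2 = rng.random(n), rng.random(n)
            icc, lo, hi = icc_a1(PairedProbeValues(t1, t2))
            df = pd.DataFrame(
                {
                    "targets": np.r_[np.arange(n), np.arange(n)],
                    "raters": ["a"] * n + ["b"] * n,
                    "ratings": np.r_[t1, t2],
                }
            )
            res = pg.intraclass_corr(df, targets="targets", raters="raters",
                                     ratings="ratings")
            row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
            assert icc == pytest.approx(row["ICC"], abs=1e-10)
            # pingouin rounds its CI bounds to 2 decimals
            assert lo == pytest.approx(row["CI95"][0], abs=0.006)
            assert hi == pytest.approx(row["CI95"][1], abs=0.006)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            icc_a1(PairedProbeValues([0.1], [0.2]))


class TestPairedT:
    def test_constant_shift_infinite_t_limit(self):
        t1 = np.linspace(0.1, 0.9, 10)
        assert paired_t_p(PairedProbeValues(t1, t1 + 0.05)) < 1e-6

    def test_antisymmetric_differences_give_p_one(self):
        t1 = np.array([0.4, 0.4, 0.4, 0.4])
        d = np.array([0.1, -0.1, 0.1, -0.1])
        assert paired_t_p(PairedProbeValues(t1, t1 + d)) == pytest.approx(1.0)

    def test_zero_differences_sentinel(self):
        t1 = np.array([0.2, 0.5, 0.7])
        assert math.isnan(paired_t_p(PairedProbeValues(t1, t1)))

    def test_matches_textbook_t_cdf(self, rng):
        from scipy import stats

        for _ in range(20):
            n = 20
            t1 = rng.random(n)
            t2 = np.clip(t1 + rng.normal(0, 0.05, n), 0, 1)
            d = t2 - t1
            t_stat = d.mean() / (d.std(ddof=1) / math.sqrt(n))
            expected = 2 * (1 - stats.t.cdf(abs(t_stat), n - 1))
            assert paired_t_p(PairedProbeValues(t1, t2)) == pytest.approx(
                expected, abs=1e-12
            )


class TestPearsonAndSd:
    def test_perfect_linear(self):
        t1 = np.linspace(0.1, 0.4, 8)
        assert pearson_paired(PairedProbeValues(t1, 2 * t1)) == pytest.approx(1.0)

    def test_reversed_is_negative(self):
        t1 = np.linspace(0.1, 0.9, 9)
        assert pearson_paired(PairedProbeValues(t1, t1[::-1])) < 0

    def test_matches_direct_formula(self, rng):
        t1, t2 = rng.random(30), rng.random(30)
        cov = np.cov(t1, t2, ddof=1)[0, 1]
        expected = cov / (t1.std(ddof=1) * t2.std(ddof=1))
        assert pearson_paired(PairedProbeValues(t1, t2)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_sd_constant_zero(self):
        assert probe_sd([0.4] * 5) == 0.0

    def test_sd_two_point(self):
        assert probe_sd([0.0, 1.0]) == pytest.approx(math.sqrt(0.5), abs=1e-4)

    def test_sd_matches_two_pass(self, rng):
        x = rng.random(40)
        mean = sum(x) / len(x)
        expected = math.sqrt(sum((v - mean) ** 2 for v in x) / (len(x) - 1))
        assert probe_sd(x) == pytest.approx(expected, abs=1e-12)


class TestMadSdRatio:
    def test_table_style_ratio(self):
        # rounded printed inputs reproduce the printed ratio within 2e-3
        assert mad_sd_ratio(0.00941, 0.0299) == pytest.approx(0.314, abs=0.002)

    def test_unit_ratio_and_zero(self):
        assert mad_sd_ratio(0.3, 0.3) == 1.0
        assert mad_sd_ratio(0.0, 0.5) == 0.0
        assert math.isnan(mad_sd_ratio(0.1, 0.0))


class TestMetricCorrelation:
    def test_identity(self, rng):
        a = rng.random(100)
        assert metric_correlation(a, a) == pytest.approx(1.0)

    def test_null_is_small(self, rng):
        a, b = rng.random(10_000), rng.random(10_000)
        assert abs(metric_correlation(a, b)) < 0.05  # 3 sigma ~ 0.03

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            metric_correlation([1.0, 2.0], [1.0, 2.0])


def _cohort_from_matrix(values, cohort_id="c1"):
    n = values.shape[1] // 2
    cols = [f"{cohort_id}_s{i}_t{t}" for t in (1, 2) for i in range(n)]
    frame = pd.DataFrame(
        values, index=[f"cg{i}" for i in range(values.shape[0])], columns=cols
    )
    pairs = [(f"subj{i}", cols[i], cols[n + i]) for i in range(n)]
    return BetaMatrix(frame), StudyDesign(cohort_id, pairs)


class TestStabilityTable:
    def test_zero_noise_limit(self, rng):
        half = rng.random((30, 10))
        beta, design = _cohort_from_matrix(np.hstack([half, half]))
        table = compute_stability_table([(beta, design)])
        assert (table["mmad"] == 0).all()
        defined = table["min_icc"].dropna()
        assert np.allclose(defined, 1.0)

    def test_single_cohort_aggregation_identity(self, rng):
        beta, design = _cohort_from_matrix(rng.random((20, 12)))
        table = compute_stability_table([(beta, design)])
        assert (table["mmad"] == table["mad_c1"]).all()
        pd.testing.assert_series_equal(
            table["min_icc"], table["icc_c1"], check_names=False
        )

    def test_worst_case_bounds_per_probe(self, small_cohorts):
        cohorts, _ = small_cohorts
        table = compute_stability_table(list(cohorts))
        for _, design in cohorts:
            cid = design.cohort_id
            ok = table[f"mad_{cid}"].notna()
            assert (table.loc[ok, "mmad"] >= table.loc[ok, f"mad_{cid}"]).all()
            ok = table[f"icc_{cid}"].notna() & table["min_icc"].notna()
            assert (table.loc[ok, "min_icc"] <= table.loc[ok, f"icc_{cid}"] + 1e-12).all()

    def test_vectorized_matches_scalar_path(self, rng):
        values = rng.random((25, 16))
        values[rng.random(values.shape) < 0.05] = np.nan
        beta, design = _cohort_from_matrix(values)
        table = compute_stability_table([(beta, design)])
        n = 8
        for i, pid in enumerate(beta.probe_ids):
            v = PairedProbeValues(values[i, :n], values[i, n:])
            if v.n >= 1:
                assert table.loc[pid, "mad_c1"] == pytest.approx(
                    probe_mad(v), abs=1e-12
                )
            if v.n >= 3:
                icc, lo, hi = icc_a1(v)
                got = table.loc[pid, "icc_c1"]
                if math.isnan(icc):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(icc, abs=1e-10)
                    assert table.loc[pid, "icc_low_c1"] == pytest.approx(lo, abs=1e-8)
                    assert table.loc[pid, "icc_high_c1"] == pytest.approx(hi, abs=1e-8)
                p = paired_t_p(v)
                got_p = table.loc[pid, "t_p_c1"]
                if math.isnan(p):
                    assert math.isnan(got_p)
                else:
                    assert got_p == pytest.approx(p, abs=1e-10)

    def test_replicate_averaging(self, rng):
        # one subject has two T2 replicates; metrics must match a manual
        # pre-averaged cohort
        n_probes = 10
        base = rng.random((n_probes, 6))
        cols = ["a1", "a2", "a2b", "b1", "b2", "c1"]
        frame = pd.DataFrame(base, index=[f"cg{i}" for i in range(n_probes)],
                             columns=cols)
        design = StudyDesign(
            "c1",
            [("A", "a1", "a2"), ("B", "b1", "b2")],
            {("A", 2): ["a2", "a2b"]},
        )
        table = compute_stability_table([(BetaMatrix(frame), design)])

        merged = frame.copy()
        merged["a2m"] = (frame["a2"] + frame["a2b"]) / 2
        design2 = StudyDesign("c1", [("A", "a1", "a2m"), ("B", "b1", "b2")])
        table2 = compute_stability_table(
            [(BetaMatrix(merged[["a1", "a2m", "b1", "b2"]].clip(0, 1)), design2)]
        )
        np.testing.assert_allclose(table["mad_c1"], table2["mad_c1"], atol=1e-12)

    def test_drop_replicates_option(self, rng):
        frame = pd.DataFrame(
            rng.random((5, 4)), index=[f"cg{i}" for i in range(5)],
            columns=["a1", "a2", "a2b", "b_unused"],
        )
        design = StudyDesign("c1", [("A", "a1", "a2")], {("A", 2): ["a2", "a2b"]})
        t_avg = compute_stability_table([(BetaMatrix(frame), design)])
        t_drop = compute_stability_table([(BetaMatrix(frame), design)],
                                         drop_replicates=True)
        expected = np.abs(frame["a2"] - frame["a1"])
        np.testing.assert_allclose(t_drop["mad_c1"], expected, atol=1e-12)
        assert not np.allclose(t_avg["mad_c1"], t_drop["mad_c1"])

    def test_no_shared_probes(self, rng):
        b1, d1 = _cohort_from_matrix(rng.random((4, 6)))
        b2, d2 = _cohort_from_matrix(rng.random((4, 6)), cohort_id="c2")
        b2.values.index = [f"xx{i}" for i in range(4)]
        with pytest.raises(InsufficientDataError):
            compute_stability_table([(b1, d1), (b2, d2)])


class TestExpectedMad:
    def test_gaussian_noise_mad_theory(self, rng):
        """For beta-scale Gaussian noise of SD sigma at both timepoints,
        E[MAD] = 2 sigma / sqrt(pi)."""
        sigma, n, p = 0.02, 120, 200
        base = rng.uniform(0.3, 0.7, (p, 1))
        t1 = base + rng.normal(0, sigma, (p, n))
        t2 = base + rng.normal(0, sigma, (p, n))
        beta, design = _cohort_from_matrix(np.clip(np.hstack([t1, t2]), 0, 1))
        table = compute_stability_table([(beta, design)])
        expected = 2 * sigma / math.sqrt(math.pi)
        assert table["mmad"].mean() == pytest.approx(expected, rel=0.10)
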