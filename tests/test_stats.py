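"""t-tests against closed forms and a numerical-integration oracle."""

import numpy as np
import pytest
from scipy.integrate import quad

from doseaccum.metrics import DoseMetrics
from doseaccum.stats import (
    CohortRecord,
    DegenerateDataError,
    GroupingError,
    SampleSizeError,
    change_summary,
    group_table,
    holm_adjust,
    independent_compare,
    paired_compare,
    paired_table,
    summarize_cohort,
    volume_table,
)


def _t_density(x, df):
    from math import gamma, pi, sqrt

    return (
        gamma((df + 1) / 2)
        / (sqrt(df * pi) * gamma(df / 2))
        * (1 + x * x / df) ** (-(df + 1) / 2)
    )


def two_sided_p_by_quadrature(t, df):
    """Independent oracle: numerically integrate the t density."""
    tail, _ = quad(_t_density, abs(t), np.inf, args=(df,))
    return 2.0 * tail


class TestPairedCompare:
    def test_closed_form_example(self):
        res = paired_compare([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert res.t == pytest.approx(-2.0 / (1.0 / np.sqrt(3)), abs=1e-10)
        assert res.t == pytest.approx(-3.4641016, abs=1e-6)
        assert res.df == 2
        assert res.correlation == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0742, abs=2e-4)

    def test_reversal_negates_t_keeps_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        r1, r2 = paired_compare(a, b), paired_compare(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)
        assert r1.correlation == pytest.approx(r2.correlation)

    def test_identical_vectors_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_small_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            paired_compare([1.0, 2.0], [3.0, 4.0])

    @pytest.mark.parametrize("df", [2, 5, 17, 40])
    def test_p_matches_quadrature_oracle(self, df):
        rng = np.random.default_rng(df)
        a = rng.normal(0, 1, df + 1)
        b = rng.normal(0.8, 1, df + 1)
        res = paired_compare(a, b)
        assert res.p == pytest.approx(two_sided_p_by_quadrature(res.t, res.df), abs=1e-8)


class TestIndependentCompare:
    def test_pooled_closed_form_example(self):
        res = independent_compare([1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0], "pooled")
        # pooled sd = sqrt(5/3) = 1.29099; t = -2 / (1.29099 * sqrt(1/2))
        assert res.t == pytest.approx(-2.1909, abs=1e-4)
        assert res.df == 6

    def test_identical_groups_give_t_zero_p_one(self):
        g = [1.0, 2.0, 3.0]
        res = independent_compare(g, g, "pooled")
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_welch_equals_pooled_for_balanced_equal_variance(self):
        g1 = [1.0, 2.0, 3.0, 4.0]
        g2 = [10.0, 11.0, 12.0, 13.0]
        pooled = independent_compare(g1, g2, "pooled")
        welch = independent_compare(g1, g2, "welch")
        assert welch.t == pytest.approx(pooled.t, abs=1e-10)
        assert welch.df == pytest.approx(pooled.df, abs=1e-10)

    def test_degenerate_and_small_samples(self):
        with pytest.raises(DegenerateDataError):
            independent_compare([2.0, 2.0], [2.0, 2.0], "pooled")
        with pytest.raises(SampleSizeError):
            independent_compare([1.0], [2.0, 3.0], "pooled")

    @pytest.mark.parametrize("kind", ["pooled", "welch"])
    def test_p_matches_quadrature_oracle(self, kind):
        rng = np.random.default_rng(99)
        res = independent_compare(
            rng.normal(0, 1, 8), rng.normal(1, 2, 13), kind
        )
        assert res.p == pytest.approx(two_sided_p_by_quadrature(res.t, res.df), abs=1e-8)

    def test_type_one_error_calibrated_under_null(self):
        # 2000 null replicates at alpha=0.05 should reject ~5% +/- 2%
        rng = np.random.default_rng(2024)
        n1, n2, reps = 8, 13, 2000
        g1 = rng.normal(0, 1, (reps, n1))
        g2 = rng.normal(0, 1, (reps, n2))
        rejections = 0
        for i in range(reps):
            if independent_compare(g1[i], g2[i], "pooled").p < 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.03 <= rate <= 0.07

    def test_paired_power_monotone_in_shift(self):
        rng = np.random.default_rng(5)
        base = rng.normal(30, 5, 40)
        noise = rng.normal(0, 1.0, 40)
        pvals = [
            paired_compare(base + shift + noise, base).p for shift in (0.5, 1.0, 2.0)
        ]
        assert pvals[0] > pvals[1] > pvals[2]


def _metrics(dmean, vol=14.0):
    # endpoints derived from Dmean so every column varies across records
    v20 = min(100.0, 2.3 * dmean)
    v30 = min(v20, 1.1 * dmean)
    v40 = min(v30, 0.55 * dmean)
    return DoseMetrics(v20, v30, v40, dmean - 6.0, dmean, vol)


def _cohort(n_x=4, n_nx=5, seed=0, delivered_shift=2.0, group_gap=3.0):
    rng = np.random.default_rng(seed)
    records = []
    pid = 0
    for label, n in ((True, n_x), (False, n_nx)):
        for _ in range(n):
            pid += 1
            for side in "LR":
                base = 26.0 + (group_gap if label else 0.0) + rng.normal(0, 2)
                pre = 20.0 + rng.normal(0, 3)
                records.append(
                    CohortRecord(
                        patient_id=f"P{pid:02d}",
                        side=side,
                        xerostomia=label,
                        planned=_metrics(base),
                        delivered=_metrics(base + delivered_shift + rng.normal(0, 0.5)),
                        pre_volume_cc=pre,
                        post_volume_cc=pre * 0.87,
                    )
                )
    return records


class TestCohortTables:
    def test_paired_table_shape_and_sd(self):
        records = _cohort()
        # two-record toy check of the mean +/- sd convention (n-1 denominator)
        sub = records[:2]
        vals = [r.planned.dmean_gy for r in sub]
        assert np.std(vals, ddof=1) == pytest.approx(
            abs(vals[0] - vals[1]) / np.sqrt(2)
        )
        table = paired_table(records)
        assert list(table["parameter"]) == ["V20", "V30", "V40", "D50", "Dmean"]
        row = table[table["parameter"] == "Dmean"].iloc[0]
        assert row["delivery_mean"] > row["planning_mean"]
        assert row["p"] < 0.01
        assert abs(row["correlation"]) <= 1.0

    def test_paired_table_two_value_sd_example(self):
        # planned Dmean (20, 30) -> "25.0 +/- 7.07"
        assert np.std([20.0, 30.0], ddof=1) == pytest.approx(7.0710678, abs=1e-6)

    def test_degenerate_endpoint_surfaced_not_fatal(self):
        records = _cohort(delivered_shift=0.0)
        for r in records:
            r.delivered = r.planned
        table = paired_table(records)
        assert (table["note"] != "").all()
        np.testing.assert_allclose(table["delta_mean"], 0.0)

    def test_group_table_tolerance_flags(self):
        records = _cohort(group_gap=6.0)
        table = group_table(records, "delivered")
        dmean = table[table["parameter"] == "Dmean"].iloc[0]
        assert dmean["ref_gy"] == 26.0
        d50 = table[table["parameter"] == "D50"].iloc[0]
        assert d50["ref_gy"] == 30.0
        # delivered Dmean ~ 34 for the xerostomia arm -> flagged above 26 Gy
        assert dmean["xerostomia_above_ref"]
        assert bool(d50["xerostomia_above_ref"]) is False

    def test_group_table_requires_both_groups(self):
        records = [r for r in _cohort() if r.xerostomia]
        with pytest.raises(GroupingError):
            group_table(records, "planned")

    def test_volume_table_uses_per_gland_relative_change(self):
        records = _cohort()
        table = volume_table(records)
        assert set(table["group"]) == {"xerostomia", "no_xerostomia"}
        np.testing.assert_allclose(table["volumetric_change_pct_mean"], 13.0, atol=0.2)

    def test_change_summary_reports_both_conventions(self):
        records = _cohort()
        cs = change_summary(records)
        assert {"mean_of_per_gland_change_pct", "change_of_means_pct"} <= set(cs.columns)
        dmean = cs[cs["parameter"] == "Dmean"].iloc[0]
        assert dmean["mean_of_per_gland_change_pct"] > 0

    def test_summarize_cohort_emits_all_tables(self):
        tables = summarize_cohort(_cohort())
        assert set(tables) == {
            "paired",
            "planned_by_group",
            "delivered_by_group",
            "volume",
            "change_summary",
        }


class TestHolm:
    def test_holm_adjustment_known_example(self):
        adj = holm_adjust([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06, 0.02])

    def test_holm_handles_nan(self):
        adj = holm_adjust([0.01, np.nan, 0.04])
        assert np.isnan(adj[1])
        assert adj[0] == pytest.approx(0.02)
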