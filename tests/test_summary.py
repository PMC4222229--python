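import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import allopotential as ap
from allopotential.binding import BindingRecord
from allopotential.errors import InsufficientDataError
from allopotential.expression import ExpressionTable
from allopotential.summary import (
    MwMethod,
    exact_u_distribution,
    per_locus_presented_counts,
    summarize_counts,
)


def record(ic50, peptide="AAAAAAAAA", allele="HLA-A*01:01", gene=None):
    prov = {"gene": gene} if gene else None
    return BindingRecord.make(peptide, allele, "SMM", ic50, prov)


def records_from_ic50s(values, gene=None):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    out = []
    for i, v in enumerate(values):
        pep = "".join(aas[(i // 20**k) % 20] for k in range(9))
        out.append(record(v, peptide=pep, gene=gene))
    return out


class TestRankCurve:
    def test_filter_and_sort(self):
        series = ap.rank_ic50_curve(records_from_ic50s([200.0, 30.0, 99.0]), cutoff_nM=100)
        assert series == [(1, 30.0), (2, 99.0)]

    def test_all_above_cutoff_gives_empty_series(self):
        assert ap.rank_ic50_curve(records_from_ic50s([500.0, 1000.0]), 100) == []

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(3.0, 1.5, size=1000).tolist()
        series = ap.rank_ic50_curve(records_from_ic50s(values), cutoff_nM=100)
        kept = sorted(v for v in values if v <= 100)
        assert [r for r, _ in series] == list(range(1, len(kept) + 1))
        assert [v for _, v in series] == pytest.approx(kept)

    def test_duplicates_retained(self):
        series = ap.rank_ic50_curve(records_from_ic50s([50.0, 50.0, 50.0]), 100)
        assert len(series) == 3


class TestQuadraticFitAndIntegral:
    def test_constant_series_fits_exactly(self):
        series = [(x, 7.0) for x in range(1, 11)]
        (c2, c1, c0), rmse = ap.fit_quadratic(series)
        assert (c2, c1, c0) == pytest.approx((0.0, 0.0, 7.0), abs=1e-9)
        assert rmse == pytest.approx(0.0, abs=1e-9)

    def test_generating_polynomial_recovered(self):
        gen = lambda x: 0.02 * x**2 + 0.5 * x + 3.0
        series = [(x, gen(x)) for x in range(1, 51)]
        (c2, c1, c0), rmse = ap.fit_quadratic(series)
        assert (c2, c1, c0) == pytest.approx((0.02, 0.5, 3.0), abs=1e-9)
        assert rmse < 1e-9

    def test_linear_series_is_a_nested_model(self):
        series = [(x, 2.0 * x) for x in range(1, 20)]
        (c2, c1, c0), _ = ap.fit_quadratic(series)
        assert (c2, c1, c0) == pytest.approx((0.0, 2.0, 0.0), abs=1e-9)

    def test_constant_integral(self):
        assert ap.integrate_curve(0, 0, 5.0, 1, 11) == pytest.approx(50.0)

    def test_hand_computed_definite_integral(self):
        # 0.02(50^3-1)/3 + 0.5(50^2-1)/2 + 3*49
        assert ap.integrate_curve(0.02, 0.5, 3.0, 1, 50) == pytest.approx(
            1605.0766666667, abs=1e-6
        )

    def test_degenerate_interval_is_zero(self):
        assert ap.integrate_curve(1.0, 2.0, 3.0, 4, 4) == 0.0

    def test_reversed_bounds_rejected(self):
        with pytest.raises(ValueError):
            ap.integrate_curve(0, 0, 1, 5, 4)


class TestAlloreactivityPotential:
    def test_empty_record_set(self):
        result = ap.compute_alloreactivity_potential([])
        assert result.auc == 0.0 and result.n_points == 0

    def test_constant_records_give_c_times_nminus1(self):
        result = ap.compute_alloreactivity_potential(records_from_ic50s([50.0] * 10))
        assert result.auc == pytest.approx(50.0 * 9, rel=1e-9)
        assert result.n_points == 10 and not result.fallback

    def test_two_points_fall_back_to_trapezoid(self):
        result = ap.compute_alloreactivity_potential(records_from_ic50s([10.0, 30.0]))
        assert result.fallback
        assert result.auc == pytest.approx(20.0)  # trapezoid over ranks 1..2

    def test_quadratic_rank_curve_recovers_generating_integral(self):
        gen = lambda x: 0.005 * x**2 + 0.2 * x + 1.0  # stays below 100 for x <= 120
        n = 80
        values = [gen(x) for x in range(1, n + 1)]
        result = ap.compute_alloreactivity_potential(records_from_ic50s(values))
        exact = ap.integrate_curve(0.005, 0.2, 1.0, 1, n)
        assert result.auc == pytest.approx(exact, rel=0.01)

    def test_trapezoid_sanity_bound(self):
        rng = np.random.default_rng(8)
        values = np.sort(rng.uniform(1, 100, size=60))
        result = ap.compute_alloreactivity_potential(records_from_ic50s(values.tolist()))
        trapezoid = float(np.trapezoid(values, np.arange(1, 61)))
        assert abs(result.auc - trapezoid) <= 3 * result.fit_rmse * (result.b - result.a) + 1e-6

    def test_potential_grows_when_adding_a_peptide_at_the_max(self):
        values = [5.0, 10.0, 20.0, 40.0, 60.0]
        base = ap.compute_alloreactivity_potential(records_from_ic50s(values))
        grown = ap.compute_alloreactivity_potential(records_from_ic50s(values + [60.0]))
        assert grown.auc > base.auc


class TestWeightedPotential:
    def _table(self):
        df = pd.DataFrame(
            {"liver": [10.0, 0.0, 3.0], "lung": [1.0, 2.0, 30.0]},
            index=["G1", "G2", "G3"],
        )
        return ExpressionTable(df)

    def test_single_record(self):
        wp = ap.weighted_potential([record(100.0, gene="G1")], self._table(), "liver")
        assert wp.value == pytest.approx(0.1)

    def test_zero_expression_gives_zero(self):
        wp = ap.weighted_potential([record(10.0, gene="G2")], self._table(), "liver")
        assert wp.value == 0.0

    def test_matches_manual_accumulation(self):
        rng = np.random.default_rng(6)
        genes = ["G1", "G2", "G3"]
        recs, expected = [], 0.0
        table = self._table()
        for i in range(20):
            g = genes[i % 3]
            ic50 = float(rng.uniform(5, 400))
            recs.append(record(ic50, peptide=f"AAAAAAAA{'ACDEFGHIKLMNPQRSTVWY'[i]}", gene=g))
            expected += table.value(g, "lung") / ic50
        wp = ap.weighted_potential(recs, table, "lung")
        assert wp.value == pytest.approx(expected)

    def test_missing_gene_contributes_zero_and_is_counted(self):
        wp = ap.weighted_potential([record(10.0, gene="NOPE")], self._table(), "liver")
        assert wp.value == 0.0 and wp.n_missing_genes == 1

    def test_unknown_tissue_lists_available(self):
        with pytest.raises(KeyError, match="liver"):
            ap.weighted_potential([], self._table(), "kidney")


class TestPowerLaw:
    def test_noise_free_exponent_recovered_exactly(self):
        ranks = np.arange(1, 200)
        recip = 3.0 * ranks**-1.5
        fit = ap.fit_power_law((1.0 / recip).tolist())
        assert fit.exponent == pytest.approx(-1.5, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_reciprocal_gives_zero_exponent(self):
        fit = ap.fit_power_law([100.0] * 10)
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(13)
        ranks = np.arange(1, 501)
        recip = 2.0 * ranks**-1.5 * 10 ** rng.normal(0, 0.1, size=500)
        fit = ap.fit_power_law((1.0 / recip).tolist())
        assert fit.exponent == pytest.approx(-1.5, abs=0.1)

    def test_scale_covariance(self):
        rng = np.random.default_rng(14)
        values = rng.lognormal(2, 1, size=100).tolist()
        base = ap.fit_power_law(values)
        scaled = ap.fit_power_law([v * 10.0 for v in values])
        assert scaled.exponent == pytest.approx(base.exponent, abs=1e-9)
        assert scaled.intercept == pytest.approx(base.intercept - 1.0, abs=1e-9)

    def test_too_few_records(self):
        with pytest.raises(InsufficientDataError):
            ap.fit_power_law([1.0, 2.0])


class TestExactMannWhitney:
    def test_complete_separation_4v5_gives_printed_p(self):
        gc = ap.exact_mann_whitney([1, 2, 3, 4], [10, 20, 30, 40, 50])
        assert gc.method is MwMethod.EXACT
        assert gc.p_two_sided == pytest.approx(2 / 126)
        assert round(gc.p_two_sided, 3) == 0.016

    def test_u18_case_matches_exhaustive_enumeration(self):
        # a beats b in 18 of 20 pairs
        a = [5, 30, 40, 50]
        b = [1, 2, 3, 4, 35]
        u = sum(1 for x in a for y in b if x > y)
        assert u == 18
        gc = ap.exact_mann_whitney(a, b)
        # oracle: enumerate all 126 labelings directly
        pooled = sorted(a + b)
        n_ge = n_le = 0
        for combo in itertools.combinations(range(9), 4):
            grp = [pooled[i] for i in combo]
            rest = [pooled[i] for i in range(9) if i not in combo]
            uu = sum(1 for x in grp for y in rest if x > y)
            n_ge += uu >= u
            n_le += uu <= u
        expected = min(1.0, 2 * min(n_le, n_ge) / 126)
        assert gc.p_two_sided == pytest.approx(expected)
        assert gc.p_two_sided == pytest.approx(8 / 126)

    def test_identical_groups_give_p_one(self):
        gc = ap.exact_mann_whitney([1, 2], [1, 2])
        assert gc.method is MwMethod.NORMAL_APPROX  # ties force the approx path
        assert gc.p_two_sided == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ap.exact_mann_whitney([], [1.0])

    def test_u_distribution_sums_to_one_and_is_symmetric(self):
        for n, m in [(3, 3), (4, 5), (2, 6)]:
            dist = exact_u_distribution(n, m)
            assert sum(dist.values()) == pytest.approx(1.0)
            for u, p in dist.items():
                assert dist[n * m - u] == pytest.approx(p)
            assert min(dist) == 0 and max(dist) == n * m

    def test_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            a = rng.choice(1000, size=5, replace=False).tolist()
            b = rng.choice(np.arange(1000, 2000), size=6, replace=False).tolist()
            rng.shuffle(b)
            mixed = a[:3] + b[:2]
            ours = ap.exact_mann_whitney(mixed, a[3:] + b[2:])
            ref = stats.mannwhitneyu(
                mixed, a[3:] + b[2:], alternative="two-sided", method="exact"
            )
            assert ours.p_two_sided == pytest.approx(ref.pvalue)
            assert ours.u_statistic == pytest.approx(ref.statistic)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(22)
        a = rng.normal(0, 1, size=30).tolist()
        b = rng.normal(0.5, 1, size=30).tolist()
        ours = ap.exact_mann_whitney(a, b)
        assert ours.method is MwMethod.NORMAL_APPROX
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)


class TestSummaryTable:
    def test_reference_cohort_medians_match_sort_oracle(self):
        table = ap.reference_cohort()
        agg = table.aggregate()
        for col in ("smm_presented", "pan_strong", "shared_presented"):
            vals = sorted(table.rows[col])
            assert agg[col]["median"] == vals[len(vals) // 2]  # odd n
            assert agg[col]["min"] == vals[0] and agg[col]["max"] == vals[-1]

    def test_single_pair_degenerate_range(self):
        rows = pd.DataFrame([{"pair_id": "1", "donor_type": "MRD", "smm_presented": 7}])
        agg = ap.SummaryTable(rows).aggregate()
        assert agg["smm_presented"] == {"median": 7.0, "min": 7.0, "max": 7.0}

    def test_aggregate_invariant_to_row_order(self):
        table = ap.reference_cohort()
        shuffled = ap.SummaryTable(table.rows.sample(frac=1.0, random_state=3))
        assert table.aggregate() == shuffled.aggregate()

    def test_summarize_counts_from_records(self):
        smm = records_from_ic50s([10.0, 100.0, 600.0])
        pan = [
            BindingRecord.make(r.peptide, r.allele, "PAN", r.ic50_nM * 1.1) for r in smm
        ]
        table = summarize_counts({"p1": {"SMM": smm, "PAN": pan}}, {"p1": "MRD"})
        row = table.rows.iloc[0]
        assert row["smm_presented"] == 2 and row["smm_strong"] == 1
        assert row["pan_presented"] == 2 and row["pan_strong"] == 1
        assert row["shared_presented"] == 2
        assert row["smm_strong"] <= row["smm_presented"]

    def test_per_locus_counts(self):
        recs = [
            record(10.0, peptide="AAAAAAAAC", allele="HLA-A*01:01"),
            record(10.0, peptide="AAAAAAAAD", allele="HLA-B*07:02"),
            record(900.0, peptide="AAAAAAAAE", allele="HLA-C*07:01"),
        ]
        assert per_locus_presented_counts(recs) == {"A": 1, "B": 1, "C": 0}
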