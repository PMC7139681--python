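"""Unit and property tests for the association engine."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from grsmr import assoc
from grsmr.types import ContingencyTable

# 2x2 from a dichotomized-score layout: a short-control, b long-control,
# c short-case, d long-case.
TBL = ContingencyTable(a=410, b=403, c=316, d=449)
LOG_OR = math.log(410 * 449 / (403 * 316))  # 0.3685013
WOOLF_SE = math.sqrt(1 / 410 + 1 / 403 + 1 / 316 + 1 / 449)  # 0.1015487


def _counts_to_rows(table):
    """Expand 2x2 counts into per-subject outcome/exposure vectors."""
    y = np.repeat([0, 0, 1, 1], [table.a, table.b, table.c, table.d])
    x = np.repeat([0, 1, 0, 1], [table.a, table.b, table.c, table.d])
    return y, x


class TestFitLogistic:
    def test_binary_exposure_reproduces_crude_or_closed_form(self):
        y, x = _counts_to_rows(TBL)
        fit = assoc.fit_logistic(y, np.column_stack([np.ones_like(x), x]),
                                 names=("intercept", "long"))
        j = fit.term("long")
        assert fit.params[j] == pytest.approx(LOG_OR, abs=1e-6)
        assert fit.se[j] == pytest.approx(WOOLF_SE, abs=1e-6)

    def test_symmetric_null_design_gives_zero_exposure_coefficient(self):
        y = np.tile([0, 1], 40)
        x = np.repeat([0, 1], 40)
        fit = assoc.fit_logistic(y, np.column_stack([np.ones(80), x]))
        assert fit.params[1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_grid_search_mle_on_small_sample(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = (rng.random(30) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        fit = assoc.fit_logistic(y, np.column_stack([np.ones(30), x]))

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return float((y * eta - np.log1p(np.exp(eta))).sum())

        b0g = np.linspace(fit.params[0] - 0.5, fit.params[0] + 0.5, 201)
        b1g = np.linspace(fit.params[1] - 0.5, fit.params[1] + 0.5, 201)
        ll = np.array([[loglik(b0, b1) for b1 in b1g] for b0 in b0g])
        i, j = np.unravel_index(ll.argmax(), ll.shape)
        assert fit.params[0] == pytest.approx(b0g[i], abs=1e-2)
        assert fit.params[1] == pytest.approx(b1g[j], abs=1e-2)
        # and the grid maximum never beats the reported MLE
        assert loglik(*fit.params) >= ll.max() - 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_statsmodels_mle(self, seed):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(seed)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.4, n)])
        eta = X @ np.array([-0.5, 0.6, -0.3])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = assoc.fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-5)

    def test_separation_raises_explicit_error(self):
        x = np.arange(20, dtype=float)
        y = (x >= 10).astype(float)
        with pytest.raises(assoc.SeparationError):
            assoc.fit_logistic(y, np.column_stack([np.ones(20), x]))

    def test_rank_deficiency_names_aliased_column(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = rng.integers(0, 2, 50).astype(float)
        X = np.column_stack([np.ones(50), x, 2.0 * x])
        with pytest.raises(assoc.RankDeficiencyError, match="x|dup"):
            # either member of the collinear pair may be reported
            assoc.fit_logistic(y, X, names=("intercept", "x", "dup"))

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            assoc.fit_logistic(np.ones(10), np.ones((10, 1)))


class TestWaldCI:
    def test_woolf_interval_for_dichotomized_table(self):
        lo, hi = assoc.wald_ci(LOG_OR, WOOLF_SE)
        assert lo == pytest.approx(1.1847, abs=1e-3)
        assert hi == pytest.approx(1.7639, abs=1e-3)

    def test_null_estimate_interval_symmetric_on_log_scale(self):
        lo, hi = assoc.wald_ci(0.0, 0.3)
        assert lo * hi == pytest.approx(1.0, rel=1e-12)

    def test_interval_collapses_as_se_vanishes(self):
        lo, hi = assoc.wald_ci(0.5, 1e-12)
        assert lo == pytest.approx(math.exp(0.5), rel=1e-9)
        assert hi == pytest.approx(math.exp(0.5), rel=1e-9)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            assoc.wald_ci(0.1, 0.0)


class TestCrudeOR:
    def test_dichotomized_table_value(self):
        res = assoc.crude_or(TBL)
        assert res.or_ == pytest.approx(1.4456, abs=1e-4)
        assert res.se == pytest.approx(WOOLF_SE, rel=1e-12)
        assert not res.corrected

    def test_uniform_table_is_null(self):
        assert assoc.crude_or(ContingencyTable(10, 10, 10, 10)).or_ == 1.0

    def test_transposing_exposure_and_outcome_preserves_or(self):
        t = ContingencyTable(12, 5, 7, 19)
        transposed = ContingencyTable(12, 7, 5, 19)
        assert assoc.crude_or(t).or_ == pytest.approx(
            assoc.crude_or(transposed).or_, rel=1e-12
        )

    def test_zero_cell_triggers_haldane_correction(self):
        res = assoc.crude_or(ContingencyTable(5, 3, 0, 7))
        assert res.corrected
        assert res.or_ == pytest.approx((5.5 * 7.5) / (3.5 * 0.5), rel=1e-12)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            assoc.crude_or(ContingencyTable(0, 5, 0, 7))

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50),
           st.integers(1, 50))
    def test_increasing_exposed_cases_increases_or(self, a, b, c, d):
        base = assoc.crude_or(ContingencyTable(a, b, c, d)).or_
        bumped = assoc.crude_or(ContingencyTable(a, b, c, d + 1)).or_
        assert bumped > base


class TestAllelicOR:
    def test_equal_frequencies_are_null(self):
        assert assoc.allelic_or_from_eaf(0.3, 0.3) == pytest.approx(1.0)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_inverse_of_swapped_groups(self, p, q):
        forward = assoc.allelic_or_from_eaf(p, q)
        assert forward * assoc.allelic_or_from_eaf(q, p) == pytest.approx(1.0)

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError):
            assoc.allelic_or_from_eaf(0.0, 0.5)


class TestChisq:
    def test_uniform_table_statistic_zero(self):
        stat, p = assoc.chisq_2x2(ContingencyTable(10, 10, 10, 10))
        assert stat == 0.0 and p == 1.0

    def test_dichotomized_table_statistic(self):
        stat, p = assoc.chisq_2x2(TBL)
        assert stat == pytest.approx(13.2065, abs=1e-4)
        ref = stats.chi2_contingency(TBL.as_array(), correction=False)
        assert stat == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_invariant_to_swapping_rows_and_columns(self):
        t = ContingencyTable(8, 3, 14, 9)
        swapped = ContingencyTable(9, 14, 3, 8)
        assert assoc.chisq_2x2(t)[0] == pytest.approx(
            assoc.chisq_2x2(swapped)[0], rel=1e-12
        )

    def test_continuity_correction_matches_scipy_yates(self):
        t = ContingencyTable(12, 5, 7, 19)
        stat, _ = assoc.chisq_2x2(t, continuity=True)
        ref = stats.chi2_contingency(t.as_array(), correction=True)
        assert stat == pytest.approx(ref.statistic, rel=1e-12)

    def test_equals_logistic_score_test(self, rng):
        """Pearson chi-square is the score test of the 2x2 logistic model."""
        from conftest import random_2x2

        for _ in range(25):
            a, b, c, d = random_2x2(rng, max_total=200)
            t = ContingencyTable(a, b, c, d)
            y, x = _counts_to_rows(t)
            X = np.column_stack([np.ones_like(x, dtype=float), x])
            # score test at the intercept-only MLE (mu = ybar)
            mu = np.full(y.shape, y.mean())
            u = X.T @ (y - mu)
            info = (X * (mu * (1 - mu))[:, None]).T @ X
            score_stat = float(u @ np.linalg.solve(info, u))
            assert assoc.chisq_2x2(t)[0] == pytest.approx(score_stat, abs=1e-6)


class TestFisherExact:
    def test_small_table_enumeration_value(self):
        assert assoc.fisher_exact(ContingencyTable(3, 1, 1, 3)) == pytest.approx(
            34 / 70, rel=1e-12
        )

    def test_degenerate_margin_p_is_one(self):
        assert assoc.fisher_exact(ContingencyTable(0, 6, 0, 6)) == 1.0

    def test_matches_independent_oracles_for_small_totals(self, rng):
        """Exhaustive hypergeometric enumeration and scipy agree exactly."""
        from conftest import random_2x2

        for _ in range(60):
            a, b, c, d = random_2x2(rng, max_total=40)
            t = ContingencyTable(a, b, c, d)
            p = assoc.fisher_exact(t)
            # brute-force oracle: enumerate every table with these margins
            r1, _, c1, _ = t.margins()
            total = 0.0
            p_obs = (
                math.comb(r1, a) * math.comb(t.n - r1, c1 - a) / math.comb(t.n, c1)
            )
            for aa in range(max(0, r1 + c1 - t.n), min(r1, c1) + 1):
                prob = (
                    math.comb(r1, aa)
                    * math.comb(t.n - r1, c1 - aa)
                    / math.comb(t.n, c1)
                )
                if prob <= p_obs * (1 + 1e-7):
                    total += prob
            assert p == pytest.approx(min(total, 1.0), rel=1e-9)
            assert p == pytest.approx(
                stats.fisher_exact(t.as_array())[1], rel=1e-7
            )

    def test_enumeration_cap_advises_chisq(self):
        with pytest.raises(ValueError, match="chisq"):
            assoc.fisher_exact(ContingencyTable(10, 10, 10, 10), max_total=20)


class TestTrend:
    @staticmethod
    def _balanced(n_per=60, k=3):
        cats = np.repeat(np.arange(1, k + 1), 2 * n_per)
        y = np.tile([0, 1], n_per * k)
        return y, cats

    def test_identical_occupancies_give_null_trend(self):
        y, cats = self._balanced()
        res = assoc.trend_test(y, cats)
        assert res.estimate == pytest.approx(0.0, abs=1e-8)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_reversing_category_order_flips_sign_same_p(self, rng):
        cats = rng.integers(1, 5, 300)
        y = (rng.random(300) < 0.2 + 0.1 * cats / 4).astype(float)
        fwd = assoc.trend_test(y, cats)
        rev = assoc.trend_test(y, 5 - cats)
        assert rev.estimate == pytest.approx(-fwd.estimate, abs=1e-6)
        assert rev.p == pytest.approx(fwd.p, abs=1e-8)

    def test_requires_three_categories(self):
        with pytest.raises(ValueError, match="3 categories"):
            assoc.trend_test(np.array([0, 1, 0, 1]), np.array([1, 1, 2, 2]))

    def test_more_powerful_than_unordered_test_under_monotone_effect(self):
        """Median trend p over replicates beats the 2-df heterogeneity test
        when category odds really are monotone."""
        rng = np.random.default_rng(17)
        wins = 0
        n_reps = 60
        for _ in range(n_reps):
            cats = rng.integers(1, 4, 240)
            y = (rng.random(240) < 1 / (1 + np.exp(-(-1.0 + 0.35 * cats)))).astype(
                float
            )
            trend_p = assoc.trend_test(y, cats).p
            # 2-df Wald test from the dummy-coded model
            X = np.column_stack(
                [np.ones(240), (cats == 2).astype(float), (cats == 3).astype(float)]
            )
            fit = assoc.fit_logistic(y, X)
            beta = fit.params[1:]
            cov = fit.cov[1:, 1:]
            w2 = float(beta @ np.linalg.solve(cov, beta))
            p2 = float(stats.chi2.sf(w2, 2))
            wins += trend_p < p2
        assert wins > n_reps / 2

    def test_cochran_armitage_agrees_with_scipy_chisquare_machinery(self):
        counts_control = [40, 35, 25]
        counts_case = [25, 35, 40]
        z, p = assoc.cochran_armitage_trend(counts_control, counts_case)
        # null-invariance and symmetry checks
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-12)
        z2, _ = assoc.cochran_armitage_trend(counts_case, counts_control)
        assert z2 == pytest.approx(-z, rel=1e-9)


class TestEAF:
    def test_mean_dosage_halved(self):
        assert assoc.eaf(np.array([0, 1, 1, 2])) == 0.5
        assert assoc.eaf(np.array([2.0, 2.0])) == 1.0

    def test_subset_selection(self):
        x = np.array([0.0, 2.0, 2.0, 2.0])
        assert assoc.eaf(x, subset=np.array([True, False, False, False])) == 0.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assoc.eaf(np.array([1.0]), subset=np.array([False]))
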