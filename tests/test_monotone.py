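"""Constrained monotone fits, BIC, sequence comparison and the trend test."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import lsq_linear
from sklearn.isotonic import IsotonicRegression

import atnseq as a
from atnseq.errors import FitError, InsufficientGroupError, ValidationError

from conftest import grouped_outcome


def lsq_linear_sse(design, y):
    """Independent bound-constrained least-squares oracle (scipy)."""
    X = design.X
    lb = np.full(X.shape[1], -np.inf)
    ub = np.full(X.shape[1], np.inf)
    ub[1:4] = 0.0  # the three successive-difference coefficients
    res = lsq_linear(X, y, bounds=(lb, ub), tol=1e-14)
    return float(np.sum((y - X @ res.x) ** 2))


def random_instance(rng, with_covariates=True, max_per_group=15):
    n_per = rng.integers(3, max_per_group, size=4)
    groups = np.repeat(list(a.AD_CONTINUUM), n_per)
    y = rng.normal(size=len(groups))
    cov = None
    if with_covariates:
        cov = pd.DataFrame(
            rng.normal(size=(len(groups), 5)),
            columns=["age", "sex", "education", "ticv", "wmh"],
        )
    return y, groups, cov


class TestBuildDesign:
    def test_shapes_no_covariates(self, ach):
        y, groups = grouped_outcome((1, 2, 3, 4), n_per=5)
        d = a.build_design(groups, ach, None)
        assert d.mean_block.shape == (20, 4)
        assert d.n_covariates == 0
        assert list(d.counts) == [5, 5, 5, 5]

    def test_subject_outside_sequence_states_excluded(self, ach):
        groups = np.append(np.repeat(list(a.AD_CONTINUUM), 5), "A-T+N-")
        d = a.build_design(groups, ach, None)
        assert d.n == 20
        assert d.n_excluded == 1

    def test_covariates_centered(self, ach):
        rng = np.random.default_rng(0)
        y, groups = grouped_outcome((1, 2, 3, 4), n_per=6)
        cov = pd.DataFrame({"age": rng.uniform(60, 80, 24)})
        d = a.build_design(groups, ach, cov)
        assert abs(d.cov_block.sum()) < 1e-9

    def test_minimum_group_size_enforced(self, ach):
        groups = np.repeat(list(a.AD_CONTINUUM), (5, 5, 2, 5))
        with pytest.raises(InsufficientGroupError, match="A\\+T\\+N-"):
            a.build_design(groups, ach, None)


class TestFitMonotone:
    def test_already_monotone_noiseless(self, ach):
        y, groups = grouped_outcome((10, 8, 5, 5))
        fit = a.fit_monotone(y, a.build_design(groups, ach, None))
        assert fit.beta1 == pytest.approx(10.0)
        assert fit.beta_diffs == pytest.approx([-2.0, -3.0, 0.0], abs=1e-10)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)

    def test_violator_pooled_like_pava(self, ach):
        y, groups = grouped_outcome((5, 6, 4, 3))
        fit = a.fit_monotone(y, a.build_design(groups, ach, None))
        assert fit.fitted_position_means == pytest.approx([5.5, 5.5, 4.0, 3.0])

    def test_constraints_and_monotonicity_invariants(self, ach):
        rng = np.random.default_rng(42)
        for _ in range(20):
            y, groups, cov = random_instance(rng)
            d = a.build_design(groups, ach, cov)
            fit = a.fit_monotone(y, d)
            assert np.all(fit.beta_diffs <= 1e-10)
            assert np.all(np.diff(fit.fitted_position_means) <= 1e-10)
            unc = a.fit_unconstrained(y, d)
            assert unc.sse <= fit.sse + 1e-10

    @pytest.mark.parametrize("with_cov", [True, False])
    def test_matches_scipy_bounded_lsq(self, ach, with_cov):
        rng = np.random.default_rng(7)
        for _ in range(30):
            y, groups, cov = random_instance(rng, with_covariates=with_cov)
            d = a.build_design(groups, ach, cov)
            fit = a.fit_monotone(y, d)
            assert fit.sse == pytest.approx(lsq_linear_sse(d, y), abs=1e-8)

    def test_pava_equivalence_unequal_groups(self, ach):
        """Without covariates the fitted means equal weighted PAVA on group means."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_per = rng.integers(3, 12, size=4)
            groups = np.repeat(list(a.AD_CONTINUUM), n_per)
            y = rng.normal(size=len(groups))
            d = a.build_design(groups, ach, None)
            fit = a.fit_monotone(y, d)
            gmeans = [y[groups == g].mean() for g in a.AD_CONTINUUM]
            iso = IsotonicRegression(increasing=False).fit(
                np.arange(4), gmeans, sample_weight=n_per
            )
            assert fit.fitted_position_means == pytest.approx(
                iso.predict(np.arange(4)), abs=1e-9
            )

    def test_non_finite_outcome_rejected(self, ach):
        y, groups = grouped_outcome((1, 2, 3, 4))
        y[3] = np.nan
        with pytest.raises(ValidationError):
            a.fit_monotone(y, a.build_design(groups, ach, None))


class TestFitUnconstrained:
    def test_equals_constrained_on_monotone_input(self, ach):
        y, groups = grouped_outcome((10, 8, 5, 2))
        d = a.build_design(groups, ach, None)
        fit_c = a.fit_monotone(y, d)
        fit_u = a.fit_unconstrained(y, d)
        expected = np.array([fit_c.beta1, *fit_c.beta_diffs])
        assert fit_u.coefs[:4] == pytest.approx(expected, abs=1e-9)

    def test_standard_errors_match_statsmodels(self, ach):
        rng = np.random.default_rng(3)
        groups = np.repeat(list(a.AD_CONTINUUM), 3)  # 12 subjects
        y = rng.normal(size=12)
        cov = pd.DataFrame({"age": rng.normal(size=12)})
        d = a.build_design(groups, ach, cov)
        fit = a.fit_unconstrained(y, d)
        ref = sm.OLS(y, d.X).fit()
        assert fit.coefs == pytest.approx(ref.params, abs=1e-10)
        assert fit.se == pytest.approx(ref.bse, abs=1e-10)
        assert fit.sse == pytest.approx(ref.ssr, abs=1e-10)


class TestBIC:
    def test_formula(self):
        assert a.bic(2.0, 8, 5) == pytest.approx(
            8 * np.log(0.25) + 5 * np.log(8)
        )
        assert a.bic(2.0, 8, 5) == pytest.approx(-0.6931, abs=1e-4)

    def test_monotone_in_sse(self):
        assert a.bic(1.0, 8, 5) < a.bic(2.0, 8, 5)
        assert a.bic(2.0, 8, 5) == a.bic(2.0, 8, 5)

    def test_zero_sse_sentinel(self):
        with pytest.warns(RuntimeWarning):
            assert a.bic(0.0, 8, 5) == -np.inf

    def test_requires_n_above_k(self):
        with pytest.raises(FitError):
            a.bic(1.0, 5, 5)


class TestCompareSequences:
    def test_single_sequence_set(self, ach):
        y, groups = grouped_outcome((4, 3, 2, 1))
        only = a.SequenceSet([ach], reference="ACH")
        comp = a.compare_sequences(y, groups, None, only)
        assert comp.winner == "ACH"
        assert comp.reference_rank == 1

    def test_noiseless_decline_wins_among_24(self, ach):
        y, groups = grouped_outcome((10, 8, 5, 2))
        comp = a.compare_sequences(y, groups, None, a.permutation_sequences())
        assert comp.winner == "ACH"
        assert not comp.tie
        assert comp.table.loc["ACH", "sse"] == pytest.approx(0.0, abs=1e-18)

    def test_reversed_decline_prefers_reversed_order(self, ach):
        y, groups = grouped_outcome((2, 5, 8, 10))
        seqs = a.permutation_sequences()
        comp = a.compare_sequences(y, groups, None, seqs)
        assert comp.winner != "ACH"
        assert seqs.get(comp.winner).states == tuple(reversed(a.AD_CONTINUUM))

    def test_bic_ranking_equals_sse_ranking_at_fixed_k_n(self, ach):
        rng = np.random.default_rng(19)
        groups = np.repeat(list(a.AD_CONTINUUM), 8)
        y = rng.normal(size=len(groups))
        comp = a.compare_sequences(y, groups, None, a.permutation_sequences())
        assert (comp.table["n"] == 32).all() and comp.table["k"].nunique() == 1
        by_bic = comp.table.sort_values("bic").index
        by_sse = comp.table.sort_values("sse").index
        assert list(by_bic) == list(by_sse)

    def test_permutation_consistency(self, ach):
        """Relabeling groups by a permutation permutes the winner accordingly."""
        rng = np.random.default_rng(23)
        groups = np.repeat(list(a.AD_CONTINUUM), 10)
        y = rng.normal(size=len(groups)) + np.repeat([3.0, 2.0, 1.0, 0.0], 10)
        seqs = a.permutation_sequences()
        comp = a.compare_sequences(y, groups, None, seqs)
        # swap two group labels everywhere; the winning *ordering of outcomes*
        # must be unchanged up to the same relabeling
        swap = {"A+T-N-": "A+T+N-", "A+T+N-": "A+T-N-"}
        groups_sw = np.array([swap.get(g, g) for g in groups])
        comp_sw = a.compare_sequences(y, groups_sw, None, seqs)
        win = seqs.get(comp.winner).states
        win_sw = seqs.get(comp_sw.winner).states
        assert tuple(swap.get(g, g) for g in win) == win_sw

    def test_underfilled_sequences_dropped_with_warning(self):
        # only the AD-continuum groups are populated: the 6-path set keeps
        # just the ACH path and drops the rest
        y, groups = grouped_outcome((5, 4, 3, 2), n_per=6)
        with pytest.warns(RuntimeWarning):
            comp = a.compare_sequences(y, groups, None, a.conversion_paths())
        assert comp.winner == "ACH"
        assert set(comp.dropped) == {"ANT", "NAT", "NTA", "TAN", "TNA"}


class TestTrendTest:
    def test_strong_decline_is_overwhelming(self, ach):
        rng = np.random.default_rng(5)
        groups = np.repeat(list(a.AD_CONTINUUM), 40)
        y = np.repeat([0.0, -2.0, -4.0, -6.0], 40) + rng.normal(size=160)
        res = a.trend_test(y, groups, None, ach)
        assert res.p < 1e-6
        assert res.t < 0

    def test_increase_has_high_one_sided_p(self, ach):
        rng = np.random.default_rng(6)
        groups = np.repeat(list(a.AD_CONTINUUM), 20)
        y = np.repeat([0.0, 1.0, 2.0, 3.0], 20) + 0.5 * rng.normal(size=80)
        assert a.trend_test(y, groups, None, ach).p > 0.5

    def test_null_p_values_uniform(self, ach):
        """One-sided p under the null is Uniform(0,1): KS statistic < 0.05."""
        rng = np.random.default_rng(8)
        groups = np.repeat(list(a.AD_CONTINUUM), 25)
        Y = rng.normal(size=(100, 1000))
        _, p, _ = a.trend_test_many(Y, groups, None, ach)
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05

    def test_matches_statsmodels_single_fit(self, ach):
        rng = np.random.default_rng(9)
        groups = np.repeat(list(a.AD_CONTINUUM), 6)
        y = rng.normal(size=24)
        cov = pd.DataFrame({"age": rng.normal(size=24), "sex": rng.integers(0, 2, 24)})
        res = a.trend_test(y, groups, cov, ach)
        pos = np.repeat([1.0, 2.0, 3.0, 4.0], 6)
        X = np.column_stack(
            [np.ones(24), pos - pos.mean(), cov - cov.mean(axis=0)]
        )
        ref = sm.OLS(y, X).fit()
        assert res.t == pytest.approx(ref.tvalues[1], abs=1e-10)
        # statsmodels p is two-sided; one-sided for decline is cdf
        assert res.p == pytest.approx(stats.t.cdf(ref.tvalues[1], ref.df_resid))
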