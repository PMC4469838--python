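"""Cross-validated partial likelihood and the validation criteria."""
import numpy as np
import pytest

from coxtp.cox import compute_lambda0, cox_partial_loglik, fit_cox_newton
from coxtp.data import SurvivalDataset
from coxtp.evaluation import (cv_folds, cv_score, deviance, km_curves,
                              logrank_test, pi_cox_pvalue, prognostic_index,
                              rank_vs_random_aic, select_lambda_by_cv,
                              _argmax_larger_lambda)
from coxtp.path import compute_path, fit_lasso_at

from conftest import enum_partial_loglik, random_dataset


class TestCVScore:
    def test_all_zero_fits_in_closed_form(self, make_dataset):
        """Above every fold's lambda0 the CV score only involves null models."""
        ds = make_dataset(20, n=30, p=3)
        K, seed = 3, 5
        fold = cv_folds(ds.events, K, seed)
        lam = 2.0 * compute_lambda0(ds)
        expected = 0.0
        for k in range(K):
            train = ds.subset(np.flatnonzero(fold != k))
            # null partial likelihoods from direct risk-set enumeration
            expected += (enum_partial_loglik(np.zeros(3), ds)
                         - enum_partial_loglik(np.zeros(3), train))
        assert cv_score(lam, ds, K=K, fold_seed=seed) == pytest.approx(expected)

    def test_matches_independent_reimplementation(self, make_dataset):
        ds = make_dataset(21, n=30, p=3, signal=1.0)
        K, seed = 3, 9
        lam = 0.4 * compute_lambda0(ds)
        fold = cv_folds(ds.events, K, seed)
        expected = 0.0
        for k in range(K):
            train = ds.subset(np.flatnonzero(fold != k))
            beta = fit_lasso_at(lam, train)
            expected += (enum_partial_loglik(beta, ds)
                         - enum_partial_loglik(beta, train))
        assert cv_score(lam, ds, K=K, fold_seed=seed) == pytest.approx(
            expected, rel=1e-8)

    def test_invariant_to_patient_order(self, make_dataset):
        ds = make_dataset(22, n=24, p=2, signal=0.8)
        lam = 0.5 * compute_lambda0(ds)
        folds = cv_folds(ds.events, 3, seed=1)
        got = cv_score(lam, ds, K=3, folds=folds)
        # permute patients together with their fold labels
        rng = np.random.default_rng(0)
        perm = rng.permutation(24)
        got2 = cv_score(lam, ds.subset(perm), K=3, folds=folds[perm])
        assert got2 == pytest.approx(got, rel=1e-6)

    def test_degenerate_fold_is_an_error(self):
        ds = SurvivalDataset(times=[1.0, 2.0, 3.0, 4.0],
                             events=[1, 0, 0, 0],
                             expression=np.eye(4))
        with pytest.raises(ValueError, match="degenerate fold"):
            cv_score(1.0, ds, K=2, fold_seed=0)


class TestSelectLambdaByCV:
    def test_tie_rule_prefers_larger_lambda(self):
        lams = np.array([5.0, 4.0, 3.0, 2.0])
        assert _argmax_larger_lambda(lams, np.array([1.0, 2.0, 2.0, 0.5])) == 1
        assert _argmax_larger_lambda(lams, np.array([1.0, 1.0, 1.0, 1.0])) == 0

    def test_selects_cv_maximizer_on_path(self, make_dataset):
        ds = make_dataset(23, n=40, p=5, signal=1.2)
        path = compute_path(ds, min_ratio=0.1)
        sel = select_lambda_by_cv(ds, path, K=4, fold_seed=3)
        i = int(np.flatnonzero(sel.lambdas == sel.lam_star)[0])
        assert sel.scores[i] == pytest.approx(sel.scores.max())
        # spot-check one curve point against the single-lambda scorer
        j = len(sel.lambdas) // 2
        assert sel.scores[j] == pytest.approx(
            cv_score(float(sel.lambdas[j]), ds, K=4, fold_seed=3), rel=1e-6)


class TestPrognosticIndex:
    def test_matches_matrix_product(self, make_dataset):
        ds = make_dataset(24, n=20, p=3)
        beta = np.array([0.5, -1.0, 0.2])
        split = prognostic_index(beta, ds)
        assert np.allclose(split.eta, ds.expression @ beta)
        assert split.group_sizes[0] + split.group_sizes[1] == 20

    def test_zero_beta_puts_everyone_at_the_median(self, make_dataset):
        ds = make_dataset(25, n=10, p=2)
        split = prognostic_index(np.zeros(2), ds)
        assert np.all(split.eta == 0.0)
        assert split.better.all()          # ties at the median -> "better"

    def test_single_gene_recovers_expression_column(self, make_dataset):
        ds = make_dataset(26, n=15, p=1)
        split = prognostic_index(np.array([1.0]), ds)
        assert np.allclose(split.eta, ds.expression[:, 0])


class TestLogrank:
    def test_matches_hand_computed_statistic(self):
        """Two tiny groups; O-E and variance accumulated by hand below."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 1, 1, 1])
        groups = np.array([True, True, True, False, False, False])
        # independent O-E computation over the six distinct event times
        o_minus_e = 0.0
        var = 0.0
        for t in times:
            at_risk = times >= t
            n1 = int((at_risk & groups).sum())
            n = int(at_risk.sum())
            d = 1
            o = int(groups[times == t][0])
            e = d * n1 / n
            o_minus_e += o - e
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        from scipy.stats import chi2
        p_hand = chi2.sf(o_minus_e ** 2 / var, 1)
        assert logrank_test(times, events, groups) == pytest.approx(
            p_hand, rel=1e-6)

    def test_null_case_label_permutation(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(size=40)
        events = np.ones(40, dtype=int)
        ps = []
        for _ in range(100):
            groups = np.zeros(40, dtype=bool)
            groups[rng.choice(40, 20, replace=False)] = True
            p = logrank_test(times, events, groups)
            assert 0.0 <= p <= 1.0
            ps.append(p)
        assert 0.35 < np.mean(ps) < 0.65

    def test_pvalues_uniform_under_permutation(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(2)
        times = rng.exponential(size=40)
        events = (rng.uniform(size=40) > 0.2).astype(int)
        ps = []
        for _ in range(500):
            groups = np.zeros(40, dtype=bool)
            groups[rng.choice(40, 20, replace=False)] = True
            ps.append(logrank_test(times, events, groups))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [True, True])


class TestPiCox:
    def test_null_permutation_pvalues_centered(self):
        ds = random_dataset(30, n=40, p=1, censor_frac=0.1)
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            eta = rng.permutation(ds.expression[:, 0])
            ps.append(pi_cox_pvalue(eta, ds).p_value)
        assert 0.4 < np.mean(ps) < 0.6

    def test_power_and_sign_on_planted_signal(self):
        hits = 0
        for seed in range(20):
            ds = random_dataset(seed, n=120, p=1, censor_frac=0.1, signal=1.5)
            res = pi_cox_pvalue(ds.expression[:, 0] * 1.5, ds)
            assert res.alpha > 0          # risk increases with the signal
            hits += res.p_value < 0.01
        assert hits >= 18

    def test_constant_index_is_an_error(self, make_dataset):
        ds = make_dataset(31, n=10, p=1)
        with pytest.raises(ValueError):
            pi_cox_pvalue(np.ones(10), ds)


class TestDeviance:
    def test_zero_for_null_coefficients(self, make_dataset):
        for seed in (40, 41):
            ds = make_dataset(seed, n=25, p=4)
            assert deviance(np.zeros(4), ds) == 0.0

    def test_compositional_check(self, make_dataset):
        ds = make_dataset(42, n=25, p=3, signal=1.0)
        beta = np.array([0.8, -0.1, 0.2])
        expected = -2.0 * (cox_partial_loglik(beta, ds)
                           - cox_partial_loglik(np.zeros(3), ds))
        assert deviance(beta, ds) == pytest.approx(expected)

    def test_negative_when_fit_improves_validation(self):
        train = random_dataset(43, n=150, p=2, signal=1.5)
        val = random_dataset(44, n=150, p=2, signal=1.5)
        fit = fit_cox_newton(train)
        assert deviance(fit.beta, val) < 0


class TestRankVsRandom:
    def test_full_subset_fraction_is_zero(self, make_dataset):
        ds = make_dataset(50, n=40, p=4, signal=1.0)
        beta = fit_lasso_at(0.3 * compute_lambda0(ds), ds)
        m = int(np.sum(np.abs(beta) > 1e-10))
        assert m >= 2
        assert rank_vs_random_aic(beta, ds, m, n_random=20, seed=0) == 0.0

    def test_null_data_fraction_near_half(self):
        fracs = []
        for seed in range(5):
            ds = random_dataset(60 + seed, n=50, p=8, censor_frac=0.0)
            rng = np.random.default_rng(seed)
            beta = np.where(rng.uniform(size=8) < 0.9,
                            rng.normal(scale=0.2, size=8), 0.0)
            if np.sum(beta != 0) < 4:
                continue
            fracs.append(rank_vs_random_aic(beta, ds, 3, n_random=60,
                                            seed=seed))
        assert 0.25 < np.mean(fracs) < 0.75

    def test_planted_signal_ranking_beats_chance(self):
        ds = random_dataset(70, n=100, p=6, censor_frac=0.0, signal=1.5)
        beta = fit_lasso_at(0.05 * compute_lambda0(ds), ds)
        m = int(np.sum(np.abs(beta) > 1e-10))
        assert m >= 3
        frac = rank_vs_random_aic(beta, ds, max(1, m // 2), n_random=100,
                                  seed=1)
        assert frac < 0.35

    def test_oversized_subset_is_an_error(self, make_dataset):
        ds = make_dataset(71, n=30, p=3)
        with pytest.raises(ValueError):
            rank_vs_random_aic(np.array([0.5, 0.0, 0.0]), ds, 2)


class TestKMExport:
    def test_tidy_frame_with_both_groups(self, make_dataset):
        ds = make_dataset(80, n=30, p=2)
        groups = np.arange(30) < 15
        df = km_curves(ds.times, ds.events, groups)
        assert set(df["group"]) == {"better", "worse"}
        for _, g in df.groupby("group"):
            s = g["survival"].to_numpy()
            assert np.all(np.diff(s) <= 1e-12)
            assert s[0] <= 1.0 + 1e-12
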