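"""Mixture density, maximum-likelihood fits and the TP/FP estimators."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from coxtp.mixture import (DegenerateFitError, MixtureParams,
                           estimate_counts, estimate_proportions, fit_mixture,
                           mixture_logpdf, select_C_by_aic)


def params(pi0=0.5, pi=(0.5,), tau=5.0, mu=(1.0,), sigma=(0.3,), **kw):
    return MixtureParams(pi0=pi0, pi=np.array(pi), tau=tau,
                         mu=np.array(mu), sigma=np.array(sigma),
                         C=len(pi), **kw)


class TestLogpdf:
    def test_pure_laplace_mode(self):
        p = params(pi0=1.0, pi=(0.0,), tau=1.0, n_over_p=1.0)
        assert mixture_logpdf(0.0, p) == pytest.approx(-np.log(2.0))

    def test_integrates_to_one(self):
        p = params(pi0=0.4, pi=(0.6,), tau=8.0, mu=(1.2,), sigma=(0.25,))
        total = quad(lambda v: np.exp(mixture_logpdf(v, p)), -30, 30,
                     limit=200)[0]
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_selected_part_scales_with_n_over_p(self):
        # away from zero the eps-spike is numerically nil, so the density
        # is n/p times the selected-gene mixture
        full = params(pi0=0.4, pi=(0.6,), n_over_p=0.2)
        sel = params(pi0=0.4, pi=(0.6,), n_over_p=1.0)
        v = 0.8
        assert mixture_logpdf(v, full) == pytest.approx(
            np.log(0.2) + mixture_logpdf(v, sel))

    def test_symmetric_when_normal_weight_vanishes(self):
        p = params(pi0=1.0, pi=(0.0,))
        for v in (0.1, 0.7, 2.0):
            assert mixture_logpdf(v, p) == pytest.approx(mixture_logpdf(-v, p))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            params(pi0=0.7, pi=(0.5,))
        with pytest.raises(ValueError):
            params(tau=-1.0)
        with pytest.raises(ValueError):
            params(sigma=(0.0,))


class TestFitMixture:
    def test_parameter_recovery_single_normal(self):
        rng = np.random.default_rng(2024)
        x = np.concatenate([rng.laplace(0, 0.2, 1000),
                            rng.normal(1.5, 0.3, 1000)])
        fit = fit_mixture(x, C=1, seed=0)
        assert fit.params.pi0 == pytest.approx(0.5, abs=0.05)
        assert fit.params.laplace_scale == pytest.approx(0.2, abs=0.05)
        assert fit.params.mu[0] == pytest.approx(1.5, abs=0.1)
        assert fit.params.sigma[0] == pytest.approx(0.3, abs=0.1)

    def test_identical_coefficients_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_mixture(np.full(20, 0.7), C=1)

    def test_insufficient_active_set(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_mixture(np.array([0.1, 0.2, 0.3]), C=1)

    def test_fixed_all_fp_reduces_to_laplace_mle(self):
        rng = np.random.default_rng(5)
        x = rng.laplace(0, 0.4, 200)
        fit = fit_mixture(x, C=1, fixed_props=(1.0, 0.0))
        assert fit.params.laplace_scale == pytest.approx(
            np.mean(np.abs(x)), rel=1e-9)
        assert not fit.free_proportions

    def test_free_proportions_dominate_fixed(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.laplace(0, 0.2, 150),
                            rng.normal(1.0, 0.3, 100)])
        free = fit_mixture(x, C=1, seed=1)
        for props in [(0.3, 0.7), (0.6, 0.4), (0.9, 0.1)]:
            fixed = fit_mixture(x, C=1, fixed_props=props)
            assert free.loglik >= fixed.loglik - 1e-6

    def test_aic_counts_free_parameters(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.laplace(0, 0.2, 100),
                            rng.normal(1.2, 0.3, 100)])
        free = fit_mixture(x, C=1, seed=0)
        assert free.aic == pytest.approx(-2 * free.loglik + 2 * 4)
        fixed = fit_mixture(x, C=1, fixed_props=(0.5, 0.5))
        assert fixed.aic == pytest.approx(-2 * fixed.loglik + 2 * 3)


class TestProportionsAndCounts:
    def test_zeta_zero_recovers_mixing_weights(self):
        p = params(pi0=0.57, pi=(0.43,), tau=1 / 0.11, mu=(0.03,),
                   sigma=(0.11,))
        p_fp, p_tp = estimate_proportions(p, zeta=0.0)
        assert p_fp == pytest.approx(0.57)
        assert p_tp == pytest.approx(0.43)

    def test_laplace_tail_closed_form(self):
        # scale 0.1, zeta = 0.1*ln2 -> two-tailed mass exactly 1/2
        p = params(pi0=0.5, pi=(0.5,), tau=10.0)
        p_fp, _ = estimate_proportions(p, zeta=0.1 * np.log(2))
        assert p_fp == pytest.approx(0.25)

    def test_large_zeta_vanishes(self):
        p = params()
        p_fp, p_tp = estimate_proportions(p, zeta=50.0)
        assert p_fp == pytest.approx(0.0, abs=1e-12)
        assert p_tp == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_zeta(self):
        p = params(pi0=0.4, pi=(0.6,), tau=6.0, mu=(0.8,), sigma=(0.4,))
        zs = np.linspace(0, 3, 40)
        fps, tps = zip(*(estimate_proportions(p, z) for z in zs))
        assert np.all(np.diff(fps) <= 1e-12)
        assert np.all(np.diff(tps) <= 1e-12)

    def test_counts_direct_substitution(self):
        fp, tp = estimate_counts(0.57, 0.43, 96)
        assert tp == pytest.approx(41.28)
        assert fp + tp == 96

    @given(st.floats(0, 1), st.floats(0, 1), st.integers(0, 500))
    @settings(max_examples=200, deadline=None)
    def test_counts_conserve_m(self, p_fp, p_tp, m):
        if p_fp + p_tp <= 0:
            with pytest.raises(ValueError):
                estimate_counts(p_fp, p_tp, m)
        else:
            fp, tp = estimate_counts(p_fp, p_tp, m)
            assert fp + tp == m
            assert fp >= 0 and tp >= 0

    def test_extreme_proportions(self):
        assert estimate_counts(0.0, 0.8, 7) == (0.0, 7.0)
        fp, tp = estimate_counts(0.5, 0.5, 10)
        assert (fp, tp) == (5.0, 5.0)


class TestSelectC:
    def _path_from_coeffs(self, steps):
        """Minimal stand-in path carrying only beta vectors (synthetic)."""
        class Step:
            def __init__(self, k, beta):
                self.index, self.lam, self.beta = k, 10.0 / (k + 1), beta

        class P:
            zero_tol = 1e-10

            def __init__(self, betas):
                self.steps = [Step(k, b) for k, b in enumerate(betas)]

        return P(steps)

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(8)
        betas = [np.concatenate([rng.laplace(0, 0.2, 20),
                                 rng.normal(1.0, 0.2, 10)]) for _ in range(3)]
        sel = select_C_by_aic(self._path_from_coeffs(betas), [2])
        assert sel.best_C == 2

    def test_single_normal_data_prefers_c1(self):
        rng = np.random.default_rng(9)
        betas = [np.concatenate([rng.laplace(0, 0.15, 40),
                                 rng.normal(1.3, 0.25, 25)])
                 for _ in range(4)]
        sel = select_C_by_aic(self._path_from_coeffs(betas), [1, 2, 3])
        assert sel.best_C == 1
        assert set(sel.per_step_best) == {0, 1, 2, 3}

    def test_no_fittable_step_is_an_error(self):
        betas = [np.array([0.5, -0.2])] * 3
        with pytest.raises(ValueError):
            select_C_by_aic(self._path_from_coeffs(betas), [1])
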