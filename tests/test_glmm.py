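"""Binomial logit mixed model: likelihood, boundary behaviour, tests, contrasts.

External oracle: the two frozen fixture datasets under tests/data were fit
with lme4::glmer (binomial, logit link, one random intercept, nAGQ = 25);
the reference coefficients, standard errors, sigma and log-likelihood are
frozen below.  glmer reports logLik relative to the saturated model, so
the comparison adds the saturated binomial log-likelihood back.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from vinebirds.calibration import quadrature_stability, sigma0_oracle_discrepancy
from vinebirds.glmm import (
    ModelSpec,
    SeparationError,
    fit_binomial_glmm,
    likelihood_ratio_test,
    marginal_loglik,
    pairwise_contrasts,
    transects_to_frame,
)
from vinebirds.io_types import SentinelTransect, read_sentinel
from vinebirds.synthetic_data import SentinelConfig, SimConfig, simulate_sentinel


def _transect(site, block, group, removed):
    outcomes = tuple([True] * removed + [False] * (5 - removed))
    return SentinelTransect(site=site, block=block, group=group, outcomes=outcomes)


@pytest.fixture(scope="module")
def fixture_boundary(sentinel_fixture_path):
    return read_sentinel(sentinel_fixture_path)


@pytest.fixture(scope="module")
def fixture_re(sentinel_fixture_re_path):
    return read_sentinel(sentinel_fixture_re_path)


class TestSigmaZeroEquivalence:
    def test_two_group_closed_form(self):
        # saturated two-group design: treatment coefficient is the log-odds
        # difference of the observed removal proportions
        data = (
            [_transect("S1", "b1", "control", r) for r in (1, 2, 1, 2)]
            + [_transect("S1", "b2", "nestbox_random", r) for r in (3, 4, 3, 4)]
        )
        fit = fit_binomial_glmm(data, ModelSpec(fixed=("treatment",)),
                                fix_sigma_b=0.0)
        p1, p2 = 6 / 20, 14 / 20
        expected = special.logit(p2) - special.logit(p1)
        assert fit.coef("treatment[nestbox_random]") == pytest.approx(expected, abs=1e-6)
        assert fit.coef("(Intercept)") == pytest.approx(special.logit(p1), abs=1e-6)

    def test_matches_brute_force_binomial_mle(self, fixture_boundary):
        assert sigma0_oracle_discrepancy(fixture_boundary) < 1e-6

    def test_marginal_loglik_at_sigma_zero_is_plain_binomial(self, fixture_re):
        frame = transects_to_frame(fixture_re)
        from vinebirds.glmm import _build_design

        X, _, _, _ = _build_design(frame, ModelSpec(fixed=("treatment",)))
        y = frame["removed"].to_numpy(float)
        n = frame["n"].to_numpy(float)
        beta = np.array([-1.0, 1.5, 2.5])
        ours = marginal_loglik(beta, 0.0, X, y, n,
                               np.zeros(len(y), int), 1)
        ref = float(stats.binom.logpmf(y, n, special.expit(X @ beta)).sum())
        assert ours == pytest.approx(ref, abs=1e-10)


class TestAgainstGlmer:
    # glmer(cbind(removed, 5-removed) ~ treatment + (1|block), nAGQ=25)
    # on tests/data/sentinel_fixture_re.csv
    GLMER_RE = {
        "loglik_vs_saturated": -51.16897882,
        "saturated": -52.65946106182951,
        "beta": {"(Intercept)": -1.4078047,
                 "treatment[nestbox_random]": 2.2513098,
                 "treatment[active_nest]": 3.4013086},
        "se": [0.43461086, 0.60843936, 0.65180278],
        "sigma_b": 0.91082365,
    }
    # glmer(... ~ treatment + site + (1|block), nAGQ=25) on
    # tests/data/sentinel_fixture.csv; glmer reports a singular (sigma=0) fit
    GLMER_BOUNDARY = {
        "loglik_vs_saturated": -13.13289762,
        "saturated": -23.46056936770891,
        "beta": {"(Intercept)": -0.73842594,
                 "treatment[nestbox_random]": 1.03575833,
                 "treatment[active_nest]": 1.99581667,
                 "site[S2]": -0.43269980},
        "se": [0.35847290, 0.42612707, 0.50115924, 0.37239000],
        "sigma_b": 0.0,
        "chi2_vs_site_null": 11.94639869,
    }

    def test_random_intercept_fit_matches_glmer(self, fixture_re):
        ref = self.GLMER_RE
        fit = fit_binomial_glmm(fixture_re, ModelSpec(fixed=("treatment",)), order=25)
        assert fit.converged
        assert fit.loglik == pytest.approx(
            ref["loglik_vs_saturated"] + ref["saturated"], abs=1e-5)
        for name, value in ref["beta"].items():
            assert fit.coef(name) == pytest.approx(value, abs=5e-5)
        assert fit.sigma_b == pytest.approx(ref["sigma_b"], abs=5e-5)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov_beta)), ref["se"],
                                   atol=5e-4)

    def test_boundary_fit_matches_glmer(self, fixture_boundary):
        ref = self.GLMER_BOUNDARY
        fit = fit_binomial_glmm(fixture_boundary,
                                ModelSpec(fixed=("treatment", "site")), order=25)
        assert fit.sigma_b == 0.0
        assert fit.loglik == pytest.approx(
            ref["loglik_vs_saturated"] + ref["saturated"], abs=1e-6)
        for name, value in ref["beta"].items():
            assert fit.coef(name) == pytest.approx(value, abs=5e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov_beta)), ref["se"],
                                   atol=5e-5)

    def test_treatment_lrt_matches_glmer_deviance_difference(self, fixture_boundary):
        full = fit_binomial_glmm(fixture_boundary, ModelSpec(fixed=("treatment", "site")))
        null = fit_binomial_glmm(fixture_boundary, ModelSpec(fixed=("site",)))
        lrt = likelihood_ratio_test(full, null)
        assert lrt.df == 2  # dropping a 3-level treatment costs 2 parameters
        assert lrt.chi2 == pytest.approx(self.GLMER_BOUNDARY["chi2_vs_site_null"],
                                         abs=1e-4)


class TestLikelihoodRatioTest:
    def test_identity_comparison(self, fixture_boundary):
        fit = fit_binomial_glmm(fixture_boundary, ModelSpec(fixed=("site",)))
        lrt = likelihood_ratio_test(fit, fit)
        assert lrt.chi2 == 0.0
        assert lrt.p == 1.0

    def test_non_nested_rejected(self, fixture_boundary):
        a = fit_binomial_glmm(fixture_boundary, ModelSpec(fixed=("treatment",)))
        b = fit_binomial_glmm(fixture_boundary, ModelSpec(fixed=("site",)))
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(a, b)

    def test_chi2_equals_independent_refit(self, fixture_re):
        full = fit_binomial_glmm(fixture_re, ModelSpec(fixed=("treatment",)))
        null = fit_binomial_glmm(fixture_re, ModelSpec(fixed=()))
        lrt = likelihood_ratio_test(full, null)
        # refit both models from scratch and recompute the deviance gap
        refit_gap = (fit_binomial_glmm(fixture_re, ModelSpec(fixed=())).deviance
                     - fit_binomial_glmm(fixture_re,
                                         ModelSpec(fixed=("treatment",))).deviance)
        assert lrt.chi2 == pytest.approx(refit_gap, abs=1e-8)
        assert lrt.df == 2


class TestQuadratureAndInvariance:
    def test_loglik_stable_between_orders_15_and_25(self, fixture_re):
        assert quadrature_stability(fixture_re, orders=(15, 25)) < 1e-6

    def test_laplace_close_but_distinct_mode(self, fixture_re):
        agq = fit_binomial_glmm(fixture_re, ModelSpec(fixed=("treatment",)),
                                method="agq", order=25)
        lap = fit_binomial_glmm(fixture_re, ModelSpec(fixed=("treatment",)),
                                method="laplace")
        assert lap.order == 1
        assert lap.loglik == pytest.approx(agq.loglik, abs=0.5)

    def test_reference_level_invariance(self, fixture_re):
        a = fit_binomial_glmm(fixture_re, ModelSpec(fixed=("treatment",)))
        b = fit_binomial_glmm(
            fixture_re,
            ModelSpec(fixed=("treatment",), treatment_reference="active_nest"))
        # coefficients differ but the likelihood and fitted story do not
        assert a.loglik == pytest.approx(b.loglik, abs=1e-6)
        assert a.sigma_b == pytest.approx(b.sigma_b, abs=1e-4)
        # population-level fitted probability per group is invariant
        p_a = {g: special.expit(a.beta @ _group_row(a, g)) for g in a.treatment_levels}
        p_b = {g: special.expit(b.beta @ _group_row(b, g)) for g in b.treatment_levels}
        for g in p_a:
            assert p_a[g] == pytest.approx(p_b[g], abs=1e-5)


def _group_row(fit, level):
    from vinebirds.glmm import _level_row

    return _level_row(fit, level)


class TestParameterRecovery:
    def test_bias_within_wald_interval_on_large_design(self):
        """Simulated truth recovered on a 200-block design."""
        sc = SentinelConfig(sigma_b=0.5)
        cfg = SimConfig(seed=31, n_sites=100, sentinel=sc)
        transects = simulate_sentinel(cfg)
        fit = fit_binomial_glmm(transects, ModelSpec(fixed=("treatment",)))
        assert fit.converged
        true = {
            "(Intercept)": sc.beta_control,
            "treatment[nestbox_random]": sc.beta_nestbox - sc.beta_control,
            "treatment[active_nest]": sc.beta_active - sc.beta_control,
        }
        se = np.sqrt(np.diag(fit.cov_beta))
        for i, name in enumerate(fit.beta_names):
            assert abs(fit.beta[i] - true[name]) < 2.6 * se[i]
        assert abs(fit.sigma_b - 0.5) < 0.2


class TestContrasts:
    @pytest.fixture(scope="class")
    def fit(self, sentinel_fixture_re_path):
        data = read_sentinel(sentinel_fixture_re_path)
        return fit_binomial_glmm(data, ModelSpec(fixed=("treatment",)))

    def test_all_three_pairs_reported(self, fit):
        contrasts = pairwise_contrasts(fit, seed=9)
        assert [c.pair for c in contrasts] == [
            ("nestbox_random", "control"),
            ("active_nest", "control"),
            ("active_nest", "nestbox_random"),
        ]
        for c in contrasts:
            assert c.z == pytest.approx(c.estimate / c.se)

    def test_bonferroni_closed_form(self, fit):
        contrasts = pairwise_contrasts(fit, adjust="bonferroni")
        for c in contrasts:
            raw = 2 * stats.norm.sf(abs(c.z))
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * raw), abs=1e-12)

    def test_bonferroni_example_z_2_2(self):
        # z = 2.2 with three independent contrasts: p = min(1, 3 x 0.0278)
        raw = 2 * stats.norm.sf(2.2)
        assert 3 * raw == pytest.approx(0.0834, abs=5e-4)

    def test_single_step_bounded_by_bonferroni_and_raw(self, fit):
        ss = pairwise_contrasts(fit, adjust="single_step", seed=10)
        bf = pairwise_contrasts(fit, adjust="bonferroni")
        for s, b in zip(ss, bf):
            raw = 2 * stats.norm.sf(abs(s.z))
            assert raw <= s.p_adjusted <= b.p_adjusted + 1e-12

    def test_single_step_deterministic_given_seed(self, fit):
        a = pairwise_contrasts(fit, seed=11)
        b = pairwise_contrasts(fit, seed=11)
        assert [c.p_adjusted for c in a] == [c.p_adjusted for c in b]

    def test_no_treatment_term_rejected(self, fixture_re):
        fit = fit_binomial_glmm(fixture_re, ModelSpec(fixed=()))
        with pytest.raises(ValueError, match="treatment"):
            pairwise_contrasts(fit)


class TestSeparation:
    def test_all_removed_group_named_in_error(self):
        data = (
            [_transect("S1", "b1", "control", r) for r in (1, 2, 1)]
            + [_transect("S1", "b2", "active_nest", 5) for _ in range(3)]
        )
        with pytest.raises(SeparationError, match="active_nest"):
            fit_binomial_glmm(data, ModelSpec(fixed=("treatment",)))

    def test_all_present_group_named_in_error(self):
        data = (
            [_transect("S1", "b1", "control", 0) for _ in range(3)]
            + [_transect("S1", "b2", "nestbox_random", r) for r in (2, 3, 4)]
        )
        with pytest.raises(SeparationError, match="control"):
            fit_binomial_glmm(data, ModelSpec(fixed=("treatment",)))
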