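"""Approximate and exact natural-effect odds ratios."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

from ccmediate import (
    ContrastSpec,
    DegenerateProbabilityError,
    DesignError,
    DesignSpec,
    EffectEstimate,
    MediatorParams,
    OutcomeParams,
    approx_nde,
    approx_nie,
    estimate_effects,
    exact_counterfactual_prob,
    exact_nde,
    exact_nie,
    total_effect,
)
from ccmediate.effects import (
    _counterfactual_prob,
    log_approx_nde,
    log_approx_nie,
    log_exact_nde,
    log_exact_nie,
)
from ccmediate.fitting import FittedModels

from conftest import random_params


def _models(theta, beta, sigma=None, mediator_type="continuous"):
    outcome = OutcomeParams.from_vector(np.asarray(theta, float))
    mediator = MediatorParams.from_vector(np.asarray(beta, float), sigma=sigma)
    return FittedModels(
        outcome=outcome, mediator=mediator, joint_cov=None,
        strategy_used="naive", mediator_type=mediator_type,
    )


UNIT = ContrastSpec(a=1.0, a_star=0.0, c=np.array([1.0]))


class TestApproximateForms:
    @pytest.mark.parametrize("mediator_type, sigma", [("continuous", 0.5), ("binary", None)])
    def test_no_interaction_reduces_to_exp_theta1(self, mediator_type, sigma):
        m = _models([-2, 0.7, 0.4, 0.0, 0.1], [1.0, 0.3, 0.2], sigma, mediator_type)
        assert approx_nde(m, UNIT) == pytest.approx(np.exp(0.7))

    @pytest.mark.parametrize("mediator_type, sigma", [("continuous", 0.5), ("binary", None)])
    def test_null_model_gives_unity(self, mediator_type, sigma):
        m = _models([0, 0, 0, 0, 0], [0, 0, 0], sigma, mediator_type)
        assert approx_nde(m, UNIT) == pytest.approx(1.0)
        assert approx_nie(m, UNIT) == pytest.approx(1.0)

    def test_continuous_nde_worked_example(self):
        # theta1=0.3, theta3=0.2, theta2=0.4, beta0=1, beta2'c=0.5, sigma=0.5
        m = _models([-2, 0.3, 0.4, 0.2, 0.5], [1.0, 0.8, 0.5], 0.5, "continuous")
        assert approx_nde(m, UNIT) == pytest.approx(np.exp(0.625), rel=1e-10)
        assert np.exp(0.625) == pytest.approx(1.8682, abs=5e-5)

    def test_binary_nie_worked_example(self):
        # beta0=-1, beta1=1, beta2'c=0, theta2=0.5, theta3=0
        m = _models([-2, 0.3, 0.5, 0.0, 0.0], [-1.0, 1.0, 0.0], None, "binary")
        expected = (
            (1 + np.exp(-1.0)) / (1 + np.exp(0.0))
            * (1 + np.exp(0.5)) / (1 + np.exp(-0.5))
        )
        assert approx_nie(m, UNIT) == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(1.1276, abs=5e-5)

    def test_no_exposure_mediator_path_gives_unit_nie(self):
        m = _models([-2, 0.3, 0.5, 0.2, 0.1], [1.0, 0.0, 0.2], 0.5, "continuous")
        assert approx_nie(m, UNIT) == pytest.approx(1.0)

    def test_cancelling_mediator_effect_gives_unit_nie(self):
        m = _models([-2, 0.3, 0.5, -0.5, 0.1], [1.0, 0.8, 0.2], 0.5, "continuous")
        assert approx_nie(m, UNIT) == pytest.approx(1.0)

    def test_nonunit_contrast_rejected(self):
        m = _models([-2, 0.3, 0.5, 0.2, 0.1], [1.0, 0.8, 0.2], 0.5, "continuous")
        with pytest.raises(DesignError):
            approx_nde(m, ContrastSpec(a=0.0, a_star=1.0, c=np.array([1.0])))


class TestExactCounterfactualProb:
    def test_mediator_free_outcome_is_plain_expit(self):
        m = _models([-2, 0.7, 0.0, 0.0, 0.3], [1.0, 0.5, 0.2], 0.5, "continuous")
        for a, a_star in ((1, 0), (1, 1), (0, 1)):
            got = exact_counterfactual_prob(m, a, a_star, [0.5])
            assert got == pytest.approx(expit(-2 + 0.7 * a + 0.15), rel=1e-9)

    def test_degenerate_binary_mediator_at_one(self):
        m = _models([-2, 0.7, 0.4, 0.2, 0.3], [40.0, 0.0, 0.0], None, "binary")
        got = exact_counterfactual_prob(m, 1, 0, [0.5])
        assert got == pytest.approx(expit(-2 + 0.7 + 0.4 + 0.2 + 0.15), rel=1e-8)

    def test_quadrature_matches_direct_integral(self):
        """Gauss-Hermite result equals adaptive quadrature of the
        logistic-normal integrand."""
        rng = np.random.default_rng(20)
        for _ in range(20):
            outcome, med = random_params(rng, "continuous")
            a, a_star = 1.0, 0.0
            c = np.array([rng.normal()])
            mu = float(med.mean(np.array([a_star]), c.reshape(1, -1))[0])

            def integrand(m):
                lp = outcome.linear_predictor(
                    np.array([a]), np.array([m]), c.reshape(1, -1)
                )[0]
                return expit(lp) * norm.pdf(m, mu, med.sigma)

            oracle, _ = quad(integrand, mu - 12 * med.sigma, mu + 12 * med.sigma)
            got = _counterfactual_prob(outcome, med, a, a_star, c, "continuous")
            assert got == pytest.approx(oracle, abs=1e-7)
            assert 0.0 < got < 1.0

    def test_degenerate_probability_raises(self):
        m = _models([80.0, 0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0], 0.5, "continuous")
        with pytest.raises(DegenerateProbabilityError):
            exact_nde(m, ContrastSpec(a=1, a_star=0, c=np.array([0.0])))


class TestExactEffects:
    def test_no_direct_path_gives_unit_nde(self):
        m = _models([-2, 0.0, 0.5, 0.0, 0.1], [1.0, 0.8, 0.2], 0.5, "continuous")
        assert exact_nde(m, UNIT) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("mediator_type, sigma", [("continuous", 0.5), ("binary", None)])
    def test_no_indirect_path_gives_unit_nie(self, mediator_type, sigma):
        m = _models([-2, 0.3, 0.5, 0.2, 0.1], [0.5, 0.0, 0.2], sigma, mediator_type)
        assert exact_nie(m, UNIT) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("mediator_type, sigma", [("continuous", 0.5), ("binary", None)])
    def test_rare_outcome_limit_recovers_approximate_forms(self, mediator_type, sigma):
        """As theta0 -> -infinity the exact ORs converge to the closed
        forms, monotonically over the tested range."""
        rng = np.random.default_rng(22)
        outcome, med = random_params(rng, mediator_type)
        if sigma is not None:
            med = MediatorParams.from_vector(med.vector, sigma=sigma)
        contrast = ContrastSpec(a=1, a_star=0, c=np.array([0.3]))
        gaps = []
        for theta0 in (-4.0, -8.0, -12.0):
            vec = outcome.vector.copy()
            vec[0] = theta0
            shifted = OutcomeParams.from_vector(vec)
            gap = abs(
                log_exact_nde(shifted, med, contrast, mediator_type)
                - log_approx_nde(shifted, med, contrast, mediator_type)
            ) + abs(
                log_exact_nie(shifted, med, contrast, mediator_type)
                - log_approx_nie(shifted, med, contrast, mediator_type)
            )
            gaps.append(gap)
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-3


class TestTotalEffect:
    def test_product_composition(self):
        nde = EffectEstimate("NDE", 1.5, "exact")
        nie = EffectEstimate("NIE", 1.2, "exact")
        te = total_effect(nde, nie)
        assert te.or_value == pytest.approx(1.8)
        assert te.effect == "TE"

    def test_unit_nie_leaves_nde(self):
        nde = EffectEstimate("NDE", 1.37, "approximate")
        nie = EffectEstimate("NIE", 1.0, "approximate")
        assert total_effect(nde, nie).or_value == pytest.approx(nde.or_value)

    def test_method_mismatch_rejected(self):
        from ccmediate.exceptions import DataError

        with pytest.raises(DataError):
            total_effect(
                EffectEstimate("NDE", 1.5, "exact"),
                EffectEstimate("NIE", 1.2, "approximate"),
            )


class TestEstimateEffects:
    def test_ipw_with_sample_fraction_equals_naive(self, cont_sample):
        for method in ("approximate", "exact"):
            naive = estimate_effects(cont_sample, DesignSpec("naive"), method=method)
            ipw = estimate_effects(
                cont_sample,
                DesignSpec("ipw", pi=cont_sample.case_fraction),
                method=method,
            )
            for eff in ("NDE", "NIE", "TE"):
                assert naive[eff].or_value == pytest.approx(
                    ipw[eff].or_value, rel=1e-7
                )

    def test_te_is_product_of_nde_and_nie(self, cont_sample, bin_sample):
        for data in (cont_sample, bin_sample):
            for method in ("approximate", "exact"):
                est = estimate_effects(data, DesignSpec("naive"), method=method)
                assert est["TE"].or_value == pytest.approx(
                    est["NDE"].or_value * est["NIE"].or_value, rel=1e-12
                )

    def test_swapping_contrast_inverts_exact_te(self, cont_sample):
        c = cont_sample.covariate_means()
        fwd = estimate_effects(
            cont_sample, DesignSpec("naive"),
            contrast=ContrastSpec(a=1, a_star=0, c=c), method="exact",
        )
        rev = estimate_effects(
            cont_sample, DesignSpec("naive"),
            contrast=ContrastSpec(a=0, a_star=1, c=c), method="exact",
        )
        assert fwd["TE"].or_value == pytest.approx(1.0 / rev["TE"].or_value, rel=1e-9)

    def test_unified_strategy_feeds_approximate_forms(self, cont_sample):
        est = estimate_effects(cont_sample, DesignSpec("unified"), method="approximate")
        for eff in ("NDE", "NIE", "TE"):
            assert est[eff].or_value > 0
            lo, hi = est[eff].ci_delta
            assert lo <= est[eff].or_value <= hi
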