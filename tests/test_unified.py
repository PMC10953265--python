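"""Joint prospective likelihood: building blocks and maximisation."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

from ccmediate import (
    DesignSpec,
    MediationDataset,
    MediatorParams,
    OutcomeParams,
    case_mediator_density,
    fit_mediator_model,
    fit_unified,
    marginal_odds,
    theta_odds,
    unified_loglik,
)
from ccmediate.simulate import ScenarioSpec, draw_case_control_sample
from ccmediate.unified import _pack, log_marginal_odds

from conftest import random_params


def _params(theta, beta, sigma=None):
    return (
        OutcomeParams.from_vector(np.asarray(theta, float)),
        MediatorParams.from_vector(np.asarray(beta, float), sigma=sigma),
    )


class TestThetaOdds:
    @pytest.mark.parametrize(
        "theta, a, m, c, expected",
        [
            ((0, 0, 0, 0, 0), 1, 2.0, [3.0], 1.0),
            ((-1, 0, 0, 0, 0), 0, 0.5, [1.0], np.exp(-1)),
            ((-2, 0.5, 0.3, 0.1, 0.2), 1, 2.0, [1.0], np.exp(-0.5)),
        ],
    )
    def test_known_values(self, theta, a, m, c, expected):
        outcome, _ = _params(theta, [0, 0, 0])
        assert theta_odds(outcome, a, m, np.array([c]))[0] == pytest.approx(expected)


class TestMarginalOdds:
    def test_mediator_free_outcome_ignores_mediator_model(self):
        outcome, med = _params([-1.0, 0.4, 0.0, 0.0, 0.3], [2.0, -1.0, 5.0], sigma=0.7)
        got = marginal_odds(outcome, med, 1, np.array([[0.5]]), "continuous")[0]
        assert got == pytest.approx(np.exp(-1.0 + 0.4 + 0.15))

    def test_degenerate_binary_mediator(self):
        # expit(beta linear predictor) -> 0: only the m = 0 term survives
        outcome, med = _params([-1.0, 0.4, 0.8, 0.2, 0.3], [-40.0, 0.0, 0.0])
        got = marginal_odds(outcome, med, 1, np.array([[0.5]]), "binary")[0]
        assert got == pytest.approx(np.exp(-1.0 + 0.4 + 0.15), rel=1e-8)

    def test_continuous_closed_form_matches_quadrature(self):
        """The Gaussian-MGF closed form equals the explicit integral of the
        conditional odds against the control mediator density."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            outcome, med = random_params(rng, "continuous")
            a, c = 1.0, np.array([[0.3]])
            mu = float(med.mean(np.array([a]), c)[0])

            def integrand(m):
                return theta_odds(outcome, a, m, c)[0] * norm.pdf(m, mu, med.sigma)

            oracle, _ = quad(integrand, mu - 12 * med.sigma, mu + 12 * med.sigma)
            got = marginal_odds(outcome, med, a, c, "continuous")[0]
            assert got == pytest.approx(oracle, rel=1e-7)

    def test_binary_sum_matches_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            outcome, med = random_params(rng, "binary")
            a, c = 0.0, np.array([[-0.4]])
            q1 = expit(float(med.mean(np.array([a]), c)[0]))
            oracle = (
                theta_odds(outcome, a, 1.0, c)[0] * q1
                + theta_odds(outcome, a, 0.0, c)[0] * (1 - q1)
            )
            got = marginal_odds(outcome, med, a, c, "binary")[0]
            assert got == pytest.approx(oracle, rel=1e-10)


class TestCaseMediatorDensity:
    def test_reduces_to_control_density_without_mediator_effect(self):
        outcome, med = _params([-1.0, 0.4, 0.0, 0.0, 0.3], [0.2, 0.5, -0.3], sigma=0.6)
        m = np.array([0.1, 1.3, -2.0])
        got = case_mediator_density(outcome, med, m, 1.0, np.array([[0.5]]), "continuous")
        mu = float(med.mean(np.array([1.0]), np.array([[0.5]]))[0])
        np.testing.assert_allclose(got, norm.pdf(m, mu, med.sigma), rtol=1e-10)

    def test_binary_masses_sum_to_one(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            outcome, med = random_params(rng, "binary")
            c = np.array([[rng.normal()]])
            total = sum(
                case_mediator_density(outcome, med, float(m), 1.0, c, "binary")[0]
                for m in (0, 1)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_continuous_density_integrates_to_one(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            outcome, med = random_params(rng, "continuous", scale=0.5)
            c = np.array([[0.2]])

            def dens(m):
                return case_mediator_density(outcome, med, m, 0.0, c, "continuous")[0]

            total, _ = quad(dens, -30, 30, limit=200)
            assert total == pytest.approx(1.0, abs=1e-6)


def _brute_force_loglik(outcome, med, data):
    """Independent reconstruction of log P(Y=y, M=m | A, C) for a binary
    mediator: P(M=m | Y=y, a, c) * P(Y=y | a, c), with the case mediator
    law and the outcome law both derived from explicit enumeration of the
    conditional odds over m in {0, 1}."""
    total = 0.0
    for y, a, m, c in zip(data.y, data.a, data.m, data.c):
        c_row = c.reshape(1, -1)
        q1 = expit(float(med.mean(np.array([a]), c_row)[0]))
        p_m_given_control = {1.0: q1, 0.0: 1.0 - q1}
        odds_by_m = {
            mv: float(theta_odds(outcome, a, mv, c_row)[0]) for mv in (0.0, 1.0)
        }
        theta_ac = sum(odds_by_m[mv] * p_m_given_control[mv] for mv in (0.0, 1.0))
        p_y = theta_ac**y / (1.0 + theta_ac)
        if y == 1.0:
            p_m = odds_by_m[m] * p_m_given_control[m] / theta_ac
        else:
            p_m = p_m_given_control[m]
        total += np.log(p_m * p_y)
    return total


class TestUnifiedLoglik:
    def test_symmetric_null_single_record(self):
        outcome, med = _params([0, 0, 0, 0], [0, 0])
        for y in (0.0, 1.0):
            d = MediationDataset(
                y=[y], a=[1.0], m=[1.0], c=np.zeros((1, 0)), mediator_type="binary"
            )
            got = unified_loglik(outcome, med, d)
            assert got == pytest.approx(np.log(0.5) - np.log(2.0))

    def test_controls_only_limit(self):
        """With vanishing outcome odds the outcome factor contributes
        nothing and the likelihood reduces to the mediator part."""
        rng = np.random.default_rng(14)
        n = 50
        d = MediationDataset(
            y=np.zeros(n),
            a=rng.binomial(1, 0.5, n).astype(float),
            m=rng.normal(0, 1, n),
            c=rng.normal(0, 1, (n, 1)),
        )
        outcome, med = _params([-40.0, 0.1, 0.2, 0.0, 0.1], [0.3, 0.5, -0.2], sigma=0.8)
        got = unified_loglik(outcome, med, d)
        mu = med.mean(d.a, d.c)
        mediator_ll = norm.logpdf(d.m, mu, med.sigma).sum()
        assert got == pytest.approx(mediator_ll, abs=1e-10)

    def test_matches_brute_force_factorisation(self):
        rng = np.random.default_rng(15)
        n = 30
        d = MediationDataset(
            y=rng.binomial(1, 0.4, n).astype(float),
            a=rng.binomial(1, 0.5, n).astype(float),
            m=rng.binomial(1, 0.5, n).astype(float),
            c=rng.normal(0, 1, (n, 2)),
            mediator_type="binary",
        )
        for _ in range(20):
            outcome, med = random_params(rng, "binary", p=2)
            got = unified_loglik(outcome, med, d)
            assert got == pytest.approx(_brute_force_loglik(outcome, med, d), abs=1e-10)


class TestFitUnified:
    @pytest.mark.parametrize("sample_fixture", ["cont_sample", "bin_sample"])
    def test_score_vanishes_at_optimum(self, sample_fixture, request):
        data = request.getfixturevalue(sample_fixture)
        res = fit_unified(data)
        assert res.converged

        x_opt = _pack(res.outcome, res.mediator, data.mediator_type)

        def ll(x):
            from ccmediate.unified import _unpack

            theta, beta, sigma = _unpack(x, data.n_covariates, data.mediator_type)
            return unified_loglik(
                OutcomeParams.from_vector(theta),
                MediatorParams.from_vector(beta, sigma=sigma),
                data,
            )

        # central differences: forward-difference truncation error (~h f'')
        # would swamp the score at likelihood curvatures of order n
        grad = np.empty_like(x_opt)
        for i in range(len(x_opt)):
            h = 1e-6 * (1.0 + abs(x_opt[i]))
            xp, xm = x_opt.copy(), x_opt.copy()
            xp[i] += h
            xm[i] -= h
            grad[i] = (ll(xp) - ll(xm)) / (2.0 * h)
        assert np.abs(grad).max() < 1e-4

    def test_ascent_over_starting_point(self, cont_sample):
        from ccmediate.fitting import fit_outcome_model

        res = fit_unified(cont_sample)
        start_out = fit_outcome_model(cont_sample)
        start_med = fit_mediator_model(cont_sample, DesignSpec("controls_only"))
        assert res.loglik >= unified_loglik(start_out, start_med, cont_sample)
        assert np.isfinite(res.loglik)
        assert res.joint_cov.shape == (10, 10)
        assert np.all(np.diag(res.joint_cov) > 0)

    def test_mediator_agrees_with_controls_only_under_null_outcome(self):
        """When the mediator does not enter the outcome model, the joint fit
        and the controls-only fit target the same mediator coefficients."""
        spec = ScenarioSpec(
            name="null-link",
            mediator_type="continuous",
            beta=(1.0, 0.4, 0.2, -0.1),
            theta=(-4.0, 0.4, 0.0, 0.0, 0.2, -0.2),
            sigma=0.5,
        )
        data = draw_case_control_sample(spec, 1200, seed=33).data
        res = fit_unified(data)
        ctrl = fit_mediator_model(data, DesignSpec("controls_only"))
        np.testing.assert_allclose(res.mediator.vector, ctrl.vector, atol=0.1)
        assert res.mediator.sigma == pytest.approx(ctrl.sigma, abs=0.05)
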