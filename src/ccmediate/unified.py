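"""Joint prospective likelihood for (M, Y) under case-control sampling.

The joint law P(Y=y, M=m | A, C) factors into the mediator law among
controls, the conditional outcome odds

    theta(a, m, c) = exp(theta0 + theta1*a + theta2*m + theta3*a*m + theta4'c),

and the mediator-marginalised odds theta(a, c) obtained by integrating
theta(a, m, c) against P(M = m | Y = 0, a, c). Each record contributes

    log P(M=m_i | Y=0, a_i, c_i) + y_i * log theta(a_i, m_i, c_i)
        - log(1 + theta(a_i, c_i))

to the log-likelihood. Maximising it estimates the outcome and mediator
coefficients jointly, accounts for the sampling design through the control-
stratum mediator model (a rare-outcome approximation), and requires no
user-supplied outcome prevalence.

All odds are handled on the log scale; for a Gaussian mediator the
marginalised odds have the closed moment-generating-function form
``exp(theta0 + theta1*a + theta4'c) * exp((theta2 + theta3*a)*mu +
(theta2 + theta3*a)^2 * sigma^2 / 2)`` with ``mu = beta0 + beta1*a +
beta2'c``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .dataset import BINARY, CONTINUOUS, DesignSpec, MediationDataset
from .exceptions import ConvergenceError, DataError, NumericalError
from .fitting import (
    MediatorParams,
    OutcomeParams,
    fit_mediator_model,
    fit_outcome_model,
)

_SCORE_TOL = 1e-4
_HESS_STEP = 1e-5


@dataclass
class UnifiedFitResult:
    """Jointly estimated outcome and mediator coefficients."""

    outcome: OutcomeParams
    mediator: MediatorParams
    loglik: float
    converged: bool
    n_iter: int
    joint_cov: Optional[np.ndarray] = None  # over (theta, beta), log-sigma marginalised out
    full_cov: Optional[np.ndarray] = None  # over (theta, beta, log sigma)


# ---------------------------------------------------------------------------
# likelihood building blocks


def log_theta_odds(outcome: OutcomeParams, a, m, c) -> np.ndarray:
    """log of the conditional outcome odds theta(a, m, c)."""
    return outcome.linear_predictor(a, m, c)


def theta_odds(outcome: OutcomeParams, a, m, c) -> np.ndarray:
    """Conditional outcome odds exp(theta0 + theta1 a + theta2 m + theta3 a m + theta4'c)."""
    return np.exp(log_theta_odds(outcome, a, m, c))


def log_marginal_odds(
    outcome: OutcomeParams, mediator: MediatorParams, a, c, mediator_type: str
) -> np.ndarray:
    """log theta(a, c): outcome odds with the mediator integrated out.

    The integral runs against the control-stratum mediator law. Binary
    mediator: two-term sum. Continuous mediator: Gaussian MGF closed form.
    """
    a = np.asarray(a, dtype=float)
    c = np.atleast_2d(np.asarray(c, dtype=float))
    mu = mediator.mean(a, c)
    base = outcome.theta0 + outcome.theta1 * a + c @ outcome.theta4
    slope = outcome.theta2 + outcome.theta3 * a
    if mediator_type == CONTINUOUS:
        if mediator.sigma is None:
            raise DataError("continuous marginal odds need the mediator sigma")
        out = base + slope * mu + 0.5 * slope**2 * mediator.sigma**2
    elif mediator_type == BINARY:
        # logsumexp over m in {0, 1} with Bernoulli(expit(mu)) masses
        out = np.logaddexp(base + slope + log_expit(mu), base + log_expit(-mu))
    else:
        raise DataError(f"unknown mediator_type {mediator_type!r}")
    if not np.all(np.isfinite(out)):
        raise NumericalError(
            "marginal outcome odds overflowed; consider rescaling the mediator/covariates"
        )
    return out


def marginal_odds(
    outcome: OutcomeParams, mediator: MediatorParams, a, c, mediator_type: str
) -> np.ndarray:
    res = np.exp(log_marginal_odds(outcome, mediator, a, c, mediator_type))
    if not np.all(np.isfinite(res)):
        raise NumericalError("marginal odds overflowed on the natural scale")
    return res


def _log_control_mediator_density(
    mediator: MediatorParams, m, a, c, mediator_type: str
) -> np.ndarray:
    """log P(M=m | Y=0, A=a, C=c): Gaussian density or Bernoulli mass."""
    m = np.asarray(m, dtype=float)
    mu = mediator.mean(a, c)
    if mediator_type == CONTINUOUS:
        s2 = mediator.sigma**2
        return -0.5 * np.log(2.0 * np.pi * s2) - (m - mu) ** 2 / (2.0 * s2)
    return m * log_expit(mu) + (1.0 - m) * log_expit(-mu)


def case_mediator_density(
    outcome: OutcomeParams, mediator: MediatorParams, m, a, c, mediator_type: str
) -> np.ndarray:
    """Mediator law among the cases, theta(a,m,c) P(M=m|Y=0,a,c) / theta(a,c).

    Sums (binary) or integrates (continuous) to one over m.
    """
    log_den = log_marginal_odds(outcome, mediator, a, c, mediator_type)
    log_num = log_theta_odds(outcome, np.asarray(a, float), m, c) + _log_control_mediator_density(
        mediator, m, a, c, mediator_type
    )
    return np.exp(log_num - log_den)


def unified_loglik(
    outcome: OutcomeParams, mediator: MediatorParams, data: MediationDataset
) -> float:
    """Log of the joint prospective likelihood over all records."""
    lp_med = _log_control_mediator_density(
        mediator, data.m, data.a, data.c, data.mediator_type
    )
    log_odds = log_theta_odds(outcome, data.a, data.m, data.c)
    log_marg = log_marginal_odds(outcome, mediator, data.a, data.c, data.mediator_type)
    terms = lp_med + data.y * log_odds - np.logaddexp(0.0, log_marg)
    if not np.all(np.isfinite(terms)):
        bad = int(np.flatnonzero(~np.isfinite(terms))[0])
        raise NumericalError(f"non-finite log-likelihood contribution at record {bad}")
    return float(terms.sum())


# ---------------------------------------------------------------------------
# maximisation


def _unpack(x: np.ndarray, p: int, mediator_type: str):
    n_theta = 4 + p
    n_beta = 2 + p
    theta = x[:n_theta]
    beta = x[n_theta : n_theta + n_beta]
    sigma = float(np.exp(x[-1])) if mediator_type == CONTINUOUS else None
    return theta, beta, sigma


def _pack(outcome: OutcomeParams, mediator: MediatorParams, mediator_type: str) -> np.ndarray:
    parts = [outcome.vector, mediator.vector]
    if mediator_type == CONTINUOUS:
        parts.append(np.array([np.log(mediator.sigma)]))
    return np.concatenate(parts)


def _negloglik_and_grad(x: np.ndarray, data: MediationDataset):
    """Negative unified log-likelihood and its analytic gradient.

    Parametrised by (theta, beta, log sigma) so the maximisation is
    unconstrained.
    """
    p = data.n_covariates
    theta, beta, sigma = _unpack(x, p, data.mediator_type)
    a, m, c, y = data.a, data.m, data.c, data.y
    x_out = np.column_stack([np.ones(data.n), a, m, a * m, c])
    x_med = np.column_stack([np.ones(data.n), a, c])
    eta = x_out @ theta  # log theta(a, m, c)
    mu = x_med @ beta
    base = theta[0] + theta[1] * a + (c @ theta[4:] if p else 0.0)
    slope = theta[2] + theta[3] * a

    grad_theta = (y[:, None] * x_out).sum(axis=0)
    if data.mediator_type == CONTINUOUS:
        s2 = sigma**2
        lam = base + slope * mu + 0.5 * slope**2 * s2
        s = expit(lam)  # d softplus / d lam
        resid = m - mu
        ll = (
            -0.5 * data.n * np.log(2.0 * np.pi * s2)
            - (resid**2).sum() / (2.0 * s2)
            + (y * eta).sum()
            - np.logaddexp(0.0, lam).sum()
        )
        # d lam / d theta
        dl_dtheta = np.column_stack(
            [np.ones(data.n), a, mu + slope * s2, a * (mu + slope * s2), c]
        )
        grad_theta -= (s[:, None] * dl_dtheta).sum(axis=0)
        grad_beta = ((resid / s2 - s * slope)[:, None] * x_med).sum(axis=0)
        grad_logsigma = float(
            (-1.0 + resid**2 / s2 - s * slope**2 * s2).sum()
        )
        grad = np.concatenate([grad_theta, grad_beta, [grad_logsigma]])
    else:
        eta1 = base + slope  # log theta at m = 1
        eta0 = base
        lam = np.logaddexp(eta1 + log_expit(mu), eta0 + log_expit(-mu))
        s = expit(lam)
        q1 = expit(mu)
        # posterior weight of m = 1 inside theta(a, c)
        w1 = np.exp(eta1 + log_expit(mu) - lam)
        ll = (
            (m * log_expit(mu) + (1.0 - m) * log_expit(-mu)).sum()
            + (y * eta).sum()
            - np.logaddexp(0.0, lam).sum()
        )
        dl_dtheta = np.column_stack([np.ones(data.n), a, w1, a * w1, c])
        grad_theta -= (s[:, None] * dl_dtheta).sum(axis=0)
        dlam_dmu = w1 * (1.0 - q1) - (1.0 - w1) * q1
        grad_beta = (((m - q1) - s * dlam_dmu)[:, None] * x_med).sum(axis=0)
        grad = np.concatenate([grad_theta, grad_beta])
    if not np.isfinite(ll):
        return np.inf, np.zeros_like(x)
    return -ll, -grad


def _observed_information(x: np.ndarray, data: MediationDataset) -> np.ndarray:
    """Hessian of the negative log-likelihood by central differences of the
    analytic gradient, step 1e-5 * (1 + |coef|)."""
    k = len(x)
    hess = np.empty((k, k))
    for i in range(k):
        h = _HESS_STEP * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        _, gp = _negloglik_and_grad(xp, data)
        _, gm = _negloglik_and_grad(xm, data)
        hess[:, i] = (gp - gm) / (2.0 * h)
    return 0.5 * (hess + hess.T)


def fit_unified(data: MediationDataset) -> UnifiedFitResult:
    """Maximise the joint prospective likelihood over (theta, beta[, sigma]).

    Starts from the controls-only mediator fit and the naive outcome fit
    (both consistent under the rare-outcome approximation), runs BFGS on the
    unconstrained parametrisation (sigma on the log scale), and returns the
    joint inverse observed information as the coefficient covariance.
    """
    if data.n_cases == 0 or data.n_controls == 0:
        raise DataError("unified fit needs both cases and controls")
    start_outcome = fit_outcome_model(data)
    start_mediator = fit_mediator_model(data, DesignSpec(strategy="controls_only"))
    x0 = _pack(start_outcome, start_mediator, data.mediator_type)

    best = None
    for attempt, jitter in enumerate((0.0, 0.05)):
        res = minimize(
            _negloglik_and_grad,
            x0 + jitter,
            args=(data,),
            jac=True,
            method="BFGS",
            options={"gtol": 5e-6, "maxiter": 1000},
        )
        _, grad = _negloglik_and_grad(res.x, data)
        score_ok = np.abs(grad).max() < _SCORE_TOL
        if best is None or res.fun < best[0].fun:
            best = (res, score_ok)
        if score_ok:
            break
    res, score_ok = best
    if not score_ok:
        raise ConvergenceError(
            f"unified likelihood maximisation stalled (max |score| "
            f"{np.abs(grad).max():.3g})",
            state=res.x,
        )
    p = data.n_covariates
    theta, beta, sigma = _unpack(res.x, p, data.mediator_type)
    info = _observed_information(res.x, data)
    try:
        full_cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular observed information: {exc}", state=res.x) from exc
    n_coef = len(theta) + len(beta)
    joint_cov = full_cov[:n_coef, :n_coef]
    n_theta = len(theta)
    outcome = OutcomeParams.from_vector(theta, cov=joint_cov[:n_theta, :n_theta])
    mediator = MediatorParams.from_vector(
        beta, sigma=sigma, cov=joint_cov[n_theta:, n_theta:]
    )
    return UnifiedFitResult(
        outcome=outcome,
        mediator=mediator,
        loglik=-float(res.fun),
        converged=True,
        n_iter=int(res.nit),
        joint_cov=joint_cov,
        full_cov=full_cov,
    )
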