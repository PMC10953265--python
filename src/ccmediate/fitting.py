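"""Design weights and (weighted) outcome / mediator regression fits.

The outcome model is the logistic regression

    logit P(Y=1 | A=a, M=m, C=c) = theta0 + theta1*a + theta2*m
                                   + theta3*a*m + theta4'c

and the mediator model is either the Gaussian linear model
``E(M | A, C) = beta0 + beta1*a + beta2'c`` with residual SD sigma, or the
analogous logistic model for a binary mediator.

Under case-control sampling the naive fits of any model involving the outcome
distribution are biased; the strategies here either refit on controls only,
reweight by inverse sampling probabilities, or (see :mod:`ccmediate.unified`)
maximise a joint prospective likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy.linalg import block_diag
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .dataset import BINARY, CONTINUOUS, DesignSpec, MediationDataset
from .exceptions import ConvergenceError, DataError, DesignError

# IRLS controls for the weighted GLM fits
_GLM_TOL = 1e-8
_GLM_MAXITER = 100


@dataclass
class OutcomeParams:
    """Coefficients of the outcome logistic model, on the log-odds scale."""

    theta0: float
    theta1: float
    theta2: float
    theta3: float
    theta4: np.ndarray
    cov: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.theta4 = np.atleast_1d(np.asarray(self.theta4, dtype=float))
        if self.theta4.ndim == 0:
            self.theta4 = self.theta4.reshape(1)
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)

    @property
    def vector(self) -> np.ndarray:
        """(theta0, theta1, theta2, theta3, theta4...) as one array."""
        return np.concatenate(([self.theta0, self.theta1, self.theta2, self.theta3], self.theta4))

    @classmethod
    def from_vector(cls, vec: np.ndarray, cov: Optional[np.ndarray] = None) -> "OutcomeParams":
        vec = np.asarray(vec, dtype=float)
        return cls(vec[0], vec[1], vec[2], vec[3], vec[4:], cov)

    @property
    def n_params(self) -> int:
        return 4 + len(self.theta4)

    def linear_predictor(self, a, m, c) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        m = np.asarray(m, dtype=float)
        c = np.atleast_2d(np.asarray(c, dtype=float))
        if c.shape[-1] != len(self.theta4):
            raise DataError(
                f"covariate dimension {c.shape[-1]} does not match theta4 length {len(self.theta4)}"
            )
        return (
            self.theta0
            + self.theta1 * a
            + self.theta2 * m
            + self.theta3 * a * m
            + c @ self.theta4
        )


@dataclass
class MediatorParams:
    """Coefficients of the mediator model.

    For a continuous mediator these are the linear-model coefficients plus the
    residual SD ``sigma``; for a binary mediator they are logistic
    coefficients and ``sigma`` is ``None``.
    """

    beta0: float
    beta1: float
    beta2: np.ndarray
    sigma: Optional[float] = None
    cov: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.beta2 = np.atleast_1d(np.asarray(self.beta2, dtype=float))
        if self.sigma is not None and self.sigma <= 0:
            raise DataError(f"sigma must be positive, got {self.sigma}")
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate(([self.beta0, self.beta1], self.beta2))

    @classmethod
    def from_vector(cls, vec, sigma=None, cov=None) -> "MediatorParams":
        vec = np.asarray(vec, dtype=float)
        return cls(vec[0], vec[1], vec[2:], sigma, cov)

    @property
    def n_params(self) -> int:
        return 2 + len(self.beta2)

    def mean(self, a, c) -> np.ndarray:
        """Linear predictor beta0 + beta1*a + beta2'c (logit scale if binary)."""
        a = np.asarray(a, dtype=float)
        c = np.atleast_2d(np.asarray(c, dtype=float))
        if c.shape[-1] != len(self.beta2):
            raise DataError(
                f"covariate dimension {c.shape[-1]} does not match beta2 length {len(self.beta2)}"
            )
        return self.beta0 + self.beta1 * a + c @ self.beta2


@dataclass
class FittedModels:
    """Outcome and mediator fits plus their joint coefficient covariance.

    ``joint_cov`` is ordered (theta, beta). When the two models were fitted
    on separate (or separately weighted) likelihoods the cross-blocks are
    zero; under the unified likelihood it is the inverse observed information
    of the joint fit.
    """

    outcome: OutcomeParams
    mediator: MediatorParams
    joint_cov: Optional[np.ndarray]
    strategy_used: str
    mediator_type: str = CONTINUOUS

    @property
    def coef_vector(self) -> np.ndarray:
        return np.concatenate((self.outcome.vector, self.mediator.vector))


# ---------------------------------------------------------------------------
# weights


def compute_weights(data: MediationDataset, pi: float) -> np.ndarray:
    """Inverse-probability design weights: pi/p for cases, (1-pi)/(1-p) for controls.

    ``p`` is the sample case fraction. Case weights sum to n*pi and control
    weights to n*(1-pi) by construction.
    """
    if not (0.0 < pi < 1.0):
        raise DesignError(f"pi must lie in (0, 1), got {pi}")
    p = data.case_fraction
    if p in (0.0, 1.0):
        raise DesignError(
            f"weights undefined: sample has {data.n_cases} cases and "
            f"{data.n_controls} controls"
        )
    return np.where(data.y == 1, pi / p, (1.0 - pi) / (1.0 - p))


# ---------------------------------------------------------------------------
# model fits


def _design_matrix_outcome(data: MediationDataset) -> np.ndarray:
    return np.column_stack(
        [np.ones(data.n), data.a, data.m, data.a * data.m, data.c]
    )


def _design_matrix_mediator(data: MediationDataset) -> np.ndarray:
    return np.column_stack([np.ones(data.n), data.a, data.c])


def _resolve_cov_type(cov_type: str, w: np.ndarray) -> str:
    """'auto' = design sandwich for non-unit weights, model-based otherwise.

    Under unequal (IPW) weights the inverse information of the weighted
    pseudo-likelihood badly overstates the variance — it treats the weighted
    sample as a rare-outcome cohort — whereas the estimating-equation
    sandwich A^-1 B A^-1 with B built from squared-weight scores is
    calibrated against the case-control sampling.
    """
    if cov_type not in ("auto", "model", "sandwich"):
        raise DesignError(f"cov_type must be auto/model/sandwich, got {cov_type!r}")
    if cov_type == "auto":
        return "sandwich" if np.ptp(w) > 0 else "model"
    return cov_type


def _sandwich(X: np.ndarray, bread_weights: np.ndarray, score_resid: np.ndarray,
              w: np.ndarray) -> np.ndarray:
    """A^-1 B A^-1 with A = X' diag(bread_weights) X and per-record scores
    w_i * score_resid_i * x_i."""
    a_inv = np.linalg.inv((X * bread_weights[:, None]).T @ X)
    meat = (X * ((w * score_resid) ** 2)[:, None]).T @ X
    return a_inv @ meat @ a_inv


def _weighted_logit(y, X, w, cov_type="auto") -> tuple[np.ndarray, np.ndarray]:
    """Weighted-ML logistic fit; returns (coef, cov)."""
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.simplefilter("error", category=PerfectSeparationWarning)
        try:
            res = model.fit(maxiter=_GLM_MAXITER, tol=_GLM_TOL)
        except (
            PerfectSeparationError,
            PerfectSeparationWarning,
            RuntimeWarning,
            np.linalg.LinAlgError,
        ) as exc:
            raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.converged:
        raise ConvergenceError("logistic fit did not converge", state=res.params)
    if np.abs(res.params).max() > 50:
        raise ConvergenceError(
            "logistic fit diverged (|coef| > 50), likely separation",
            state=res.params,
        )
    coef = np.asarray(res.params)
    if _resolve_cov_type(cov_type, w) == "model":
        cov = np.asarray(res.cov_params())
    else:
        from scipy.special import expit

        p = expit(X @ coef)
        cov = _sandwich(X, w * p * (1.0 - p), y - p, w)
    return coef, cov


def fit_outcome_model(
    data: MediationDataset, weights: Optional[np.ndarray] = None, cov_type: str = "auto"
) -> OutcomeParams:
    """Weighted-ML fit of the outcome logistic model (unit weights = plain fit)."""
    w = np.ones(data.n) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != data.n or (w <= 0).any():
        raise DesignError("weights must be strictly positive, one per record")
    coef, cov = _weighted_logit(data.y, _design_matrix_outcome(data), w, cov_type)
    return OutcomeParams.from_vector(coef, cov)


def fit_mediator_model(
    data: MediationDataset, spec: DesignSpec, cov_type: str = "auto"
) -> MediatorParams:
    """Fit the mediator model under the given case-control strategy.

    naive: all records, unit weights. controls_only: records with y = 0,
    unit weights. ipw: all records, design weights from ``spec.pi``.
    """
    if spec.strategy == "naive":
        sub, w = data, np.ones(data.n)
    elif spec.strategy == "controls_only":
        if data.n_controls == 0:
            raise DesignError("controls-only fit impossible: no controls in data")
        sub = data.subset(data.y == 0)
        w = np.ones(sub.n)
    elif spec.strategy == "ipw":
        if spec.pi is None:
            raise DesignError("ipw mediator fit requires spec.pi")
        sub, w = data, compute_weights(data, spec.pi)
    else:
        raise DesignError(
            f"fit_mediator_model handles naive/controls_only/ipw, not {spec.strategy!r}"
        )
    X = _design_matrix_mediator(sub)
    if data.mediator_type == BINARY:
        coef, cov = _weighted_logit(sub.m, X, w, cov_type)
        return MediatorParams.from_vector(coef, sigma=None, cov=cov)
    # continuous: weighted least squares, sigma^2 = weighted RSS / (sum w - k)
    res = sm.WLS(sub.m, X, weights=w).fit()
    coef = np.asarray(res.params)
    resid = sub.m - X @ coef
    k = X.shape[1]
    denom = w.sum() - k
    if denom <= 0:
        raise DataError("too few records to estimate the residual SD")
    sigma2 = float((w * resid**2).sum() / denom)
    if sigma2 <= 0:
        raise ConvergenceError("degenerate mediator fit: zero residual variance")
    if _resolve_cov_type(cov_type, w) == "model":
        cov = sigma2 * np.linalg.inv(X.T @ (w[:, None] * X))
    else:
        cov = _sandwich(X, w, resid, w)
    return MediatorParams.from_vector(coef, sigma=float(np.sqrt(sigma2)), cov=cov)


def fit_models(
    data: MediationDataset, spec: DesignSpec, cov_type: str = "auto"
) -> FittedModels:
    """Fit outcome and mediator models under one strategy.

    naive / controls_only fit the outcome model on the full sample with unit
    weights; ipw weights both models; unified delegates to the joint
    prospective likelihood. Except for unified, ``joint_cov`` is assembled
    block-diagonally from the two separate fits.
    """
    if spec.strategy == "unified":
        from .unified import fit_unified

        res = fit_unified(data)
        return FittedModels(
            outcome=res.outcome,
            mediator=res.mediator,
            joint_cov=res.joint_cov,
            strategy_used="unified",
            mediator_type=data.mediator_type,
        )
    if spec.strategy in ("naive", "controls_only"):
        outcome = fit_outcome_model(data, cov_type=cov_type)
    elif spec.strategy == "ipw":
        outcome = fit_outcome_model(
            data, compute_weights(data, spec.pi), cov_type=cov_type
        )
    else:  # pragma: no cover - DesignSpec already validates
        raise DesignError(f"unknown strategy {spec.strategy!r}")
    mediator = fit_mediator_model(data, spec, cov_type=cov_type)
    joint_cov = block_diag(outcome.cov, mediator.cov)
    return FittedModels(
        outcome=outcome,
        mediator=mediator,
        joint_cov=joint_cov,
        strategy_used=spec.strategy,
        mediator_type=data.mediator_type,
    )
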