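"""Approximate and exact natural direct/indirect/total effect odds ratios.

Natural effects decompose the total effect of a binary exposure on a binary
outcome through a mediator. On the odds-ratio scale, with nested
counterfactual probabilities P(a, a*) = P(Y(a, M(a*)) = 1 | C = c),

    OR_NDE = odds(P(a, a*)) / odds(P(a*, a*))
    OR_NIE = odds(P(a, a))  / odds(P(a, a*))
    OR_TE  = OR_NDE * OR_NIE

The *approximate* estimators invoke the rare-outcome assumption to obtain
closed forms in the fitted coefficients; the *exact* estimators evaluate the
counterfactual probabilities themselves — a two-term closed form for a binary
mediator, Gauss-Hermite quadrature of the logistic-normal integral for a
continuous one — and plug them into the odds ratios above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit

from .dataset import BINARY, CONTINUOUS, DesignSpec, MediationDataset
from .exceptions import (
    DataError,
    DegenerateProbabilityError,
    DesignError,
    NumericalError,
)
from .fitting import (
    FittedModels,
    MediatorParams,
    OutcomeParams,
    compute_weights,
    fit_models,
)

EFFECTS = ("NDE", "NIE", "TE")
METHODS = ("approximate", "exact")

_QUAD_NODES = 64
_QUAD_TOL = 1e-8
_PROB_EPS = 1e-12


@lru_cache(maxsize=8)
def _hermgauss_cached(n_nodes: int):
    return hermgauss(n_nodes)


@dataclass(frozen=True)
class ContrastSpec:
    """Exposure contrast a vs a* at fixed covariate values c."""

    a: float = 1.0
    a_star: float = 0.0
    c: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "c", np.atleast_1d(np.asarray(self.c, dtype=float)))
        if self.a == self.a_star:
            raise DataError("contrast requires a != a_star")

    @property
    def is_unit(self) -> bool:
        return self.a == 1.0 and self.a_star == 0.0


@dataclass
class EffectEstimate:
    """One natural-effect odds ratio with optional interval estimates."""

    effect: str
    or_value: float
    method: str
    log_se: Optional[float] = None
    ci_delta: Optional[tuple] = None
    ci_boot: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.or_value <= 0:
            raise DataError(f"odds ratio must be positive, got {self.or_value}")


def _check_dims(outcome: OutcomeParams, mediator: MediatorParams, contrast: ContrastSpec):
    if len(contrast.c) != len(outcome.theta4) or len(contrast.c) != len(mediator.beta2):
        raise DataError(
            f"conditioning covariate length {len(contrast.c)} does not match "
            f"fitted dimensions ({len(outcome.theta4)}, {len(mediator.beta2)})"
        )


# ---------------------------------------------------------------------------
# approximate (rare-outcome) closed forms, binary 0/1 exposure only


def log_approx_nde(
    outcome: OutcomeParams, mediator: MediatorParams, contrast: ContrastSpec,
    mediator_type: str,
) -> float:
    _check_dims(outcome, mediator, contrast)
    if not contrast.is_unit:
        raise DesignError("approximate closed forms are printed for the 1-vs-0 contrast only")
    b2c = float(contrast.c @ mediator.beta2)
    t = outcome
    if mediator_type == CONTINUOUS:
        s2 = mediator.sigma**2
        return t.theta1 + t.theta3 * (mediator.beta0 + b2c + t.theta2 * s2) + 0.5 * t.theta3**2 * s2
    num = np.logaddexp(0.0, t.theta2 + t.theta3 + mediator.beta0 + b2c)
    den = np.logaddexp(0.0, t.theta2 + mediator.beta0 + b2c)
    return float(t.theta1 + num - den)


def log_approx_nie(
    outcome: OutcomeParams, mediator: MediatorParams, contrast: ContrastSpec,
    mediator_type: str,
) -> float:
    _check_dims(outcome, mediator, contrast)
    if not contrast.is_unit:
        raise DesignError("approximate closed forms are printed for the 1-vs-0 contrast only")
    b2c = float(contrast.c @ mediator.beta2)
    t = outcome
    b = mediator
    if mediator_type == CONTINUOUS:
        return b.beta1 * (t.theta2 + t.theta3)
    # four-term ratio of 1+exp(...) factors
    return float(
        np.logaddexp(0.0, b.beta0 + b2c)
        - np.logaddexp(0.0, b.beta0 + b.beta1 + b2c)
        + np.logaddexp(0.0, t.theta2 + t.theta3 + b.beta0 + b.beta1 + b2c)
        - np.logaddexp(0.0, t.theta2 + t.theta3 + b.beta0 + b2c)
    )


def approx_nde(models: FittedModels, contrast: ContrastSpec, mediator_type=None) -> float:
    mt = mediator_type or models.mediator_type
    return float(np.exp(log_approx_nde(models.outcome, models.mediator, contrast, mt)))


def approx_nie(models: FittedModels, contrast: ContrastSpec, mediator_type=None) -> float:
    mt = mediator_type or models.mediator_type
    return float(np.exp(log_approx_nie(models.outcome, models.mediator, contrast, mt)))


# ---------------------------------------------------------------------------
# exact counterfactual probabilities


def _counterfactual_prob(
    outcome: OutcomeParams, mediator: MediatorParams, a: float, a_star: float,
    c: np.ndarray, mediator_type: str,
) -> float:
    c_row = c.reshape(1, -1)
    mu_star = float(mediator.mean(np.array([a_star]), c_row)[0])
    if mediator_type == BINARY:
        p_m1 = expit(mu_star)
        lp1 = outcome.linear_predictor(np.array([a]), np.array([1.0]), c_row)[0]
        lp0 = outcome.linear_predictor(np.array([a]), np.array([0.0]), c_row)[0]
        return float(expit(lp1) * p_m1 + expit(lp0) * (1.0 - p_m1))
    # continuous: Gauss-Hermite quadrature centred at the mediator mean,
    # scaled by sigma * sqrt(2); doubling check against the tolerance
    sigma = mediator.sigma
    prev = None
    for n_nodes in (_QUAD_NODES, 2 * _QUAD_NODES, 4 * _QUAD_NODES, 8 * _QUAD_NODES):
        nodes, weights = _hermgauss_cached(n_nodes)
        m = mu_star + np.sqrt(2.0) * sigma * nodes
        lp = outcome.linear_predictor(np.full_like(m, a), m, c_row)
        val = float(weights @ expit(lp) / np.sqrt(np.pi))
        if prev is not None and abs(val - prev) < _QUAD_TOL:
            return val
        prev = val
    raise NumericalError(
        f"quadrature for the counterfactual probability did not stabilise "
        f"below {_QUAD_TOL} at {8 * _QUAD_NODES} nodes"
    )


def exact_counterfactual_prob(
    models: FittedModels, a: float, a_star: float, c, mediator_type=None
) -> float:
    """P(Y(a, M(a*)) = 1 | C = c) under the fitted models."""
    mt = mediator_type or models.mediator_type
    c = np.atleast_1d(np.asarray(c, dtype=float))
    p = _counterfactual_prob(models.outcome, models.mediator, a, a_star, c, mt)
    if not (0.0 < p < 1.0):
        raise DegenerateProbabilityError(f"counterfactual probability {p} outside (0, 1)")
    return p


def _log_odds(p: float) -> float:
    if p < _PROB_EPS or p > 1.0 - _PROB_EPS:
        raise DegenerateProbabilityError(
            f"counterfactual probability {p} within {_PROB_EPS} of 0/1; odds undefined"
        )
    return float(np.log(p) - np.log1p(-p))


def log_exact_nde(
    outcome: OutcomeParams, mediator: MediatorParams, contrast: ContrastSpec,
    mediator_type: str,
) -> float:
    _check_dims(outcome, mediator, contrast)
    a, s, c = contrast.a, contrast.a_star, contrast.c
    p_as = _counterfactual_prob(outcome, mediator, a, s, c, mediator_type)
    p_ss = _counterfactual_prob(outcome, mediator, s, s, c, mediator_type)
    return _log_odds(p_as) - _log_odds(p_ss)


def log_exact_nie(
    outcome: OutcomeParams, mediator: MediatorParams, contrast: ContrastSpec,
    mediator_type: str,
) -> float:
    _check_dims(outcome, mediator, contrast)
    a, s, c = contrast.a, contrast.a_star, contrast.c
    p_aa = _counterfactual_prob(outcome, mediator, a, a, c, mediator_type)
    p_as = _counterfactual_prob(outcome, mediator, a, s, c, mediator_type)
    return _log_odds(p_aa) - _log_odds(p_as)


def exact_nde(models: FittedModels, contrast: ContrastSpec, mediator_type=None) -> float:
    mt = mediator_type or models.mediator_type
    return float(np.exp(log_exact_nde(models.outcome, models.mediator, contrast, mt)))


def exact_nie(models: FittedModels, contrast: ContrastSpec, mediator_type=None) -> float:
    mt = mediator_type or models.mediator_type
    return float(np.exp(log_exact_nie(models.outcome, models.mediator, contrast, mt)))


def total_effect(nde: EffectEstimate, nie: EffectEstimate) -> EffectEstimate:
    """TE odds ratio as the product of the NDE and NIE odds ratios."""
    if nde.method != nie.method:
        raise DataError(f"mismatched methods: {nde.method} vs {nie.method}")
    if nde.effect != "NDE" or nie.effect != "NIE":
        raise DataError("total_effect expects an NDE and an NIE estimate")
    return EffectEstimate(
        effect="TE", or_value=nde.or_value * nie.or_value, method=nde.method
    )


# ---------------------------------------------------------------------------
# end-to-end driver


_LOG_OR_FNS = {
    ("approximate", "NDE"): log_approx_nde,
    ("approximate", "NIE"): log_approx_nie,
    ("exact", "NDE"): log_exact_nde,
    ("exact", "NIE"): log_exact_nie,
}


def log_or_function(effect: str, method: str, contrast: ContrastSpec,
                    mediator_type: str, sigma: Optional[float], n_theta: int):
    """log-OR as a function of the stacked (theta, beta) coefficient vector.

    Used by the delta method; sigma is held fixed at its fitted value.
    """

    def fn(vec: np.ndarray) -> float:
        outcome = OutcomeParams.from_vector(vec[:n_theta])
        mediator = MediatorParams.from_vector(vec[n_theta:], sigma=sigma)
        if effect == "TE":
            return (
                _LOG_OR_FNS[(method, "NDE")](outcome, mediator, contrast, mediator_type)
                + _LOG_OR_FNS[(method, "NIE")](outcome, mediator, contrast, mediator_type)
            )
        return _LOG_OR_FNS[(method, effect)](outcome, mediator, contrast, mediator_type)

    return fn


def resolve_contrast(
    data: MediationDataset, spec: DesignSpec, contrast=None, conditioning="means"
) -> ContrastSpec:
    """Fill in conditioning covariates: sample means (default), IPW-corrected
    means, or explicit values from a user-supplied contrast."""
    if contrast is not None:
        return contrast
    if conditioning == "means":
        c = data.covariate_means()
    elif conditioning == "ipw-means":
        if spec.pi is None:
            raise DesignError("ipw-means conditioning requires spec.pi")
        c = data.covariate_means(compute_weights(data, spec.pi))
    else:
        raise DesignError(f"unknown conditioning rule {conditioning!r}")
    return ContrastSpec(a=1.0, a_star=0.0, c=c)


def estimate_effects(
    data: MediationDataset,
    spec: DesignSpec,
    contrast: Optional[ContrastSpec] = None,
    method: str = "exact",
    level: float = 0.95,
    bootstrap=None,
    conditioning: str = "means",
) -> dict:
    """Fit models per strategy and return {"NDE", "NIE", "TE"} estimates.

    ``method`` selects the approximate closed forms or the exact plug-in
    estimators; with strategy "unified" the jointly estimated coefficients
    are substituted into the chosen formulas. Delta-method intervals are
    attached when requested in ``spec.ci_methods``; percentile-bootstrap
    intervals when a :class:`ccmediate.inference.BootstrapConfig` is given.
    """
    if method not in METHODS:
        raise DataError(f"method must be one of {METHODS}")
    models = fit_models(data, spec)
    contrast = resolve_contrast(data, spec, contrast, conditioning)
    return effects_from_models(
        models, contrast, method,
        level=level,
        bootstrap=bootstrap,
        data=data,
        spec=spec,
        conditioning=conditioning,
    )


def effects_from_models(
    models: FittedModels,
    contrast: ContrastSpec,
    method: str,
    level: float = 0.95,
    bootstrap=None,
    data: Optional[MediationDataset] = None,
    spec: Optional[DesignSpec] = None,
    conditioning: str = "means",
) -> dict:
    """Compute the three effect estimates from already-fitted models."""
    from .inference import delta_ci  # local import avoids a cycle

    mt = models.mediator_type
    sigma = models.mediator.sigma
    n_theta = models.outcome.n_params
    want_delta = spec is None or "delta" in spec.ci_methods
    out = {}
    for effect in EFFECTS:
        fn = log_or_function(effect, method, contrast, mt, sigma, n_theta)
        log_or = fn(models.coef_vector)
        est = EffectEstimate(effect=effect, or_value=float(np.exp(log_or)), method=method)
        if want_delta and models.joint_cov is not None:
            lo, hi, se = delta_ci(fn, models, level=level)
            est.log_se = se
            est.ci_delta = (lo, hi)
        out[effect] = est
    if bootstrap is not None:
        from .inference import bootstrap_ci

        if data is None or spec is None:
            raise DataError("bootstrap intervals need the raw data and design spec")
        boot = bootstrap_ci(
            data, spec, contrast, method, bootstrap, level=level,
            conditioning=conditioning,
        )
        for effect in EFFECTS:
            out[effect].ci_boot = boot[effect]
    return out
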