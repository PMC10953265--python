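"""Synthetic populations and balanced case-control samples.

The generative model mirrors the structure used to evaluate case-control
mediation estimators: two independent covariates (binary C1, zero-mean
Gaussian C2), a binary exposure A with logit linear in the covariates, a
mediator M that is either Gaussian with mean linear in (A, C) or Bernoulli
with logit linear in (A, C), and a Bernoulli outcome Y with

    logit P(Y=1) = theta0 + theta1*a + theta2*m + theta3*a*m
                   + theta41*c1 + theta42*c2.

Balanced case-control samples draw n/2 cases and n/2 controls without
replacement from a generated population. True natural effects for a scenario
are evaluated at the true coefficients with covariates at their population
means (E[C1] = c1_prob, E[C2] = 0); the implied marginal outcome prevalence
is available in closed(-quadrature) form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit

from .dataset import BINARY, CONTINUOUS, MediationDataset
from .exceptions import DataError, DesignError
from .fitting import MediatorParams, OutcomeParams
from .effects import (
    ContrastSpec,
    EffectEstimate,
    log_approx_nde,
    log_approx_nie,
    log_exact_nde,
    log_exact_nie,
    total_effect,
)

_DEFAULT_EXPOSURE_COEFS = (-0.5, 0.1, -0.15)


@dataclass(frozen=True)
class ScenarioSpec:
    """Full generative specification for one simulation scenario."""

    name: str
    mediator_type: str
    beta: tuple  # (beta0, beta1, beta21, beta22)
    theta: tuple  # (theta0, theta1, theta2, theta3, theta41, theta42)
    sigma: Optional[float] = None  # mediator residual SD, continuous only
    c1_prob: float = 0.5
    c2_sd: float = 0.75
    exposure_coefs: tuple = _DEFAULT_EXPOSURE_COEFS

    def __post_init__(self) -> None:
        if self.mediator_type not in (CONTINUOUS, BINARY):
            raise DataError(f"unknown mediator_type {self.mediator_type!r}")
        if self.mediator_type == CONTINUOUS and (self.sigma is None or self.sigma <= 0):
            raise DataError("continuous scenarios need sigma > 0")
        if not (0.0 < self.c1_prob < 1.0):
            raise DataError("c1_prob must lie in (0, 1)")
        if len(self.beta) != 4 or len(self.theta) != 6:
            raise DataError("beta must have 4 entries and theta 6")

    @property
    def outcome_params(self) -> OutcomeParams:
        t = self.theta
        return OutcomeParams(t[0], t[1], t[2], t[3], np.array(t[4:6]))

    @property
    def mediator_params(self) -> MediatorParams:
        b = self.beta
        sigma = self.sigma if self.mediator_type == CONTINUOUS else None
        return MediatorParams(b[0], b[1], np.array(b[2:4]), sigma=sigma)

    @property
    def covariate_means(self) -> np.ndarray:
        return np.array([self.c1_prob, 0.0])

    @property
    def pi_true(self) -> float:
        return marginal_prevalence(self)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mediator_type": self.mediator_type,
            "beta": list(self.beta),
            "theta": list(self.theta),
            "sigma": self.sigma,
            "c1_prob": self.c1_prob,
            "c2_sd": self.c2_sd,
            "exposure_coefs": list(self.exposure_coefs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        kwargs = dict(d)
        for key in ("beta", "theta", "exposure_coefs"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class CaseControlSample:
    """A balanced outcome-dependent sample drawn from a population."""

    data: MediationDataset
    n_cases: int
    n_controls: int
    pi_true: float


# ---------------------------------------------------------------------------
# generation


def generate_population(spec: ScenarioSpec, n_pop: int, seed) -> MediationDataset:
    """Draw n_pop independent records from the scenario's generative model."""
    if n_pop < 1:
        raise DataError("n_pop must be >= 1")
    rng = np.random.default_rng(seed)
    c1 = rng.binomial(1, spec.c1_prob, size=n_pop).astype(float)
    c2 = rng.normal(0.0, spec.c2_sd, size=n_pop)
    e0, e1, e2 = spec.exposure_coefs
    a = rng.binomial(1, expit(e0 + e1 * c1 + e2 * c2)).astype(float)
    b0, b1, b21, b22 = spec.beta
    m_lin = b0 + b1 * a + b21 * c1 + b22 * c2
    if spec.mediator_type == CONTINUOUS:
        m = m_lin + rng.normal(0.0, spec.sigma, size=n_pop)
    else:
        m = rng.binomial(1, expit(m_lin)).astype(float)
    t0, t1, t2, t3, t41, t42 = spec.theta
    y = rng.binomial(
        1, expit(t0 + t1 * a + t2 * m + t3 * a * m + t41 * c1 + t42 * c2)
    ).astype(float)
    return MediationDataset(
        y=y, a=a, m=m, c=np.column_stack([c1, c2]), mediator_type=spec.mediator_type
    )


def sample_case_control(
    population: MediationDataset, n: int, seed, pi_true: Optional[float] = None
) -> CaseControlSample:
    """Simple random sample of n/2 cases and n/2 controls, without replacement."""
    if n < 2 or n % 2:
        raise DesignError(f"balanced sample size must be a positive even number, got {n}")
    half = n // 2
    cases = np.flatnonzero(population.y == 1)
    controls = np.flatnonzero(population.y == 0)
    if len(cases) < half or len(controls) < half:
        raise DesignError(
            f"population has {len(cases)} cases and {len(controls)} controls; "
            f"cannot draw {half} of each"
        )
    rng = np.random.default_rng(seed)
    idx = np.concatenate(
        [rng.choice(cases, size=half, replace=False),
         rng.choice(controls, size=half, replace=False)]
    )
    if pi_true is None:
        pi_true = population.case_fraction
    return CaseControlSample(
        data=population.subset(idx), n_cases=half, n_controls=half, pi_true=pi_true
    )


def draw_case_control_sample(
    spec: ScenarioSpec, n: int, seed, pi: Optional[float] = None
) -> CaseControlSample:
    """Balanced case-control sample from a fresh population.

    Generates an adaptively sized population — large enough that n/2 cases
    (or controls, whichever stratum is rarer) are expected with margin — and
    samples from it, doubling the size if a draw comes up short. Each call
    uses an independent population, so replicate-level summaries are not
    contaminated by a shared finite-population offset.
    """
    if pi is None:
        pi = marginal_prevalence(spec)
    half = n // 2
    n_pop = int(1.5 * half / min(pi, 1.0 - pi)) + 2000
    seq = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    for attempt in range(8):
        pop_seed, draw_seed, seq = seq.spawn(3)
        population = generate_population(spec, n_pop, pop_seed)
        try:
            return sample_case_control(population, n, draw_seed, pi_true=pi)
        except DesignError:
            n_pop *= 2
    raise DesignError(
        f"could not accumulate {half} cases and controls even with a "
        f"population of {n_pop // 2} records"
    )


# ---------------------------------------------------------------------------
# scenario truths


def true_effects(spec: ScenarioSpec, method: str = "exact") -> dict:
    """True (NDE, NIE, TE) odds ratios at the population covariate means."""
    contrast = ContrastSpec(a=1.0, a_star=0.0, c=spec.covariate_means)
    outcome, mediator = spec.outcome_params, spec.mediator_params
    if method == "approximate":
        log_nde = log_approx_nde(outcome, mediator, contrast, spec.mediator_type)
        log_nie = log_approx_nie(outcome, mediator, contrast, spec.mediator_type)
    elif method == "exact":
        log_nde = log_exact_nde(outcome, mediator, contrast, spec.mediator_type)
        log_nie = log_exact_nie(outcome, mediator, contrast, spec.mediator_type)
    else:
        raise DataError(f"method must be 'approximate' or 'exact', got {method!r}")
    nde = EffectEstimate("NDE", float(np.exp(log_nde)), method)
    nie = EffectEstimate("NIE", float(np.exp(log_nie)), method)
    te = total_effect(nde, nie)
    return {"NDE": nde.or_value, "NIE": nie.or_value, "TE": te.or_value}


def marginal_prevalence(spec: ScenarioSpec, n_nodes: int = 40) -> float:
    """P(Y = 1) implied by the scenario, by Gauss-Hermite quadrature.

    Integrates over C2 (and M when continuous) and sums over C1, A (and M
    when binary); deterministic, no simulation.
    """
    nodes, weights = hermgauss(n_nodes)
    c2 = np.sqrt(2.0) * spec.c2_sd * nodes  # quadrature points for C2
    wc2 = weights / np.sqrt(np.pi)
    e0, e1, e2 = spec.exposure_coefs
    b0, b1, b21, b22 = spec.beta
    t0, t1, t2, t3, t41, t42 = spec.theta
    total = 0.0
    for c1, p_c1 in ((0.0, 1.0 - spec.c1_prob), (1.0, spec.c1_prob)):
        p_a1 = expit(e0 + e1 * c1 + e2 * c2)  # per c2 node
        for a, p_a in ((0.0, 1.0 - p_a1), (1.0, p_a1)):
            mu_m = b0 + b1 * a + b21 * c1 + b22 * c2
            base = t0 + t1 * a + t41 * c1 + t42 * c2
            slope = t2 + t3 * a
            if spec.mediator_type == CONTINUOUS:
                m = mu_m[:, None] + np.sqrt(2.0) * spec.sigma * nodes[None, :]
                p_y = (expit(base[:, None] + slope * m) * (weights / np.sqrt(np.pi))).sum(axis=1)
            else:
                p_m1 = expit(mu_m)
                p_y = expit(base + slope) * p_m1 + expit(base) * (1.0 - p_m1)
            total += p_c1 * float((wc2 * p_a * p_y).sum())
    return total


def scenario_prevalence(spec: ScenarioSpec, n_mc: int = 200_000, seed=0) -> dict:
    """Monte-Carlo marginal and conditional outcome prevalences.

    Conditional strata: quartiles of M for a continuous mediator, the four
    A x M cells for a binary one. Characterises how rare the outcome is
    within strata, which is what the rare-outcome approximation cares about.
    """
    if n_mc < 1:
        raise DataError("n_mc must be >= 1")
    pop = generate_population(spec, n_mc, seed)
    out = {"marginal": float(pop.y.mean())}
    if spec.mediator_type == CONTINUOUS:
        qs = np.quantile(pop.m, [0.25, 0.5, 0.75])
        labels = ["m_q1", "m_q2", "m_q3", "m_q4"]
        bins = np.digitize(pop.m, qs)
        for k, lab in enumerate(labels):
            mask = bins == k
            out[lab] = float(pop.y[mask].mean()) if mask.any() else np.nan
    else:
        for a_val in (0, 1):
            for m_val in (0, 1):
                mask = (pop.a == a_val) & (pop.m == m_val)
                out[f"a{a_val}_m{m_val}"] = (
                    float(pop.y[mask].mean()) if mask.any() else np.nan
                )
    return out
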