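"""Delta-method and percentile-bootstrap confidence intervals.

The delta method propagates the joint coefficient covariance through the
log-OR functional with a central finite-difference gradient; intervals are
symmetric on the log scale. The percentile bootstrap resamples records with
replacement — by default stratified on the outcome so the case:control ratio
of the design is preserved — re-runs the whole estimation per replicate, and
reports empirical order-statistic quantiles of the odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import norm

from .dataset import DesignSpec, MediationDataset
from .exceptions import (
    CCMediateError,
    ConvergenceError,
    DataError,
    DegenerateProbabilityError,
    NumericalError,
)
from .fitting import FittedModels

_GRAD_STEP = 1e-6


@dataclass(frozen=True)
class BootstrapConfig:
    reps: int = 1000
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise DataError("bootstrap reps must be >= 1")


def _gradient(fn: Callable[[np.ndarray], float], x: np.ndarray) -> np.ndarray:
    """Central finite differences with step 1e-6 * (1 + |coef|)."""
    g = np.empty_like(x)
    for i in range(len(x)):
        h = _GRAD_STEP * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fn(xp) - fn(xm)) / (2.0 * h)
    return g


def delta_ci(
    effect_fn: Callable[[np.ndarray], float],
    models: FittedModels,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """(lower, upper, log_se) for exp(effect_fn) via the delta method.

    ``effect_fn`` maps the stacked (theta, beta) coefficient vector to a
    log-OR; its gradient g gives SE = sqrt(g' Sigma g) with Sigma the joint
    coefficient covariance.
    """
    if models.joint_cov is None:
        raise DataError("delta interval needs the joint coefficient covariance")
    cov = np.asarray(models.joint_cov, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise NumericalError("joint covariance contains non-finite entries")
    x = models.coef_vector
    if cov.shape != (len(x), len(x)):
        raise DataError(
            f"joint covariance shape {cov.shape} does not match {len(x)} coefficients"
        )
    g = _gradient(effect_fn, x)
    var = float(g @ cov @ g)
    if var < 0:
        raise NumericalError(f"negative delta variance {var}; covariance not PSD")
    se = float(np.sqrt(var))
    log_or = effect_fn(x)
    z = norm.ppf(0.5 + level / 2.0)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se)), se


def _resample_index(data: MediationDataset, rng, stratified: bool) -> np.ndarray:
    if not stratified:
        return rng.integers(0, data.n, size=data.n)
    cases = np.flatnonzero(data.y == 1)
    controls = np.flatnonzero(data.y == 0)
    return np.concatenate(
        [rng.choice(cases, size=len(cases), replace=True),
         rng.choice(controls, size=len(controls), replace=True)]
    )


def bootstrap_ci(
    data: MediationDataset,
    spec: DesignSpec,
    contrast,
    method: str,
    config: BootstrapConfig,
    level: float = 0.95,
    conditioning: str = "means",
) -> dict:
    """Percentile intervals for the NDE/NIE/TE odds ratios.

    Replicates that fail to converge (or hit degenerate probabilities) are
    dropped and counted; more than 50% failures aborts. The returned dict
    maps each effect to (lower, upper) and carries the failure count under
    the key ``"n_failed"``.
    """
    from .effects import EFFECTS, estimate_effects  # local import avoids a cycle

    rng = np.random.default_rng(config.seed)
    point_spec = DesignSpec(strategy=spec.strategy, pi=spec.pi, ci_methods=())
    ors = {eff: [] for eff in EFFECTS}
    n_failed = 0
    for _ in range(config.reps):
        idx = _resample_index(data, rng, config.stratified)
        try:
            rep = estimate_effects(
                data.subset(idx), point_spec, contrast=contrast, method=method,
                conditioning=conditioning,
            )
        except (ConvergenceError, DegenerateProbabilityError, NumericalError):
            n_failed += 1
            continue
        for eff in EFFECTS:
            ors[eff].append(rep[eff].or_value)
    if n_failed > config.reps / 2:
        raise CCMediateError(
            f"bootstrap aborted: {n_failed}/{config.reps} replicates failed"
        )
    alpha = 1.0 - level
    out = {"n_failed": n_failed}
    for eff in EFFECTS:
        vals = np.asarray(ors[eff])
        lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0],
                             method="closest_observation")
        out[eff] = (float(lo), float(hi))
    return out
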