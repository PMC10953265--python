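"""Replicate-level evaluation of the six estimation approaches.

Approaches (strategy for fitting x formula for the effects):

==============  ==================  ============
label           fitting strategy    effect formulas
==============  ==================  ============
Approx_Naive    naive               approximate
Approx_C        controls only       approximate
Approx_IPW      IPW (needs pi)      approximate
Exact_Naive     naive               exact
Exact_IPW       IPW (needs pi)      exact
Unified         joint likelihood    approximate
==============  ==================  ============

Each replicate draws a balanced case-control sample from a fresh,
adaptively sized population, runs each approach with covariates conditioned
at the sample means, and the summary reports bias, SD, RMSE and CI coverage
against the scenario's true effects. Per-replicate seeds derive from the
master seed through a counter-based split so any replicate is reproducible
in isolation; replicates where a fit fails are excluded from the metrics
and counted.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import DesignSpec, MediationDataset
from .effects import EFFECTS, ContrastSpec, effects_from_models, resolve_contrast
from .exceptions import (
    CCMediateError,
    ConvergenceError,
    DegenerateProbabilityError,
    NumericalError,
)
from .fitting import fit_models
from .inference import BootstrapConfig, bootstrap_ci
from .simulate import ScenarioSpec, draw_case_control_sample, true_effects

logger = logging.getLogger(__name__)

APPROACHES = {
    "Approx_Naive": ("naive", "approximate"),
    "Approx_C": ("controls_only", "approximate"),
    "Approx_IPW": ("ipw", "approximate"),
    "Exact_Naive": ("naive", "exact"),
    "Exact_IPW": ("ipw", "exact"),
    "Unified": ("unified", "approximate"),
}

_FIT_ERRORS = (ConvergenceError, DegenerateProbabilityError, NumericalError)


def _seed_for(master_seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=key)


def _design_for(strategy: str, pi: float) -> DesignSpec:
    return DesignSpec(strategy=strategy, pi=pi if strategy == "ipw" else None)


def run_replicates(
    spec: ScenarioSpec,
    n: int,
    reps: int,
    approaches: Optional[Sequence[str]] = None,
    boot_reps: int = 0,
    seed: int = 0,
    pi: Optional[float] = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Point estimates and CI endpoints for each (replicate, approach, effect).

    ``pi`` is the prevalence handed to the IPW approaches; it defaults to the
    scenario's true marginal prevalence, mirroring a correctly informed IPW
    analysis (pass a perturbed value to study misspecification). Bootstrap
    intervals (when ``boot_reps > 0``) are computed for every approach except
    Unified.
    """
    if approaches is None:
        approaches = list(APPROACHES)
    unknown = set(approaches) - set(APPROACHES)
    if unknown:
        raise CCMediateError(f"unknown approaches: {sorted(unknown)}")
    pi_true = spec.pi_true
    if pi is None:
        pi = pi_true
    strategies = {APPROACHES[app][0] for app in approaches}
    rows = []
    for rep in range(reps):
        sample = draw_case_control_sample(
            spec, n, _seed_for(seed, 1, rep), pi=pi_true
        ).data
        contrast = ContrastSpec(a=1.0, a_star=0.0, c=sample.covariate_means())
        fits, fit_fail = {}, {}
        for strategy in strategies:
            try:
                fits[strategy] = fit_models(sample, _design_for(strategy, pi))
            except _FIT_ERRORS as exc:
                fit_fail[strategy] = exc
                logger.debug("rep %d: %s fit failed: %s", rep, strategy, exc)
        for app in approaches:
            strategy, method = APPROACHES[app]
            base = {"rep": rep, "approach": app}
            if strategy in fit_fail:
                for eff in EFFECTS:
                    rows.append({**base, "effect": eff, "ok": False})
                continue
            try:
                ests = effects_from_models(
                    fits[strategy], contrast, method, level=level
                )
                boot = None
                if boot_reps > 0 and app != "Unified":
                    boot = bootstrap_ci(
                        sample, _design_for(strategy, pi), contrast, method,
                        BootstrapConfig(
                            reps=boot_reps,
                            seed=_seed_for(seed, 2, rep).generate_state(1)[0] % (2**31),
                        ),
                        level=level,
                    )
            except _FIT_ERRORS as exc:
                logger.debug("rep %d: %s effects failed: %s", rep, app, exc)
                for eff in EFFECTS:
                    rows.append({**base, "effect": eff, "ok": False})
                continue
            for eff in EFFECTS:
                est = ests[eff]
                row = {
                    **base,
                    "effect": eff,
                    "ok": True,
                    "estimate": est.or_value,
                    "ci_delta_lo": est.ci_delta[0] if est.ci_delta else np.nan,
                    "ci_delta_hi": est.ci_delta[1] if est.ci_delta else np.nan,
                }
                if boot is not None:
                    row["ci_boot_lo"], row["ci_boot_hi"] = boot[eff]
                rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["scenario"] = spec.name
    df.attrs["pi"] = pi
    df.attrs["n"] = n
    return df


def _coverage(lo: pd.Series, hi: pd.Series, truth: float) -> float:
    ok = lo.notna() & hi.notna()
    if not ok.any():
        return np.nan
    inside = (lo[ok] <= truth) & (truth <= hi[ok])
    return 100.0 * inside.mean()


def summarize(estimates: pd.DataFrame, true_values: dict) -> pd.DataFrame:
    """Per-(approach, effect) bias, relative bias, SD, RMSE and CI coverage.

    ``true_values`` maps effect name to the true OR. SD uses the n-1
    denominator; RMSE is computed from replicate-level squared errors, so
    rmse^2 = bias^2 + sd^2 holds up to the SD denominator convention.
    """
    rows = []
    for (app, eff), grp in estimates.groupby(["approach", "effect"], sort=False):
        truth = true_values[eff]
        used = grp[grp["ok"] == True]  # noqa: E712
        est = used["estimate"].to_numpy(dtype=float)
        if len(est) < 1:
            continue
        mean = est.mean()
        bias = mean - truth
        sd = est.std(ddof=1) if len(est) > 1 else 0.0
        rmse = float(np.sqrt(np.mean((est - truth) ** 2)))
        row = {
            "scenario": estimates.attrs.get("scenario", ""),
            "effect": eff,
            "approach": app,
            "true_value": truth,
            "mean": mean,
            "bias": bias,
            "relative_bias": 100.0 * bias / truth,
            "sd": sd,
            "rmse": rmse,
            "cp_delta": _coverage(
                used.get("ci_delta_lo", pd.Series(dtype=float)),
                used.get("ci_delta_hi", pd.Series(dtype=float)),
                truth,
            ),
            "cp_boot": _coverage(
                used.get("ci_boot_lo", pd.Series(np.nan, index=used.index)),
                used.get("ci_boot_hi", pd.Series(np.nan, index=used.index)),
                truth,
            ),
            "n_reps_used": len(est),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def benchmark_scenario(
    spec: ScenarioSpec,
    n: int = 1000,
    reps: int = 1000,
    approaches: Optional[Sequence[str]] = None,
    boot_reps: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """run_replicates + summarize against the scenario's exact true effects."""
    estimates = run_replicates(
        spec, n, reps, approaches=approaches, boot_reps=boot_reps, seed=seed
    )
    return summarize(estimates, true_effects(spec, "exact"))


def format_metrics(metrics: pd.DataFrame) -> str:
    """Fixed-width table with the conventional column order."""
    cols = [
        "effect", "approach", "true_value", "mean", "bias", "relative_bias",
        "sd", "rmse", "cp_delta", "cp_boot",
    ]
    disp = metrics[cols].copy()
    for col in cols[2:8]:
        disp[col] = disp[col].map(lambda v: f"{v:.3f}")
    for col in ("cp_delta", "cp_boot"):
        disp[col] = disp[col].map(lambda v: "-" if pd.isna(v) else f"{v:.1f}")
    return disp.to_string(index=False)


# ---------------------------------------------------------------------------
# prevalence misspecification sweep


def default_misspecification_grid() -> np.ndarray:
    """{-99%} plus -95% .. +100% in 5% steps, as fractions."""
    return np.concatenate(([-0.99], np.arange(-0.95, 1.0001, 0.05)))


def misspecification_sweep(
    spec: ScenarioSpec,
    n: int,
    reps: int,
    grid: Optional[Iterable[float]] = None,
    seed: int = 0,
    include_reference: bool = True,
) -> pd.DataFrame:
    """Average natural effects of the IPW approaches over a grid of relative
    prevalence errors.

    For each relative error r the IPW approaches run with
    pi = pi_true * (1 + r); grid points with pi >= 1 are skipped with a
    warning. The prevalence-free approaches (Approx_C, Unified) are constant
    across the grid and reported at r = 0 for reference.
    """
    grid = default_misspecification_grid() if grid is None else np.asarray(list(grid), float)
    if (grid <= -1.0).any():
        raise CCMediateError("relative errors must exceed -100%")
    pi_true = spec.pi_true
    samples = [
        draw_case_control_sample(spec, n, _seed_for(seed, 1, rep), pi=pi_true).data
        for rep in range(reps)
    ]
    contrasts = [
        ContrastSpec(a=1.0, a_star=0.0, c=s.covariate_means()) for s in samples
    ]
    rows = []

    def _collect(app: str, rel_error: float, pi: Optional[float]) -> None:
        strategy, method = APPROACHES[app]
        sums = {eff: [] for eff in EFFECTS}
        for sample, contrast in zip(samples, contrasts):
            try:
                models = fit_models(sample, _design_for(strategy, pi))
                ests = effects_from_models(models, contrast, method)
            except _FIT_ERRORS:
                continue
            for eff in EFFECTS:
                sums[eff].append(ests[eff].or_value)
        for eff in EFFECTS:
            vals = sums[eff]
            rows.append(
                {
                    "approach": app,
                    "rel_error": rel_error,
                    "pi": pi if pi is not None else np.nan,
                    "effect": eff,
                    "mean_or": float(np.mean(vals)) if vals else np.nan,
                    "n_reps_used": len(vals),
                }
            )

    for r in grid:
        pi = pi_true * (1.0 + r)
        if pi >= 1.0:
            warnings.warn(
                f"skipping grid point {r:+.2f}: pi = {pi:.3f} >= 1", stacklevel=2
            )
            continue
        for app in ("Approx_IPW", "Exact_IPW"):
            _collect(app, float(r), pi)
    if include_reference:
        for app in ("Approx_C", "Unified"):
            _collect(app, 0.0, None)
    df = pd.DataFrame(rows)
    df.attrs["scenario"] = spec.name
    df.attrs["pi_true"] = pi_true
    return df


# ---------------------------------------------------------------------------
# parameter recovery


def coef_recovery_test(
    spec: ScenarioSpec,
    n: int,
    reps: int,
    strategy: str = "ipw",
    seed: int = 0,
) -> pd.DataFrame:
    """Average fitted coefficients across replicates, with one-sample two-sided
    t-tests against the generative values.

    Zero t-statistics (estimates exactly at truth in every replicate) report
    a p-value of 1.
    """
    pi = spec.pi_true
    truth = np.concatenate((spec.outcome_params.vector, spec.mediator_params.vector))
    names = (
        ["theta0", "theta1", "theta2", "theta3", "theta41", "theta42"]
        + ["beta0", "beta1", "beta21", "beta22"]
    )
    draws = []
    for rep in range(reps):
        sample = draw_case_control_sample(spec, n, _seed_for(seed, 1, rep), pi=pi).data
        try:
            models = fit_models(sample, _design_for(strategy, pi))
        except _FIT_ERRORS:
            continue
        draws.append(models.coef_vector)
    if len(draws) < 2:
        raise CCMediateError("coefficient recovery needs at least two successful replicates")
    draws = np.asarray(draws)
    rows = []
    for j, name in enumerate(names):
        vals = draws[:, j]
        if np.allclose(vals, truth[j]):
            pval = 1.0
        else:
            pval = float(stats.ttest_1samp(vals, truth[j]).pvalue)
        rows.append(
            {
                "coef": name,
                "truth": truth[j],
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)),
                "p_value": pval,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["strategy"] = strategy
    df.attrs["n_reps_used"] = len(draws)
    return df
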