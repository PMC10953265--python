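"""Bundled illustrative simulation scenarios.

Three scenarios per mediator type span the outcome-prevalence regimes that
separate the estimators under comparison:

``*_rare``
    Outcome rare both marginally and within mediator/exposure strata
    (~1-2% everywhere): the rare-outcome approximation holds and every
    approach, including the naive ones, should be nearly unbiased.
``*_rare_marginal``
    Outcome rare-to-moderate marginally (~8-9%) but common (~20-25%) in the
    high-mediator strata: the rare-outcome approximation fails conditionally,
    which biases the approximate closed forms even when the regression
    coefficients are estimated consistently (IPW). Exact estimators with IPW
    stay nearly unbiased.
``*_common``
    Outcome common everywhere (~33-35% marginally): a stress regime for
    every approximation and for naive design handling.

These specs are this package's own evaluation conditions, chosen to realise
the regimes above; the implied prevalences and true effects are computed, not
asserted (see :func:`ccmediate.simulate.marginal_prevalence` and
:func:`ccmediate.simulate.true_effects`).
"""

from __future__ import annotations

from .simulate import ScenarioSpec

CONTINUOUS_SCENARIOS = {
    "cont_rare": ScenarioSpec(
        name="cont_rare",
        mediator_type="continuous",
        beta=(1.0, 0.2, 0.15, -0.1),
        theta=(-5.5, 0.35, 0.25, 0.05, 0.2, -0.2),
        sigma=0.5,
        c2_sd=0.75,
    ),
    "cont_rare_marginal": ScenarioSpec(
        name="cont_rare_marginal",
        mediator_type="continuous",
        beta=(1.0, 0.4, 0.15, -0.1),
        theta=(-6.0, 0.15, 2.2, 0.2, 0.3, -0.2),
        sigma=0.5,
        c2_sd=0.75,
    ),
    "cont_common": ScenarioSpec(
        name="cont_common",
        mediator_type="continuous",
        beta=(1.0, 0.3, 0.15, -0.1),
        theta=(-1.5, 0.3, 0.5, 0.1, 0.2, -0.2),
        sigma=0.5,
        c2_sd=0.75,
    ),
}

BINARY_SCENARIOS = {
    "bin_rare": ScenarioSpec(
        name="bin_rare",
        mediator_type="binary",
        beta=(-0.3, 0.5, 0.2, -0.1),
        theta=(-5.0, 0.5, 0.6, 0.15, 0.2, -0.2),
        c2_sd=1.0,
    ),
    "bin_rare_marginal": ScenarioSpec(
        name="bin_rare_marginal",
        mediator_type="binary",
        beta=(-0.5, 0.8, 0.2, -0.1),
        theta=(-5.5, 0.4, 3.2, 0.3, 0.3, -0.2),
        c2_sd=1.0,
    ),
    "bin_common": ScenarioSpec(
        name="bin_common",
        mediator_type="binary",
        beta=(-0.3, 0.6, 0.2, -0.1),
        theta=(-1.5, 0.4, 0.8, 0.2, 0.2, -0.2),
        c2_sd=1.0,
    ),
}

SCENARIOS = {**CONTINUOUS_SCENARIOS, **BINARY_SCENARIOS}


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
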