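"""Synthetic demonstration dataset in the style of a cancer case-control study.

Generates an entirely synthetic case-control sample loosely emulating the
marginals of a published ovarian-cancer study of long-term oral-contraceptive
use (binary exposure), lifetime number of ovulatory cycles (continuous
mediator), age and education (covariates): 364 cases, 907 controls, exposure
prevalence higher among controls, mediator mean near 384 (SD ~111) among
cases and 354 (SD ~122) among controls. No real subject data are used or
reproduced; the generator is a demonstration input for the estimation API,
not an analysis of the original study.
"""

from __future__ import annotations

import numpy as np

from .dataset import MediationDataset


def synthetic_ovarian_study(
    n_cases: int = 364, n_controls: int = 907, seed: int = 0
) -> MediationDataset:
    """Draw a synthetic case-control sample with study-like marginals.

    Controls are generated from covariates -> exposure -> mediator models
    calibrated to the target marginals; cases re-use the same structural
    models with a mediator-and-exposure-tilted sampling weight, emulating a
    modest protective exposure effect mediated partly through the mediator.
    """
    rng = np.random.default_rng(seed)

    def _draw(n, exposure_logit_shift, extra_cycles):
        age = np.clip(rng.normal(58.5, 12.3, size=4 * n), 25, 79)
        education = rng.binomial(1, 0.67, size=4 * n).astype(float)
        # younger, more educated women are more often long-term users
        p_exp = 1.0 / (1.0 + np.exp(-(1.2 - 0.05 * age + 0.6 * education
                                      + exposure_logit_shift)))
        a = rng.binomial(1, p_exp).astype(float)
        # long-term use suppresses ovulation -> far fewer lifetime cycles
        cycles = (
            440.0 - 130.0 * a - 0.9 * (age - 58.5) + extra_cycles
            + rng.normal(0.0, 105.0, size=4 * n)
        )
        keep = rng.permutation(4 * n)[:n]
        return age[keep], education[keep], a[keep], np.clip(cycles[keep], 0, None)

    age0, edu0, a0, m0 = _draw(n_controls, 0.0, -55.0)
    age1, edu1, a1, m1 = _draw(n_cases, -0.7, -20.0)
    y = np.concatenate([np.zeros(n_controls), np.ones(n_cases)])
    return MediationDataset(
        y=y,
        a=np.concatenate([a0, a1]),
        m=np.concatenate([m0, m1]),
        c=np.column_stack(
            [np.concatenate([age0, age1]), np.concatenate([edu0, edu1])]
        ),
        mediator_type="continuous",
    )
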