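"""Individual-level mediation data and case-control design specifications.

The core container holds one record per subject: a binary outcome ``y``, a
binary exposure ``a``, a mediator ``m`` (Gaussian-continuous or binary) and a
covariate matrix ``c``. A :class:`DesignSpec` states how the case-control
sampling is handled when fitting the outcome and mediator regressions:

``naive``
    Ignore the design; fit both models on the full sample with unit weights.
``controls_only``
    Fit the mediator model among controls only (valid when the outcome is
    rare, since then the control-stratum mediator law approximates the
    population one); outcome model on the full sample.
``ipw``
    Weight cases by pi/p and controls by (1-pi)/(1-p), where p is the sample
    case fraction and pi the population outcome prevalence, in both models.
``unified``
    Jointly maximise the prospective likelihood for (M, Y); needs no pi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, DesignError

CONTINUOUS = "continuous"
BINARY = "binary"

STRATEGIES = ("naive", "controls_only", "ipw", "unified")


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _check_binary(arr: np.ndarray, name: str) -> None:
    if not np.isin(arr, (0.0, 1.0)).all():
        bad = np.flatnonzero(~np.isin(arr, (0.0, 1.0)))[:5]
        raise DataError(f"{name} must be coded 0/1; offending rows: {bad.tolist()}")


@dataclass
class MediationDataset:
    """Records (Y, A, M, C) with a mediator-type tag.

    Parameters
    ----------
    y, a : array-like of 0/1, length n
        Outcome and exposure indicators.
    m : array-like, length n
        Mediator values; must be 0/1 when ``mediator_type`` is ``"binary"``.
    c : array-like, shape (n, p)
        Covariate columns (numeric; binary columns allowed). May be empty
        (p = 0).
    mediator_type : {"continuous", "binary"}
    """

    y: np.ndarray
    a: np.ndarray
    m: np.ndarray
    c: np.ndarray
    mediator_type: str = CONTINUOUS

    def __post_init__(self) -> None:
        self.y = _as_1d(self.y, "y")
        self.a = _as_1d(self.a, "a")
        self.m = _as_1d(self.m, "m")
        c = np.asarray(self.c, dtype=float)
        if c.ndim == 1:
            c = c.reshape(-1, 1) if c.size else c.reshape(len(self.y), 0)
        self.c = c
        n = len(self.y)
        if n < 1:
            raise DataError("dataset must contain at least one record")
        for name, arr in (("a", self.a), ("m", self.m)):
            if len(arr) != n:
                raise DataError(f"{name} has length {len(arr)}, expected {n}")
        if self.c.shape[0] != n:
            raise DataError(f"c has {self.c.shape[0]} rows, expected {n}")
        _check_binary(self.y, "y")
        _check_binary(self.a, "a")
        if self.mediator_type not in (CONTINUOUS, BINARY):
            raise DataError(f"unknown mediator_type {self.mediator_type!r}")
        if self.mediator_type == BINARY:
            _check_binary(self.m, "m")
        if not (
            np.isfinite(self.m).all()
            and np.isfinite(self.c).all()
        ):
            raise DataError("non-finite values in m or c")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_covariates(self) -> int:
        return self.c.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n

    def subset(self, idx) -> "MediationDataset":
        """New dataset restricted to (or resampled by) integer/boolean index."""
        return MediationDataset(
            y=self.y[idx], a=self.a[idx], m=self.m[idx], c=self.c[idx],
            mediator_type=self.mediator_type,
        )

    def covariate_means(self, weights: Optional[np.ndarray] = None) -> np.ndarray:
        """Column means of C, optionally weighted (e.g. by IPW weights)."""
        if self.n_covariates == 0:
            return np.zeros(0)
        if weights is None:
            return self.c.mean(axis=0)
        w = np.asarray(weights, dtype=float)
        return (w[:, None] * self.c).sum(axis=0) / w.sum()

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        exposure: str,
        mediator: str,
        covariates: Sequence[str] = (),
        mediator_type: str = CONTINUOUS,
    ) -> "MediationDataset":
        cols = [outcome, exposure, mediator, *covariates]
        missing_cols = [col for col in cols if col not in df.columns]
        if missing_cols:
            raise DataError(f"columns not found in data: {missing_cols}")
        sub = df[cols]
        na_rows = sub.index[sub.isna().any(axis=1)]
        if len(na_rows):
            raise DataError(
                f"missing values in rows {na_rows[:10].tolist()}"
                + (" ..." if len(na_rows) > 10 else "")
            )
        cmat = sub[list(covariates)].to_numpy(dtype=float) if covariates else np.zeros((len(sub), 0))
        return cls(
            y=sub[outcome].to_numpy(dtype=float),
            a=sub[exposure].to_numpy(dtype=float),
            m=sub[mediator].to_numpy(dtype=float),
            c=cmat,
            mediator_type=mediator_type,
        )

    @classmethod
    def from_csv(cls, path, outcome="y", exposure="a", mediator="m",
                 covariates: Sequence[str] = (), mediator_type: str = CONTINUOUS,
                 ) -> "MediationDataset":
        return cls.from_dataframe(
            pd.read_csv(path), outcome, exposure, mediator, covariates, mediator_type
        )

    def to_dataframe(self, covariate_names: Optional[Sequence[str]] = None) -> pd.DataFrame:
        if covariate_names is None:
            covariate_names = [f"c{i + 1}" for i in range(self.n_covariates)]
        out = pd.DataFrame({"y": self.y.astype(int), "a": self.a.astype(int), "m": self.m})
        for j, name in enumerate(covariate_names):
            out[name] = self.c[:, j]
        return out


@dataclass(frozen=True)
class DesignSpec:
    """How to account (or not) for case-control sampling when fitting.

    ``pi`` is the population outcome prevalence and is required exactly when
    ``strategy == "ipw"``; the unified likelihood needs no prevalence and
    forbids one.
    """

    strategy: str = "naive"
    pi: Optional[float] = None
    ci_methods: tuple = ("delta",)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise DesignError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.strategy == "ipw":
            if self.pi is None:
                raise DesignError("strategy 'ipw' requires a population prevalence pi")
        if self.strategy == "unified" and self.pi is not None:
            raise DesignError("strategy 'unified' does not take a prevalence pi")
        if self.pi is not None and not (0.0 < self.pi < 1.0):
            raise DesignError(f"pi must lie strictly in (0, 1), got {self.pi}")
        for meth in self.ci_methods:
            if meth not in ("delta", "percentile_bootstrap"):
                raise DesignError(f"unknown CI method {meth!r}")


def load_config(path) -> dict:
    """Read a plain-text key-value (YAML) analysis configuration.

    Recognised keys: strategy, pi, mediator_type, outcome, exposure,
    mediator, covariates, seed, bootstrap_reps, level.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise DataError("config file must contain key: value pairs")
    return dict(cfg)
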