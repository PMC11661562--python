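"""Core containers shared across the simulation, forest, and metric layers.

The study objects are deliberately small, explicit dataclasses rather than
opaque arrays: a benchmark run touches every one of them (covariate draws,
linear-predictor forms, response families, fitted curves, forest settings)
and reproducibility hinges on their fields being inspectable and loggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "CovariateMatrix",
    "LinearPredictorSpec",
    "ResponseModel",
    "DataSet",
    "SurvivalCurve",
    "ForestSpec",
    "SNRReport",
    "CensoringCalibration",
    "FLC",
    "CalibrationError",
    "MomentError",
]

ColumnKind = Literal[
    "binary",
    "uniform",
    "categorical5",
    "extra_correlated",
    "extra_noise_corr",
    "extra_noise_indep",
]


class CalibrationError(RuntimeError):
    """Root search for a calibration parameter failed to bracket or converge."""


class MomentError(ValueError):
    """A conditional moment of the response family is non-finite."""


@dataclass
class CovariateMatrix:
    """An n x p design with per-column semantics.

    Columns are stored as a dense float array; ``kinds`` tags each column so
    downstream code knows which columns are dummy-coded, which are ordered
    numerics, and which are unimportant extras (coefficient zero by design).
    """

    values: np.ndarray  # (n, p) float64
    kinds: list[str]
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d array")
        if len(self.kinds) != self.values.shape[1] or len(self.names) != self.values.shape[1]:
            raise ValueError("kinds/names length must match number of columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


@dataclass
class LinearPredictorSpec:
    """Functional form and coefficients of the linear predictor x'beta.

    ``form`` selects how the ten base covariates enter:

    - ``baseline``: first-order terms only (categoricals dummy coded,
      level 1 as reference).
    - ``poly_int``: the X2..X5 linear terms are replaced by X2^2, X3*X4,
      X5^2, X2*X5 and an extra X3*X6 interaction is added.
    - ``sine``: the X2 term becomes sin(2*pi*X2) (seasonality-like signal).
    - ``piecewise``: X2 and X3 become continuous piecewise-linear with knots
      at 1/3 and 2/3 and a separate slope per segment.

    ``signal_scale`` multiplies every non-intercept coefficient and is the
    single knob used by SNR calibration.
    """

    form: Literal["baseline", "poly_int", "sine", "piecewise"] = "baseline"
    coefficients: Optional[Mapping[str, object]] = None
    signal_scale: float = 1.0

    def scaled(self, signal_scale: float) -> "LinearPredictorSpec":
        return replace(self, signal_scale=signal_scale)


@dataclass
class ResponseModel:
    """Conditional distribution of the latent survival time T given x'beta.

    family:
      - ``weibull_ph``: hazard h(t|x) = lambda*rho*t^(rho-1)*exp(x'beta),
        a proportional-hazards Weibull.
      - ``lognormal_aft``: log t = intercept + x'beta + sigma*Z, an
        accelerated failure time model (crossing survival curves possible,
        hazards never cross).
      - ``gen_gamma``: generalized gamma with scale a*exp(x'beta) and shape
        pair (b, k); k switches between k0 and k1 by the binary covariate X1
        so the two halves of each sample have crossing hazards (k=1/16 gives
        a bathtub hazard, k=1 a monotone Weibull hazard).
    """

    family: Literal["weibull_ph", "lognormal_aft", "gen_gamma"] = "weibull_ph"
    # weibull_ph
    shape: float = 2.0  # rho
    scale: float = 1.0  # lambda
    # lognormal_aft
    intercept: float = 0.0
    error_sd: float = 0.5  # sigma
    # gen_gamma
    gg_scale: float = 1.0  # a
    gg_shape: float = 2.0  # b
    gg_k0: float = 1.0  # k when X1 = 0 (monotone Weibull hazard)
    gg_k1: float = 1.0 / 16.0  # k when X1 = 1 (bathtub hazard)

    def __post_init__(self) -> None:
        for name in ("shape", "scale", "error_sd", "gg_scale", "gg_shape", "gg_k0", "gg_k1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class DataSet:
    """Observed right-censored triples (y, delta, X), plus latent truth if simulated."""

    y: np.ndarray
    delta: np.ndarray
    X: CovariateMatrix
    t_true: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.delta = np.asarray(self.delta, dtype=int)
        if self.t_true is not None:
            self.t_true = np.asarray(self.t_true, dtype=float)
            if len(self.t_true) != len(self.y):
                raise ValueError("t_true length mismatch")
        if len(self.y) != len(self.delta) or len(self.y) != self.X.n:
            raise ValueError("y, delta, X must share length")
        if np.any(self.y <= 0):
            raise ValueError("observed times must be strictly positive")
        if not np.all(np.isin(self.delta, (0, 1))):
            raise ValueError("delta must be 0/1")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class SurvivalCurve:
    """Right-continuous step function on a sorted grid.

    ``kind='survival'`` carries S(t) (non-increasing, implicit 1 at t=0);
    ``kind='cumulative_hazard'`` carries H(t) (non-decreasing, implicit 0).
    """

    times: np.ndarray
    values: np.ndarray
    kind: Literal["survival", "cumulative_hazard"] = "survival"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times/values length mismatch")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Step-function value at each t (value at t=0 is 1 or 0 by kind)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        base = 1.0 if self.kind == "survival" else 0.0
        padded = np.concatenate(([base], self.values))
        return padded[idx + 1]

    def to_survival(self) -> "SurvivalCurve":
        if self.kind == "survival":
            return self
        return SurvivalCurve(self.times, np.exp(-self.values), kind="survival")


_METHODS = (
    "rsf_logrank",
    "rsf_logrank_score",
    "rsf_cindex",
    "rsf_brier",
    "rsf_l1",
    "rist",
    "rotsf",
    "cif",
)


@dataclass
class ForestSpec:
    """Ensemble hyper-parameters shared by all construction methods.

    mtry=None means ceil(sqrt(p)) resolved at fit time. ``bootstrap=False``
    is a test hook that fits every tree on the full sample.
    """

    method: str = "rsf_logrank"
    n_trees: int = 500
    mtry: Optional[int] = None
    min_node: int = 6
    min_events: int = 1
    rist_folds: int = 1
    cif_alpha: float = 0.05
    cif_permutations: int = 0  # 0 = asymptotic normal reference (fast mode)
    rot_subset_size: int = 3
    seed: int = 0
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {_METHODS}")
        if self.n_trees < 1 or self.min_events < 1 or self.rist_folds < 1:
            raise ValueError("n_trees, min_events, rist_folds must be >= 1")
        if not 0 < self.cif_alpha < 1:
            raise ValueError("cif_alpha must be in (0,1)")


@dataclass
class SNRReport:
    """Pseudo-R^2 and the derived signal-to-noise ratio R^2/(1-R^2)."""

    r2: float
    snr: float
    mc_outer: int
    seed: int


@dataclass
class CensoringCalibration:
    rate: float
    achieved_proportion: float
    target: float
    tolerance: float


@dataclass(frozen=True)
class FLC:
    """One factor-level combination of the simulation design."""

    dgm_y: Literal["weibull", "aft", "gg"]
    dgm_x: Literal["baseline", "poly_int", "sine", "piecewise"]
    censoring: float
    n_train: int
    extra: Literal["baseline", "correlated", "noise"]

    def label(self) -> str:
        return (
            f"{self.dgm_y}/{self.dgm_x}/cens{int(round(self.censoring * 100))}"
            f"/n{self.n_train}/{self.extra}"
        )
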