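"""Synthetic censored time-to-event data generators.

The generators emulate a factorial benchmark for survival forests: ten base
covariates (one Bernoulli, five uniforms, four five-level categoricals),
four linear-predictor shapes (linear, polynomial/interaction, sine,
piecewise-linear), three response families (proportional-hazards Weibull,
lognormal AFT, generalized gamma with crossing hazards), independent
exponential censoring, and optional blocks of unimportant extra covariates
(three correlated with an important covariate, or fifty noise variables).

All latent survival times are drawn by inverse-cdf transforms of U(0,1)
draws, so every dataset is reproducible from a single integer seed with
independent substreams for covariates, response, and censoring.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .types import CovariateMatrix, DataSet, LinearPredictorSpec, ResponseModel

__all__ = [
    "gen_covariates",
    "linear_predictor",
    "draw_survival_times",
    "draw_censoring",
    "assemble_dataset",
    "simulate_dataset",
    "default_coefficients",
    "required_terms",
    "dataset_to_frame",
    "dataset_from_frame",
    "MissingCoefficientError",
    "PIECEWISE_KNOTS",
    "CORRELATED_TARGET",
    "NOISE_BLOCK_TARGET",
    "DESIGNATED_COVARIATE",
]

EXTRA_LEVELS = ("baseline", "correlated", "noise")

#: population Pearson correlation between each correlated extra and X2
CORRELATED_TARGET = 0.75
#: pairwise correlation within the 30-column noise block
NOISE_BLOCK_TARGET = 0.5
#: the "important covariate" the correlated extras shadow
DESIGNATED_COVARIATE = "x2"
#: knots of the piecewise-linear predictor form (range of a U(0,1) covariate)
PIECEWISE_KNOTS = (1.0 / 3.0, 2.0 / 3.0)

# corr(Z, Phi(Z)) for Z ~ N(0,1): latent Gaussian correlation is scaled up by
# its inverse so the *observed* Pearson correlation with the uniform covariate
# hits CORRELATED_TARGET.
_NORMAL_UNIFORM_CORR = np.sqrt(3.0 / np.pi)

DEFAULT_CATEGORICAL_PROBS = (0.2, 0.2, 0.2, 0.2, 0.2)


class MissingCoefficientError(KeyError):
    """A term required by the linear-predictor form has no coefficient."""


def _base_columns(n: int, rng: np.random.Generator, probs) -> tuple[np.ndarray, list, list]:
    cols = [rng.integers(0, 2, size=n).astype(float)]
    kinds = ["binary"]
    names = ["x1"]
    for j in range(2, 7):
        cols.append(rng.random(n))
        kinds.append("uniform")
        names.append(f"x{j}")
    levels = np.arange(1, 6)
    for j in range(7, 11):
        cols.append(rng.choice(levels, size=n, p=probs).astype(float))
        kinds.append("categorical5")
        names.append(f"x{j}")
    return np.column_stack(cols), kinds, names


def gen_covariates(
    n: int,
    extra_level: str = "baseline",
    seed: int | np.random.SeedSequence = 0,
    categorical_probs=DEFAULT_CATEGORICAL_PROBS,
    designated: str = DESIGNATED_COVARIATE,
) -> CovariateMatrix:
    """Draw the base 10-column design plus the requested extra-variable block.

    extra_level:
      - ``baseline``: the ten base covariates only.
      - ``correlated``: appends 3 mean-zero normal columns, each with
        population Pearson correlation 0.75 to the designated important
        covariate (default X2).
      - ``noise``: appends 30 standard normals with pairwise correlation 0.5
        among themselves (independent of everything else) and 20 mutually
        independent standard normals.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if extra_level not in EXTRA_LEVELS:
        raise ValueError(f"unknown extra_level {extra_level!r}; choose from {EXTRA_LEVELS}")
    probs = np.asarray(categorical_probs, dtype=float)
    if probs.shape != (5,) or abs(probs.sum() - 1.0) > 1e-12 or np.any(probs < 0):
        raise ValueError("categorical_probs must be 5 non-negative values summing to 1")

    rng = np.random.default_rng(seed)
    values, kinds, names = _base_columns(n, rng, probs)

    if extra_level == "correlated":
        u = values[:, names.index(designated)]
        z = ndtri(np.clip(u, 1e-12, 1 - 1e-12))
        r = CORRELATED_TARGET / _NORMAL_UNIFORM_CORR
        eps = rng.standard_normal((n, 3))
        extras = r * z[:, None] + np.sqrt(1.0 - r * r) * eps
        values = np.hstack([values, extras])
        kinds += ["extra_correlated"] * 3
        names += [f"z{j}" for j in range(1, 4)]
    elif extra_level == "noise":
        shared = rng.standard_normal(n)
        block = np.sqrt(NOISE_BLOCK_TARGET) * shared[:, None] + np.sqrt(
            1.0 - NOISE_BLOCK_TARGET
        ) * rng.standard_normal((n, 30))
        indep = rng.standard_normal((n, 20))
        values = np.hstack([values, block, indep])
        kinds += ["extra_noise_corr"] * 30 + ["extra_noise_indep"] * 20
        names += [f"w{j}" for j in range(1, 31)] + [f"v{j}" for j in range(1, 21)]

    return CovariateMatrix(values, kinds, names)


# ---------------------------------------------------------------------------
# Linear predictors


def _dummy_terms() -> list[str]:
    return [f"x{j}:{lvl}" for j in range(7, 11) for lvl in range(2, 6)]


def required_terms(form: str) -> list[str]:
    """Term names whose coefficients a LinearPredictorSpec of this form needs."""
    dummies = _dummy_terms()
    if form == "baseline":
        return ["x1", "x2", "x3", "x4", "x5", "x6"] + dummies
    if form == "poly_int":
        return ["x1", "x6", "x2^2", "x3*x4", "x5^2", "x2*x5", "x3*x6"] + dummies
    if form == "sine":
        return ["x1", "sin(2*pi*x2)", "x3", "x4", "x5", "x6"] + dummies
    if form == "piecewise":
        return (
            ["x1", "x4", "x5", "x6"]
            + [f"x2:seg{s}" for s in (1, 2, 3)]
            + [f"x3:seg{s}" for s in (1, 2, 3)]
            + dummies
        )
    raise ValueError(f"unknown linear-predictor form {form!r}")


def default_coefficients(form: str) -> dict[str, float]:
    """Shipped default coefficient table for each linear-predictor form.

    The values are package defaults chosen to give every base covariate a
    non-trivial effect with mixed signs and non-monotone categorical
    patterns; SNR calibration rescales them jointly through signal_scale,
    so only their relative sizes matter. All overridable per spec.
    """
    beta: dict[str, float] = {
        "x1": 1.0,
        "x2": 1.0,
        "x3": -1.0,
        "x4": 0.8,
        "x5": -0.8,
        "x6": 0.6,
        # categoricals: dummy coding, level 1 reference
        "x7:2": 0.5, "x7:3": 1.0, "x7:4": -0.5, "x7:5": -1.0,
        "x8:2": -0.4, "x8:3": 0.4, "x8:4": 0.8, "x8:5": -0.8,
        "x9:2": 0.25, "x9:3": 0.5, "x9:4": 0.75, "x9:5": 1.0,
        "x10:2": -0.25, "x10:3": -0.5, "x10:4": -0.75, "x10:5": -1.0,
    }
    if form == "baseline":
        return beta
    if form == "poly_int":
        for t in ("x2", "x3", "x4", "x5"):
            del beta[t]
        beta.update({"x2^2": 1.5, "x3*x4": -1.5, "x5^2": 1.2, "x2*x5": -1.2, "x3*x6": 1.5})
        return beta
    if form == "sine":
        beta["sin(2*pi*x2)"] = beta.pop("x2")
        return beta
    if form == "piecewise":
        del beta["x2"], beta["x3"]
        beta.update({
            "x2:seg1": 3.0, "x2:seg2": -3.0, "x2:seg3": 3.0,
            "x3:seg1": -3.0, "x3:seg2": 3.0, "x3:seg3": -3.0,
        })
        return beta
    raise ValueError(f"unknown linear-predictor form {form!r}")


def _piecewise(x: np.ndarray, slopes: tuple[float, float, float]) -> np.ndarray:
    """Continuous piecewise-linear function with knots at 1/3 and 2/3."""
    k1, k2 = PIECEWISE_KNOTS
    s1, s2, s3 = slopes
    return (
        s1 * np.minimum(x, k1)
        + s2 * np.clip(x - k1, 0.0, k2 - k1)
        + s3 * np.maximum(x - k2, 0.0)
    )


def linear_predictor(X: CovariateMatrix, spec: LinearPredictorSpec) -> np.ndarray:
    """Evaluate x'beta for the base ten covariates (extras get coefficient 0).

    No intercept is included here; the AFT intercept lives in the response
    model. Categorical effects use dummy coding with level 1 as reference.
    """
    beta = dict(spec.coefficients) if spec.coefficients is not None else default_coefficients(spec.form)
    needed = required_terms(spec.form)
    missing = [t for t in needed if t not in beta]
    if missing:
        raise MissingCoefficientError(f"missing coefficients for terms: {missing}")

    col = X.column
    s = spec.signal_scale
    lp = np.zeros(X.n)
    b = {t: float(beta[t]) for t in needed}

    lp += b["x1"] * col("x1")
    if spec.form == "baseline":
        for t in ("x2", "x3", "x4", "x5", "x6"):
            lp += b[t] * col(t)
    elif spec.form == "poly_int":
        lp += b["x6"] * col("x6")
        lp += b["x2^2"] * col("x2") ** 2
        lp += b["x3*x4"] * col("x3") * col("x4")
        lp += b["x5^2"] * col("x5") ** 2
        lp += b["x2*x5"] * col("x2") * col("x5")
        lp += b["x3*x6"] * col("x3") * col("x6")
    elif spec.form == "sine":
        lp += b["sin(2*pi*x2)"] * np.sin(2.0 * np.pi * col("x2"))
        for t in ("x3", "x4", "x5", "x6"):
            lp += b[t] * col(t)
    elif spec.form == "piecewise":
        for t in ("x4", "x5", "x6"):
            lp += b[t] * col(t)
        lp += _piecewise(col("x2"), (b["x2:seg1"], b["x2:seg2"], b["x2:seg3"]))
        lp += _piecewise(col("x3"), (b["x3:seg1"], b["x3:seg2"], b["x3:seg3"]))

    for j in range(7, 11):
        xj = col(f"x{j}")
        for lvl in range(2, 6):
            lp += b[f"x{j}:{lvl}"] * (xj == lvl)
    return s * lp


# ---------------------------------------------------------------------------
# Response families and censoring


def _clip_u(u: np.ndarray) -> np.ndarray:
    tiny = np.finfo(float).tiny
    return np.clip(u, tiny, 1.0 - 1e-16)


def draw_survival_times(
    lp: np.ndarray,
    model: ResponseModel,
    x1: Optional[np.ndarray] = None,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Inverse-cdf draws of the latent survival time T given the linear predictor.

    weibull_ph:    t = (-log u / (lambda * exp(lp)))^(1/rho)
    lognormal_aft: t = exp(intercept + lp + sigma * Phi^{-1}(u))
    gen_gamma:     t = a*exp(lp) * Q_gamma(u; k)^(1/b) with k chosen by x1;
                   k = 1 reduces to Weibull(a*exp(lp), b).
    """
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor contains non-finite entries")
    rng = np.random.default_rng(seed)
    u = _clip_u(rng.random(len(lp)))

    if model.family == "weibull_ph":
        return (-np.log(u) / (model.scale * np.exp(lp))) ** (1.0 / model.shape)
    if model.family == "lognormal_aft":
        return np.exp(model.intercept + lp + model.error_sd * ndtri(u))
    if model.family == "gen_gamma":
        if x1 is None:
            raise ValueError("gen_gamma requires the binary covariate x1")
        x1 = np.asarray(x1)
        if len(x1) != len(lp):
            raise ValueError("x1 length mismatch")
        k = np.where(x1 == 1, model.gg_k1, model.gg_k0)
        g = stats.gamma.ppf(u, a=k)
        t = model.gg_scale * np.exp(lp) * np.power(g, 1.0 / model.gg_shape)
        return np.maximum(t, np.finfo(float).tiny)
    raise ValueError(f"unknown family {model.family!r}")


def draw_censoring(n: int, rate: float, seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """i.i.d. exponential censoring times with the given rate parameter."""
    if rate <= 0:
        raise ValueError("censoring rate must be > 0")
    rng = np.random.default_rng(seed)
    return rng.exponential(scale=1.0 / rate, size=n)


def assemble_dataset(t: np.ndarray, c: np.ndarray, X: CovariateMatrix) -> DataSet:
    """Combine latent event and censoring times: y = min(t,c), delta = 1(t <= c)."""
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if len(t) != len(c) or len(t) != X.n:
        raise ValueError("t, c, X must share length")
    y = np.minimum(t, c)
    delta = (t <= c).astype(int)
    return DataSet(y=y, delta=delta, X=X, t_true=t)


def simulate_dataset(
    n: int,
    model: ResponseModel,
    spec: LinearPredictorSpec,
    censoring_rate: Optional[float],
    extra_level: str = "baseline",
    seed: int | np.random.SeedSequence = 0,
) -> DataSet:
    """One benchmark dataset: covariates, latent times, censoring, assembly.

    The master seed is split into independent substreams for covariates,
    response, and censoring, so each component is independently replayable.
    ``censoring_rate=None`` disables censoring (delta all 1).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_x, ss_t, ss_c = ss.spawn(3)
    X = gen_covariates(n, extra_level, seed=ss_x)
    lp = linear_predictor(X, spec)
    t = draw_survival_times(lp, model, x1=X.column("x1"), seed=ss_t)
    if censoring_rate is None:
        c = np.full(n, np.inf)
    else:
        c = draw_censoring(n, censoring_rate, seed=ss_c)
    return assemble_dataset(t, c, X)


# ---------------------------------------------------------------------------
# Delimited-table I/O (CLI + user datasets)


def dataset_to_frame(data: DataSet) -> pd.DataFrame:
    df = pd.DataFrame({"time": data.y, "status": data.delta})
    if data.t_true is not None:
        df["t_true"] = data.t_true
    for j, name in enumerate(data.X.names):
        df[name] = data.X.values[:, j]
    return df


def dataset_from_frame(df: pd.DataFrame, kinds: Optional[list[str]] = None) -> DataSet:
    """Read (time, status, covariates) from a delimited table.

    Column kinds are taken from the given list, or inferred: integer 0/1
    columns -> binary, integer columns with <= 5 levels in 1..5 ->
    categorical5, everything else -> uniform (treated as plain numeric).
    """
    cov_cols = [c for c in df.columns if c not in ("time", "status", "t_true")]
    values = df[cov_cols].to_numpy(dtype=float)
    if kinds is None:
        kinds = []
        for j, c in enumerate(cov_cols):
            v = values[:, j]
            if np.all(np.isin(v, (0.0, 1.0))):
                kinds.append("binary")
            elif np.all(v == np.round(v)) and np.all((v >= 1) & (v <= 5)):
                kinds.append("categorical5")
            else:
                kinds.append("uniform")
    X = CovariateMatrix(values, kinds, list(cov_cols))
    t_true = df["t_true"].to_numpy(dtype=float) if "t_true" in df.columns else None
    return DataSet(
        y=df["time"].to_numpy(dtype=float),
        delta=df["status"].to_numpy(dtype=int),
        X=X,
        t_true=t_true,
    )
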