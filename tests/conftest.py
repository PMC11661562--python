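"""Shared fixtures: calibrated study cells and small reusable datasets."""

from __future__ import annotations

import numpy as np
import pytest

import survbench as sb
from survbench import calibration as cal
from survbench.types import LinearPredictorSpec, ResponseModel

CAL_MC = 50_000  # Monte-Carlo size for fixture calibration


@pytest.fixture(scope="session")
def weibull_baseline_cell():
    """Weibull-PH / linear-predictor baseline cell calibrated to SNR 1,
    with censoring rates for the 10% and 70% levels."""
    model = ResponseModel(family="weibull_ph")
    spec = LinearPredictorSpec(form="baseline")
    model, spec = cal.calibrate_signal(model, spec, target_snr=1.0, mc_outer=CAL_MC, seed=5)
    rate10 = cal.calibrate_censoring_rate(model, spec, 0.10, tol=0.001, mc=CAL_MC, seed=6).rate
    return {"model": model, "spec": spec, "rate10": rate10}


@pytest.fixture(scope="session")
def small_censored_dataset():
    """A 150-row single-signal dataset with ~35% censoring (no study DGM)."""
    rng = np.random.default_rng(7)
    n = 150
    X = sb.CovariateMatrix(rng.random((n, 4)), ["uniform"] * 4, ["a", "b", "c", "d"])
    t = rng.exponential(np.exp(1.5 * X.values[:, 0])) + 1e-9
    c = rng.exponential(2.0, n)
    return sb.DataSet(y=np.minimum(t, c), delta=(t <= c).astype(int), X=X, t_true=t)


@pytest.fixture(scope="session")
def train_test_200(weibull_baseline_cell):
    m, s, r = (weibull_baseline_cell[k] for k in ("model", "spec", "rate10"))
    train = sb.simulate_dataset(200, m, s, r, seed=11)
    test = sb.simulate_dataset(200, m, s, r, seed=12)
    return train, test
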