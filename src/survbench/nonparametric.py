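"""Kaplan-Meier and Nelson-Aalen step estimators.

These are the terminal-node summaries of every tree in the engine, so they
are implemented here directly on sorted arrays (no per-call object overhead)
and cross-checked against lifelines in the test suite.
"""

from __future__ import annotations

import numpy as np

from .types import SurvivalCurve

__all__ = ["event_table", "kaplan_meier", "nelson_aalen", "weighted_kaplan_meier"]


def event_table(y: np.ndarray, delta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique event times with event counts d_j and at-risk counts n_j."""
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta)
    if len(y) == 0:
        raise ValueError("empty input")
    times, counts = np.unique(y[delta == 1], return_counts=True)
    # at risk at t-: y_i >= t_j
    order = np.sort(y)
    n_at_risk = len(y) - np.searchsorted(order, times, side="left")
    return times, counts.astype(float), n_at_risk.astype(float)


def kaplan_meier(y: np.ndarray, delta: np.ndarray) -> SurvivalCurve:
    """Product-limit estimate S(t) = prod_{t_j <= t} (1 - d_j/n_j)."""
    times, d, n = event_table(y, delta)
    s = np.cumprod(1.0 - d / n)
    return SurvivalCurve(times=times, values=s, kind="survival")


def nelson_aalen(y: np.ndarray, delta: np.ndarray) -> SurvivalCurve:
    """Cumulative hazard estimate H(t) = sum_{t_j <= t} d_j/n_j."""
    times, d, n = event_table(y, delta)
    h = np.cumsum(d / n)
    return SurvivalCurve(times=times, values=h, kind="cumulative_hazard")


def weighted_kaplan_meier(y: np.ndarray, delta: np.ndarray, weights: np.ndarray) -> SurvivalCurve:
    """Kaplan-Meier with subject weights (nearest-neighbour forest aggregation)."""
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta)
    w = np.asarray(weights, dtype=float)
    keep = w > 0
    y, delta, w = y[keep], delta[keep], w[keep]
    if len(y) == 0:
        raise ValueError("all weights are zero")
    times = np.unique(y[delta == 1])
    if len(times) == 0:
        return SurvivalCurve(times=np.array([np.max(y)]), values=np.array([1.0]), kind="survival")
    order = np.argsort(y)
    y_s, w_s = y[order], w[order]
    cum_w = np.concatenate(([0.0], np.cumsum(w_s)))
    total = cum_w[-1]
    n_at_risk = total - cum_w[np.searchsorted(y_s, times, side="left")]
    ev = delta == 1
    idx = np.searchsorted(times, y[ev])
    dw = np.bincount(idx, weights=w[ev], minlength=len(times))
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(n_at_risk > 0, 1.0 - dw / n_at_risk, 1.0)
    s = np.cumprod(np.clip(factors, 0.0, 1.0))
    return SurvivalCurve(times=times, values=s, kind="survival")
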