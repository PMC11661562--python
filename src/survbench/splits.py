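"""Vectorized split statistics for survival tree construction.

Every criterion is evaluated simultaneously at all candidate cutpoints of a
covariate: rows are ordered by the covariate and per-cutpoint child
quantities (at-risk and event counts per event time, child survival curves,
pairwise concordance sums) are obtained from prefix cumulative sums. This is
what keeps pure-Python forests affordable at benchmark sample sizes.

Scores are "larger is better"; cutpoints whose children would violate the
node constraints (minimum size, minimum unique events) score -inf and are
never selected.
"""

from __future__ import annotations

import numpy as np

from .nonparametric import event_table, nelson_aalen

__all__ = ["NodeData", "prefix_scores", "split_statistic", "CRITERIA", "INVALID"]

CRITERIA = ("logrank", "logrank_score", "l1", "cindex", "brier")
INVALID = -np.inf


class NodeData:
    """Precomputed per-node arrays shared across candidate covariates."""

    def __init__(self, y: np.ndarray, delta: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.delta = np.asarray(delta, dtype=int)
        self.n = len(self.y)
        if self.n == 0:
            raise ValueError("empty node")
        self.times, self.d, self.n_risk = event_table(self.y, self.delta)
        self.m = len(self.times)
        # event-time index of each row (-1 for censored rows)
        self.ev_idx = np.where(
            self.delta == 1, np.searchsorted(self.times, self.y) if self.m else -1, -1
        )
        self._at_risk: np.ndarray | None = None
        self._event: np.ndarray | None = None
        self._lr_scores: np.ndarray | None = None
        self._pair_A: np.ndarray | None = None
        self._pair_B: np.ndarray | None = None
        self._perm_total: float | None = None
        self._ygrid: np.ndarray | None = None
        self._y_le: np.ndarray | None = None

    # -- lazily built shared structures ------------------------------------

    @property
    def at_risk(self) -> np.ndarray:
        """(n, m) float32 indicator y_i >= t_j."""
        if self._at_risk is None:
            self._at_risk = (self.y[:, None] >= self.times[None, :]).astype(np.float32)
        return self._at_risk

    @property
    def event(self) -> np.ndarray:
        """(n, m) float32 indicator of row i having its event at t_j."""
        if self._event is None:
            ev = np.zeros((self.n, self.m), dtype=np.float32)
            rows = np.nonzero(self.ev_idx >= 0)[0]
            ev[rows, self.ev_idx[rows]] = 1.0
            self._event = ev
        return self._event

    @property
    def logrank_scores(self) -> np.ndarray:
        """Log-rank (Hothorn-Lausen) scores a_i = delta_i - H_NA(y_i)."""
        if self._lr_scores is None:
            if self.m == 0:
                self._lr_scores = self.delta.astype(float)
            else:
                na = nelson_aalen(self.y, self.delta)
                self._lr_scores = self.delta - na.evaluate(self.y)
        return self._lr_scores

    def _pair_matrices(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Concordance contribution matrices for the C-index criterion.

        A[i,j]: contribution of pair (i in left, j in right) with the left
        child carrying the smaller predicted value. B[i,j]: contribution when
        i and j fall in the same child (equal predictions). Pairs follow the
        Harrell permissibility rule: drop pairs whose shorter observed time
        is censored and tied pairs that are both censored.
        """
        if self._pair_A is None:
            y, d = self.y, self.delta
            yi, yj = y[:, None], y[None, :]
            di, dj = d[:, None], d[None, :]
            lt, eq = yi < yj, yi == yj
            perm = (lt & (di == 1)) | ((yi > yj) & (dj == 1)) | (eq & ((di + dj) >= 1))
            np.fill_diagonal(perm, False)
            A = perm * (1.0 * lt + 0.5 * eq)
            B = perm * (0.5 * (~eq) + 1.0 * eq)
            self._pair_A, self._pair_B = A, B
            self._perm_total = float(perm.sum()) / 2.0  # unordered pairs
        return self._pair_A, self._pair_B, self._perm_total

    def _y_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """All unique observed times and the (n, G) matrix 1(y_i <= u_g)."""
        if self._ygrid is None:
            self._ygrid = np.unique(self.y)
            self._y_le = self.y[:, None] <= self._ygrid[None, :]
        return self._ygrid, self._y_le


def _child_km(dL: np.ndarray, nL: np.ndarray) -> np.ndarray:
    """KM curves of left children for every prefix: (cuts, m) cumprod."""
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(nL > 0, 1.0 - dL / np.maximum(nL, 1.0), 1.0)
    return np.cumprod(factors, axis=1)


def _prefix_square_sum(M: np.ndarray) -> np.ndarray:
    """s_k = sum of M[:k+1, :k+1] for each k, via double cumulative sums."""
    return np.diag(np.cumsum(np.cumsum(M, axis=0), axis=1)).copy()


def prefix_scores(
    node: NodeData,
    order: np.ndarray,
    criterion: str,
    min_node: int = 1,
    min_events: int = 1,
) -> np.ndarray:
    """Split score for every prefix cut of the given row ordering.

    Entry k scores the split {order[:k+1]} vs {order[k+1:]}, k = 0..n-2.
    Constraint-violating cuts get -inf. The caller is responsible for
    restricting to positions where the covariate value actually changes.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown split criterion {criterion!r}")
    n, m = node.n, node.m
    if n < 2 or m == 0:
        return np.full(max(n - 1, 0), INVALID)

    sizes_L = np.arange(1, n)
    sizes_R = n - sizes_L

    # unique event times per child, tracked by first/last-occurrence flags of
    # each event time along the candidate ordering (no (n, m) matrix needed)
    ev = node.ev_idx[order]
    rows = np.nonzero(ev >= 0)[0]
    jj = ev[rows]
    grp = np.lexsort((rows, jj))
    r_sorted, j_sorted = rows[grp], jj[grp]
    boundary_flags = np.ones(len(grp), dtype=bool)
    boundary_flags[1:] = j_sorted[1:] != j_sorted[:-1]
    first = np.zeros(n)
    first[r_sorted[boundary_flags]] = 1.0
    last_flags = np.ones(len(grp), dtype=bool)
    last_flags[:-1] = j_sorted[1:] != j_sorted[:-1]
    last = np.zeros(n)
    last[r_sorted[last_flags]] = 1.0
    uniq_L = np.cumsum(first)[:-1]
    uniq_R = m - np.cumsum(last)[:-1]

    valid = (
        (sizes_L >= min_node)
        & (sizes_R >= min_node)
        & (uniq_L >= min_events)
        & (uniq_R >= min_events)
    )
    kidx = np.nonzero(valid)[0]
    scores = np.full(n - 1, INVALID)
    if len(kidx) == 0:
        return scores

    if criterion == "logrank":
        # numerator O-E at cut k is the prefix sum of the log-rank scores
        a = node.logrank_scores
        o_minus_e = np.cumsum(a[order])[:-1][kidx]
        nL = np.cumsum(node.at_risk[order], axis=0, dtype=np.float64)[:-1][kidx]
        with np.errstate(divide="ignore", invalid="ignore"):
            vterm = np.where(
                node.n_risk > 1,
                node.d * (node.n_risk - node.d) / (node.n_risk - 1),
                0.0,
            )
        # var = sum_j vterm_j * f(1-f), f = nL/n_j, as two BLAS mat-vecs
        c1 = vterm / node.n_risk
        c2 = vterm / node.n_risk**2
        var = nL @ c1 - (nL * nL) @ c2
        scores[kidx] = np.where(
            var > 0, np.abs(o_minus_e) / np.sqrt(np.maximum(var, 1e-300)), INVALID
        )

    elif criterion == "logrank_score":
        a = node.logrank_scores
        abar, s2 = float(np.mean(a)), float(np.var(a))
        SL = np.cumsum(a[order])[:-1][kidx]
        var = sizes_L[kidx] * sizes_R[kidx] / (n - 1.0) * s2
        scores[kidx] = np.where(
            var > 0, np.abs(SL - sizes_L[kidx] * abar) / np.sqrt(np.maximum(var, 1e-300)), INVALID
        )

    elif criterion == "l1":
        if m < 2:
            scores[kidx] = 0.0
            return scores
        dL = np.cumsum(node.event[order], axis=0, dtype=np.float64)[:-1][kidx]
        dR = node.d[None, :] - dL
        nL = np.cumsum(node.at_risk[order], axis=0, dtype=np.float64)[:-1][kidx]
        nR = node.n_risk[None, :] - nL
        S_L = _child_km(dL, nL)
        S_R = _child_km(dR, nR)
        dt = np.diff(node.times)
        scores[kidx] = np.sum(np.abs(S_L - S_R)[:, :-1] * dt[None, :], axis=1)

    elif criterion == "cindex":
        A, B, perm_total = node._pair_matrices()
        if perm_total == 0:
            return np.full(n - 1, INVALID)
        A_o = A[np.ix_(order, order)]
        B_o = B[np.ix_(order, order)]
        row_A = np.cumsum(A_o.sum(axis=1))[:-1][kidx]
        colcum_A = np.cumsum(A_o, axis=0)[kidx]
        pref_A = np.cumsum(colcum_A, axis=1)[np.arange(len(kidx)), kidx]
        cross_A = row_A - pref_A  # sum over i in L, j in R of A[i,j]
        row_B = np.cumsum(B_o.sum(axis=1))[:-1][kidx]
        colcum_B = np.cumsum(B_o, axis=0)[kidx]
        pref_B = np.cumsum(colcum_B, axis=1)[np.arange(len(kidx)), kidx]
        total_B = float(B_o.sum())
        within_L = pref_B / 2.0
        within_R = (total_B - 2.0 * row_B + pref_B) / 2.0
        C = (cross_A + within_L + within_R) / perm_total
        scores[kidx] = np.maximum(C, 1.0 - C)

    else:  # brier
        ygrid, y_le = node._y_grid()
        w = float(ygrid[-1])
        du = np.diff(ygrid)
        if len(du) == 0 or w <= 0:
            scores[kidx] = 0.0
            return scores
        dL = np.cumsum(node.event[order], axis=0, dtype=np.float64)[:-1][kidx]
        dR = node.d[None, :] - dL
        nL_risk = np.cumsum(node.at_risk[order], axis=0, dtype=np.float64)[:-1][kidx]
        nR_risk = node.n_risk[None, :] - nL_risk
        S_L = _child_km(dL, nL_risk)
        S_R = _child_km(dR, nR_risk)
        # survival value on each interval (u_g, u_{g+1}): step at last event <= u_g
        pos = np.searchsorted(node.times, ygrid, side="right") - 1
        SLg = np.where(pos[None, :] >= 0, S_L[:, np.maximum(pos, 0)], 1.0)
        SRg = np.where(pos[None, :] >= 0, S_R[:, np.maximum(pos, 0)], 1.0)
        cum_le = np.cumsum(y_le[order], axis=0, dtype=np.float64)[:-1][kidx]  # (K, G)
        szL = sizes_L[kidx][:, None]
        szR = sizes_R[kidx][:, None]
        NL = szL - cum_le  # left rows with y > u_g
        NR = szR - (y_le.sum(axis=0)[None, :] - cum_le)
        integrand = (
            NL * (1.0 - 2.0 * SLg) + szL * SLg**2
            + NR * (1.0 - 2.0 * SRg) + szR * SRg**2
        )
        total = np.sum(integrand[:, :-1] * du[None, :], axis=1)
        scores[kidx] = -total / (n * w)

    return scores


def split_statistic(y: np.ndarray, delta: np.ndarray, left_mask: np.ndarray, criterion: str) -> float:
    """Score one explicit binary split (larger = better).

    Children with zero events score -inf (the invalid-split sentinel).
    """
    left_mask = np.asarray(left_mask, dtype=bool)
    if not left_mask.any() or left_mask.all():
        raise ValueError("both children must be non-empty")
    node = NodeData(np.asarray(y, float), np.asarray(delta))
    order = np.argsort(~left_mask, kind="stable")  # left rows first
    k = int(left_mask.sum()) - 1
    scores = prefix_scores(node, order, criterion, min_node=1, min_events=1)
    return float(scores[k])


def logrank_at_cut(node: NodeData, order: np.ndarray, k: int) -> float:
    """Standardized log-rank statistic at a single prefix cut (ERT path)."""
    left = order[: k + 1]
    mask = np.zeros(node.n, dtype=bool)
    mask[left] = True
    dL = node.event[mask].sum(axis=0).astype(float)
    nL = node.at_risk[mask].sum(axis=0).astype(float)
    frac = nL / node.n_risk
    o_minus_e = float(np.sum(dL - node.d * frac))
    with np.errstate(divide="ignore", invalid="ignore"):
        vterm = np.where(node.n_risk > 1, node.d * (node.n_risk - node.d) / (node.n_risk - 1), 0.0)
    var = float(np.sum(vterm * frac * (1.0 - frac)))
    if var <= 0 or (dL > 0).sum() < 1 or ((node.d - dL) > 0).sum() < 1:
        return INVALID
    return abs(o_minus_e) / np.sqrt(var)
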