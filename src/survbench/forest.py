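"""Survival tree ensembles: RSF variants, RIST, RotSF, and CIF.

All methods share one recursive tree grower and differ in how trees see the
data (bootstrap, subsample, rotated features, imputed times), how candidate
splits are scored (log-rank, log-rank score, L1, C-index, Brier, random
cutpoints, permutation-test screening), and how trees are aggregated
(mean cumulative hazard vs nearest-neighbour weighted Kaplan-Meier).

Determinism contract: every source of randomness derives from
ForestSpec.seed through numpy SeedSequence spawning, with separate
substreams per tree for bootstrap, rotation, and growth, so refitting with
the same spec replays byte-identical forests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.stats import norm

from . import splits as sp
from .nonparametric import kaplan_meier, nelson_aalen, weighted_kaplan_meier
from .types import CovariateMatrix, DataSet, ForestSpec, SurvivalCurve

__all__ = [
    "FittedForest",
    "fit_forest",
    "fit_rsf",
    "fit_rist",
    "fit_rotsf",
    "fit_cif",
    "grow_tree",
    "impute_censored",
    "predict_survival",
    "predict_median",
]

_RSF_CRITERIA = {
    "rsf_logrank": "logrank",
    "rsf_logrank_score": "logrank_score",
    "rsf_cindex": "cindex",
    "rsf_brier": "brier",
    "rsf_l1": "l1",
}

CATEGORICAL_LEVELS = np.arange(1.0, 6.0)


# ---------------------------------------------------------------------------
# Tree structures


@dataclass
class _Split:
    feature: int
    threshold: float = np.nan           # numeric: x <= threshold goes left
    left_levels: Optional[np.ndarray] = None  # categorical: bool mask over levels 1..5
    majority_left: bool = True          # routing rule for unseen levels


@dataclass
class _Node:
    split: Optional[_Split] = None
    left: Optional["_Node"] = None
    right: Optional["_Node"] = None
    # terminal payload
    curve_times: Optional[np.ndarray] = None
    curve_values: Optional[np.ndarray] = None  # CHF (rsf/rist/rotsf) or unused for cif
    rows: Optional[np.ndarray] = None          # training row ids (cif aggregation)
    n_unique_events: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class _Tree:
    root: _Node
    rotation: Optional[np.ndarray] = None  # rotsf: encoded-feature rotation matrix
    oob: Optional[np.ndarray] = None       # out-of-bag row mask (bootstrap methods)


@dataclass
class FittedForest:
    trees: list
    method: str
    grid: np.ndarray  # sorted unique observed event times of the training data
    spec: ForestSpec
    kinds: list
    # cif aggregation needs the training responses
    train_y: Optional[np.ndarray] = None
    train_delta: Optional[np.ndarray] = None
    train_n: int = 0
    encoded: bool = False  # trees consume one-hot encoded (rotated) features


# ---------------------------------------------------------------------------
# Helpers


def _ordinalize(xv: np.ndarray, y: np.ndarray, delta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map categorical levels to ranks of their within-level KM median.

    Returns (mapped values, level order) where level_order[r] is the level
    with rank r. Levels are then treated as ordinal for cutpoint search,
    avoiding 2^(L-1) subset enumeration.
    """
    levels = np.unique(xv)
    medians = []
    for lvl in levels:
        m = xv == lvl
        if delta[m].sum() == 0:
            medians.append(np.inf)  # all censored: sort last
        else:
            medians.append(predict_median(kaplan_meier(y[m], delta[m])))
    order = np.argsort(medians, kind="stable")
    level_order = levels[order]
    rank_of = {lvl: r for r, lvl in enumerate(level_order)}
    mapped = np.array([rank_of[v] for v in xv], dtype=float)
    return mapped, level_order


def _terminal(y: np.ndarray, delta: np.ndarray, rows: np.ndarray, cif: bool) -> _Node:
    node = _Node(rows=rows, n_unique_events=len(np.unique(y[delta == 1])))
    if not cif:
        curve = nelson_aalen(y, delta)
        node.curve_times, node.curve_values = curve.times, curve.values
    return node


def _grow(
    y: np.ndarray,
    delta: np.ndarray,
    Xv: np.ndarray,
    kinds: list,
    spec: ForestSpec,
    rng: np.random.Generator,
    criterion: str,
    rows: np.ndarray,
    ert: bool = False,
    cif: bool = False,
) -> _Node:
    """Recursive best-split search; returns the subtree root."""
    n, p = Xv.shape
    mtry = spec.mtry or int(np.ceil(np.sqrt(p)))
    node_data = sp.NodeData(y, delta)
    if n < 2 * spec.min_node or node_data.m < 2 * spec.min_events:
        return _terminal(y, delta, rows, cif)

    cand = np.sort(rng.choice(p, size=min(mtry, p), replace=False))

    if cif:
        chosen = _cif_screen(node_data, Xv, kinds, cand, spec, rng)
        if chosen is None:
            return _terminal(y, delta, rows, cif)
        cand = np.array([chosen])
        criterion = "logrank_score"

    best = (sp.INVALID, None, None, None)  # score, feature, threshold/levels, mask
    for f in cand:
        xv = Xv[:, f]
        categorical = kinds[f] == "categorical5"
        if categorical:
            mapped, level_order = _ordinalize(xv, y, delta)
        else:
            mapped, level_order = xv, None
        order = np.argsort(mapped, kind="stable")
        xs = mapped[order]
        boundary = xs[:-1] < xs[1:]
        if not boundary.any():
            continue
        if ert:
            thr = rng.uniform(xs[0], xs[-1])
            k = int(np.searchsorted(xs, thr, side="right")) - 1
            if k < 0 or k >= n - 1:
                continue
            sizes_ok = (k + 1) >= spec.min_node and (n - k - 1) >= spec.min_node
            score = sp.logrank_at_cut(node_data, order, k) if sizes_ok else sp.INVALID
            if score > best[0]:
                best = _pack_split(best, score, f, k, xs, categorical, level_order, order, n)
        else:
            scores = sp.prefix_scores(node_data, order, criterion, spec.min_node, spec.min_events)
            scores = np.where(boundary, scores, sp.INVALID)
            k = int(np.argmax(scores))
            if scores[k] > best[0]:
                best = _pack_split(best, float(scores[k]), f, k, xs, categorical, level_order, order, n)

    if best[1] is None:
        return _terminal(y, delta, rows, cif)

    _, f, payload, left_mask = best
    split = payload
    node = _Node(split=split)
    lm = left_mask
    node.left = _grow(y[lm], delta[lm], Xv[lm], kinds, spec, rng, criterion, rows[lm], ert, cif)
    node.right = _grow(y[~lm], delta[~lm], Xv[~lm], kinds, spec, rng, criterion, rows[~lm], ert, cif)
    return node


def _pack_split(prev, score, f, k, xs, categorical, level_order, order, n):
    left_mask = np.zeros(n, dtype=bool)
    left_mask[order[: k + 1]] = True
    if categorical:
        # left child holds the levels whose KM-median rank is <= the rank
        # of the last row in the prefix
        max_rank = int(round(xs[k]))
        mask = np.zeros(len(CATEGORICAL_LEVELS), dtype=bool)
        for lvl in level_order[: max_rank + 1]:
            mask[int(lvl) - 1] = True
        split = _Split(feature=int(f), left_levels=mask, majority_left=(k + 1) >= (n - k - 1))
    else:
        thr = 0.5 * (xs[k] + xs[k + 1])
        split = _Split(feature=int(f), threshold=float(thr), majority_left=(k + 1) >= (n - k - 1))
    return (score, int(f), split, left_mask)


def _cif_screen(node_data, Xv, kinds, cand, spec, rng) -> Optional[int]:
    """Permutation-test screen: most significant candidate, or None to stop.

    The association statistic is the standardized linear statistic
    sum_i a_i * g(x_i) with log-rank scores a_i; the default fast mode uses
    the asymptotic normal reference, exact permutation is available via
    spec.cif_permutations > 0. Bonferroni correction over the candidates.
    """
    a = node_data.logrank_scores
    n = node_data.n
    abar = a.mean()
    sa = a - abar
    pvals = np.ones(len(cand))
    for idx, f in enumerate(cand):
        xv = Xv[:, f]
        if kinds[f] == "categorical5":
            xv, _ = _ordinalize(xv, node_data.y, node_data.delta)
        sx = xv - xv.mean()
        denom = np.sqrt(np.sum(sa**2) * np.sum(sx**2) / (n - 1))
        if denom <= 0:
            continue
        t_obs = float(np.sum(a * xv) - n * abar * xv.mean())
        if spec.cif_permutations > 0:
            perms = np.array([
                np.sum(rng.permutation(sa) * sx) for _ in range(spec.cif_permutations)
            ])
            pvals[idx] = (1.0 + np.sum(np.abs(perms) >= abs(t_obs))) / (spec.cif_permutations + 1.0)
        else:
            z = t_obs / denom
            pvals[idx] = 2.0 * norm.sf(abs(z))
    adj = np.minimum(pvals * len(cand), 1.0)
    j = int(np.argmin(adj))
    if adj[j] > spec.cif_alpha:
        return None
    return int(cand[j])


def grow_tree(data: DataSet, spec: ForestSpec, rng: Optional[np.random.Generator] = None) -> _Tree:
    """Grow a single tree on the given data (no resampling)."""
    if data.delta.sum() == 0:
        raise ValueError("cannot grow a survival tree on data with no events")
    rng = rng or np.random.default_rng(spec.seed)
    criterion = _RSF_CRITERIA.get(spec.method, "logrank")
    root = _grow(
        data.y, data.delta, data.X.values, data.X.kinds, spec, rng,
        criterion, rows=np.arange(data.n),
        ert=(spec.method == "rist"), cif=(spec.method == "cif"),
    )
    return _Tree(root=root)


# ---------------------------------------------------------------------------
# Encoding / rotation (RotSF)


def _encode(X: CovariateMatrix) -> tuple[np.ndarray, list]:
    """One-hot encode categorical columns; all other columns pass through."""
    cols, kinds = [], []
    for j, kind in enumerate(X.kinds):
        if kind == "categorical5":
            for lvl in CATEGORICAL_LEVELS:
                cols.append((X.values[:, j] == lvl).astype(float))
                kinds.append("uniform")
        else:
            cols.append(X.values[:, j])
            kinds.append("uniform")
    return np.column_stack(cols), kinds


def _rotation_matrix(Xb: np.ndarray, subset_size: int, rng: np.random.Generator) -> np.ndarray:
    """Block-diagonal principal-axes rotation on a random column partition.

    Each random subset of encoded columns gets the eigenvector matrix of its
    sample covariance (on the bootstrap sample); subsets containing a
    constant column fall back to the identity block. Column positions are
    preserved, so the rotation matrix is orthogonal but scatters each
    block's loadings to the subset's original column indices.
    """
    p = Xb.shape[1]
    perm = rng.permutation(p)
    R = np.zeros((p, p))
    for start in range(0, p, subset_size):
        idx = perm[start : start + subset_size]
        block = Xb[:, idx]
        if len(idx) == 1 or np.any(block.std(axis=0) == 0):
            Q = np.eye(len(idx))
        else:
            cov = np.cov(block, rowvar=False)
            _, Q = np.linalg.eigh(cov)
        R[np.ix_(idx, idx)] = Q
    return R


# ---------------------------------------------------------------------------
# Forest fitting


def _tree_streams(seed: int, n_trees: int):
    return [ss.spawn(3) for ss in np.random.SeedSequence(seed).spawn(n_trees)]


def _training_grid(data: DataSet) -> np.ndarray:
    return np.unique(data.y[data.delta == 1])


def fit_rsf(data: DataSet, spec: ForestSpec) -> FittedForest:
    """B bootstrap samples, one tree each, with the spec's split criterion."""
    if spec.method not in _RSF_CRITERIA:
        raise ValueError(f"fit_rsf expects an rsf_* method, got {spec.method!r}")
    trees = []
    for ss_boot, _ss_rot, ss_grow in _tree_streams(spec.seed, spec.n_trees):
        if spec.bootstrap:
            idx = np.random.default_rng(ss_boot).integers(0, data.n, size=data.n)
            oob = ~np.isin(np.arange(data.n), idx)
        else:
            idx = np.arange(data.n)
            oob = np.zeros(data.n, dtype=bool)
        sub = DataSet(data.y[idx], data.delta[idx], CovariateMatrix(
            data.X.values[idx], data.X.kinds, data.X.names))
        tree = grow_tree(sub, spec, rng=np.random.default_rng(ss_grow))
        tree.oob = oob
        trees.append(tree)
    return FittedForest(trees=trees, method=spec.method, grid=_training_grid(data),
                        spec=spec, kinds=list(data.X.kinds), train_n=data.n)


def fit_rotsf(data: DataSet, spec: ForestSpec) -> FittedForest:
    """Per-tree principal-components rotations of random feature subsets.

    Categoricals are one-hot encoded before rotation; each tree bootstraps,
    computes its block rotation on the bootstrap sample, rotates the full
    encoded matrix, and grows a log-rank tree on the rotated features.
    """
    Xe, kinds_e = _encode(data.X)
    grow_spec = replace(spec, method="rsf_logrank")
    trees = []
    for ss_boot, ss_rot, ss_grow in _tree_streams(spec.seed, spec.n_trees):
        if spec.bootstrap:
            idx = np.random.default_rng(ss_boot).integers(0, data.n, size=data.n)
        else:
            idx = np.arange(data.n)
        R = _rotation_matrix(Xe[idx], spec.rot_subset_size, np.random.default_rng(ss_rot))
        Xr = Xe @ R
        root = _grow(
            data.y[idx], data.delta[idx], Xr[idx], kinds_e, grow_spec,
            np.random.default_rng(ss_grow), "logrank", rows=np.arange(len(idx)),
        )
        trees.append(_Tree(root=root, rotation=R))
    return FittedForest(trees=trees, method="rotsf", grid=_training_grid(data),
                        spec=spec, kinds=kinds_e, train_n=data.n, encoded=True)


def fit_cif(data: DataSet, spec: ForestSpec) -> FittedForest:
    """Conditional-inference forest: test-based stopping, subsampling,
    nearest-neighbour weighted Kaplan-Meier aggregation."""
    m = int(np.floor(0.632 * data.n))
    trees = []
    for ss_boot, _ss_rot, ss_grow in _tree_streams(spec.seed, spec.n_trees):
        idx = np.random.default_rng(ss_boot).permutation(data.n)[:m] if spec.bootstrap else np.arange(data.n)
        root = _grow(
            data.y[idx], data.delta[idx], data.X.values[idx], data.X.kinds, spec,
            np.random.default_rng(ss_grow), "logrank_score", rows=idx, cif=True,
        )
        trees.append(_Tree(root=root))
    return FittedForest(trees=trees, method="cif", grid=_training_grid(data), spec=spec,
                        kinds=list(data.X.kinds), train_y=data.y.copy(),
                        train_delta=data.delta.copy(), train_n=data.n)


def impute_censored(data: DataSet, forest: FittedForest, rng: np.random.Generator) -> DataSet:
    """Replace censored times by draws from the ensemble conditional survival
    distribution truncated to (c_i, inf); uncensored rows are untouched.

    Inverse-cdf sampling on the step function: the imputed time is the first
    grid time beyond c_i where S(t)/S(c_i) drops to or below the uniform
    draw; remaining tail mass maps to the last grid time. If the estimated
    conditional survival never drops (or the grid ends before c_i) the
    fallback is the largest grid time, floored just above c_i so imputed
    times always exceed the censoring time.
    """
    cens = np.nonzero(data.delta == 0)[0]
    y_new = data.y.astype(float).copy()
    if len(cens):
        Xc = CovariateMatrix(data.X.values[cens], data.X.kinds, data.X.names)
        curves = predict_survival(forest, Xc)
        grid = forest.grid
        for row, curve in zip(cens, curves):
            c_i = data.y[row]
            s_c = float(curve.evaluate(np.array([c_i]))[0])
            u = rng.random()
            target = u * s_c
            elig = (grid > c_i) & (curve.values <= target)
            if elig.any():
                t_imp = float(grid[np.argmax(elig)])
            else:
                t_imp = float(grid[-1]) if len(grid) else c_i
            y_new[row] = max(t_imp, np.nextafter(c_i, np.inf))
    return DataSet(y=y_new, delta=np.ones(data.n, dtype=int), X=data.X, t_true=data.t_true)


def fit_rist(data: DataSet, spec: ForestSpec) -> FittedForest:
    """Recursively imputed survival trees.

    Extremely randomized trees (one random cutpoint per candidate, best by
    log-rank) are fit on the full sample; the ensemble imputes every
    censored time from its conditional survival distribution, and the
    ensemble is refit on the imputed (fully uncensored) data. Imputation +
    refit repeats rist_folds times; predictions come from the final round.
    Each round reuses the same tree seed substreams, so on fully uncensored
    data the refit replays the initial ensemble exactly.
    """
    ss = np.random.SeedSequence(spec.seed)
    ss_trees, ss_imp = ss.spawn(2)
    tree_seed = ss_trees.generate_state(1)[0] % (2**31)
    ert_spec = replace(spec, method="rist", bootstrap=False, seed=int(tree_seed))

    def fit_round(d: DataSet) -> FittedForest:
        trees = []
        for _ss_boot, _ss_rot, ss_grow in _tree_streams(ert_spec.seed, spec.n_trees):
            tree = _Tree(root=_grow(
                d.y, d.delta, d.X.values, d.X.kinds, ert_spec,
                np.random.default_rng(ss_grow), "logrank",
                rows=np.arange(d.n), ert=True,
            ))
            trees.append(tree)
        return FittedForest(trees=trees, method="rist", grid=_training_grid(d), spec=spec,
                            kinds=list(d.X.kinds), train_n=d.n)

    forest = fit_round(data)
    imp_rngs = [np.random.default_rng(s) for s in ss_imp.spawn(spec.rist_folds)]
    current = data
    for r in range(spec.rist_folds):
        current = impute_censored(current, forest, imp_rngs[r])
        forest = fit_round(current)
    return forest


def fit_forest(data: DataSet, spec: ForestSpec) -> FittedForest:
    """Dispatch to the construction method named in the spec."""
    if spec.method in _RSF_CRITERIA:
        return fit_rsf(data, spec)
    if spec.method == "rist":
        return fit_rist(data, spec)
    if spec.method == "rotsf":
        return fit_rotsf(data, spec)
    if spec.method == "cif":
        return fit_cif(data, spec)
    raise ValueError(f"unknown method {spec.method!r}")


# ---------------------------------------------------------------------------
# Prediction


def _route(node: _Node, Xv: np.ndarray, idx: np.ndarray, out: list) -> None:
    if node.is_leaf:
        out.append((node, idx))
        return
    s = node.split
    xv = Xv[idx, s.feature]
    if s.left_levels is not None:
        lv = np.round(xv).astype(int) - 1
        known = (lv >= 0) & (lv < len(s.left_levels))
        go_left = np.where(known, s.left_levels[np.clip(lv, 0, len(s.left_levels) - 1)],
                           s.majority_left)
    else:
        go_left = xv <= s.threshold
    if go_left.any():
        _route(node.left, Xv, idx[go_left], out)
    if (~go_left).any():
        _route(node.right, Xv, idx[~go_left], out)


def _leaf_assignments(tree: _Tree, Xv: np.ndarray) -> list:
    out: list = []
    _route(tree.root, Xv, np.arange(Xv.shape[0]), out)
    return out


def _chf_on_grid(node: _Node, grid: np.ndarray) -> np.ndarray:
    pos = np.searchsorted(node.curve_times, grid, side="right") - 1
    padded = np.concatenate(([0.0], node.curve_values))
    return padded[pos + 1]


def predict_survival(forest: FittedForest, Xnew: CovariateMatrix) -> list:
    """Per-subject survival curves on the training event-time grid.

    RSF-family / RIST / RotSF: ensemble mean cumulative hazard across trees,
    reported as S = exp(-Hbar). CIF: nearest-neighbour weighted Kaplan-Meier,
    with each training row weighted by the fraction of trees in which it is
    co-terminal with the query.
    """
    if Xnew.kinds != forest.kinds and not forest.encoded:
        if Xnew.values.shape[1] != len(forest.kinds):
            raise ValueError("query columns do not match training columns")
    grid = forest.grid
    nq = Xnew.n
    Xq = _encode(Xnew)[0] if forest.encoded else Xnew.values

    if forest.method == "cif":
        weights = np.zeros((nq, forest.train_n))
        for tree in forest.trees:
            for leaf, idx in _leaf_assignments(tree, Xq):
                weights[np.ix_(idx, leaf.rows)] += 1.0 / len(leaf.rows)
        weights /= len(forest.trees)
        curves = []
        for i in range(nq):
            km = weighted_kaplan_meier(forest.train_y, forest.train_delta, weights[i])
            curves.append(SurvivalCurve(grid, km.evaluate(grid), kind="survival"))
        return curves

    H = np.zeros((nq, len(grid)))
    for tree in forest.trees:
        Xt = Xq @ tree.rotation if tree.rotation is not None else Xq
        for leaf, idx in _leaf_assignments(tree, Xt):
            H[idx] += _chf_on_grid(leaf, grid)
    H /= len(forest.trees)
    return [SurvivalCurve(grid, np.exp(-H[i]), kind="survival") for i in range(nq)]


def predict_cif_weights(forest: FittedForest, Xnew: CovariateMatrix) -> np.ndarray:
    """Nearest-neighbour training-row weights per query (rows sum to 1)."""
    if forest.method != "cif":
        raise ValueError("weights are defined for cif forests only")
    Xq = Xnew.values
    weights = np.zeros((Xnew.n, forest.train_n))
    for tree in forest.trees:
        for leaf, idx in _leaf_assignments(tree, Xq):
            weights[np.ix_(idx, leaf.rows)] += 1.0 / len(leaf.rows)
    return weights / len(forest.trees)


def predict_median(curve: SurvivalCurve) -> float:
    """Smallest grid time with S <= 0.5; if S stays above 0.5, the largest
    grid time (the maximum available quantile)."""
    if len(curve) == 0:
        raise ValueError("empty survival curve")
    s = curve.to_survival()
    below = s.values <= 0.5
    if below.any():
        return float(s.times[np.argmax(below)])
    return float(s.times[-1])


def predict_medians(forest: FittedForest, Xnew: CovariateMatrix) -> np.ndarray:
    return np.array([predict_median(c) for c in predict_survival(forest, Xnew)])


def terminal_nodes(tree: _Tree) -> list:
    out, stack = [], [tree.root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            out.append(node)
        else:
            stack.extend([node.left, node.right])
    return out
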