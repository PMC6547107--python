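"""Reinforcement-learning-tree (RLT) regression forest with variable muting.

Each tree is grown by *embedded* split selection: at every internal node a
small internal ensemble is fit on the node's data and the node splits on the
variable that ensemble ranks most important, at the variance-minimizing
cutpoint.  After the split, the lowest-ranked fraction ``muting_rate`` of the
remaining candidate variables is muted — removed from the candidate set of
both children — so a variable judged uninformative in a region of covariate
space has its effect set exactly to zero everywhere below that node.

The embedded ensemble is a bag of regression stumps: each of the
``embedded_trees`` internal learners scores every candidate variable by its
best one-step variance reduction on a bootstrap resample of the node's data,
and a variable's importance is its mean gain across the bag.  Bagging the
one-step lookahead separates persistent signal from variables whose apparent
gain is a quirk of the particular sample, which is what drives muting.  All
bags at a node share one pre-sort of the node's columns, so split selection
costs a handful of vectorized passes per node.

Muting is the mechanism that creates the "muted" treatment group downstream:
when the treatment indicator is muted along every routing path of a
participant, the counterfactual predictions under the two arms are
*identically equal*, not merely close.

With ``muting_rate=0``, ``embedded_trees=1``, ``subsample_frac=1`` and
``n_trees=1`` the estimator collapses to a classic greedy variance-reduction
CART tree: a single embedded learner uses the unweighted node data, so its
top-gain variable and variance-minimizing cutpoint are precisely the greedy
split choice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RLTParams",
    "TreeNode",
    "RLTForest",
    "embedded_importance",
    "fit_tree",
    "fit_forest",
    "predict",
    "path_variables",
]


@dataclass(frozen=True)
class RLTParams:
    """Hyperparameters of the muting forest.

    muting_rate is the fraction of a node's remaining candidate variables
    (split variable excluded) muted from both children; embedded_trees is the
    size of the per-node internal stump ensemble used to rank candidates
    (embedded_trees=1 degenerates to the deterministic greedy one-step
    lookahead).
    """

    n_trees: int = 100
    min_node_size: int = 10
    muting_rate: float = 0.3
    embedded_trees: int = 20
    importance_threshold: float = 3.0
    subsample_frac: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.muting_rate < 1:
            raise ValueError("muting_rate must lie in [0, 1)")
        if self.min_node_size < 2:
            raise ValueError("min_node_size must be >= 2")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.embedded_trees < 1:
            raise ValueError("embedded_trees must be >= 1")
        if self.importance_threshold < 0:
            raise ValueError("importance_threshold must be nonnegative")
        if not 0 < self.subsample_frac <= 1:
            raise ValueError("subsample_frac must lie in (0, 1]")


@dataclass
class TreeNode:
    """Leaf (split_var is None) or internal node of one RLT tree.

    candidate_set lists the variables not yet muted on the path to this node;
    children's candidate sets are subsets of the parent's.
    """

    prediction: float
    n_samples: int
    candidate_set: tuple[int, ...]
    split_var: int | None = None
    split_value: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    def to_dict(self) -> dict:
        d = {
            "prediction": self.prediction,
            "n_samples": self.n_samples,
            "candidate_set": list(self.candidate_set),
        }
        if not self.is_leaf:
            d.update(
                split_var=self.split_var,
                split_value=self.split_value,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(
            prediction=d["prediction"],
            n_samples=d["n_samples"],
            candidate_set=tuple(d["candidate_set"]),
        )
        if "split_var" in d:
            node.split_var = d["split_var"]
            node.split_value = d["split_value"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _best_cut(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Variance-minimizing cutpoint of one variable.

    Returns ``(gain, cut)`` where gain is the reduction in total SSE, or
    ``None`` when no cut leaves at least ``min_leaf`` samples per child.
    Cut values are midpoints between adjacent distinct observed values; score
    ties resolve to the smallest cut.
    """
    n = len(y)
    if n < 2 * min_leaf:
        return None
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    csum = np.cumsum(ys)
    total = csum[-1]
    sizes = np.arange(1, n)  # left-child sizes
    valid = (sizes >= min_leaf) & (sizes <= n - min_leaf) & (xs[1:] > xs[:-1])
    if not valid.any():
        return None
    left_sum = csum[:-1]
    score = left_sum**2 / sizes + (total - left_sum) ** 2 / (n - sizes)
    score = np.where(valid, score, -np.inf)
    i = int(np.argmax(score))  # argmax takes the first maximum: smallest cut
    gain = float(score[i] - total**2 / n)
    cut = float((xs[i] + xs[i + 1]) / 2.0)
    return max(gain, 0.0), cut


def _stump_gains(Xc: np.ndarray, y: np.ndarray, min_leaf: int) -> np.ndarray:
    """In-sample best-split SSE reduction per column (the greedy CART
    criterion).  Cut validity requires at least ``min_leaf`` samples per
    child and a strict increase between adjacent sorted values."""
    n, p = Xc.shape
    if n < 2 * min_leaf:
        return np.zeros(p)
    order = np.argsort(Xc, axis=0, kind="stable")
    Xs = np.take_along_axis(Xc, order, axis=0)
    ys = y[order]
    Sy = np.cumsum(ys, axis=0)
    total = Sy[-1]
    sizes = np.arange(1, n)[:, None].astype(float)
    valid = (sizes >= min_leaf) & (n - sizes >= min_leaf) & (Xs[1:] > Xs[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        score = Sy[:-1] ** 2 / sizes + (total - Sy[:-1]) ** 2 / (n - sizes)
    score = np.where(valid, score, -np.inf)
    best = score.max(axis=0)
    gains = best - total**2 / n
    return np.where(np.isfinite(best), np.maximum(gains, 0.0), 0.0)


def _honest_gains(Xc, y, min_leaf, w, oob, order):
    """Honest centered stump gain per column for one bootstrap bag.

    The cut of each column is *chosen* to maximize the bag-weighted split
    score (subject to >= ``min_leaf`` bag weight per child) but *evaluated*
    as the SSE reduction it achieves on the out-of-bag rows, minus the
    out-of-bag null expectation of that reduction (the residual variance,
    one extra fitted mean).  Under a locally null variable the centered gain
    has mean zero, no matter how many cutpoints the variable offers; a real
    effect scales with the out-of-bag count.  Rows outside the node carry
    zero in both ``w`` and ``oob``.

    Returns ``(gains, best_pos, sorted_x)`` so the caller can recover the
    chosen cut value of any column.
    """
    n, p = Xc.shape
    Xs = np.take_along_axis(Xc, order, axis=0)
    ws = w[order]
    Sw = np.cumsum(ws, axis=0)
    Sy = np.cumsum((w * y)[order], axis=0)
    Wt = Sw[-1]
    left_w = Sw[:-1]
    valid = (left_w >= min_leaf) & (Wt - left_w >= min_leaf) & (Xs[1:] > Xs[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        score = Sy[:-1] ** 2 / left_w + (Sy[-1] - Sy[:-1]) ** 2 / (Wt - left_w)
    score = np.where(valid, score, -np.inf)
    best_pos = score.argmax(axis=0)
    any_valid = valid.any(axis=0)

    So_w = np.cumsum(oob[order], axis=0)
    So_y = np.cumsum((oob * y)[order], axis=0)
    cols = np.arange(p)
    Wo, Yo = So_w[-1], So_y[-1]
    lw, ly = So_w[best_pos, cols], So_y[best_pos, cols]
    rw, ry = Wo - lw, Yo - ly
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = ly**2 / lw + ry**2 / rw - Yo**2 / Wo
    n_oob = oob.sum()
    if n_oob > 1:
        sse_oob = float((oob * y * y).sum() - (oob * y).sum() ** 2 / n_oob)
        sigma2 = sse_oob / (n_oob - 1)
    else:
        sigma2 = 0.0
    gain = gain - sigma2
    ok = any_valid & (lw > 0) & (rw > 0)
    return np.where(ok, gain, 0.0), best_pos, Xs


def embedded_importance(
    X_node: np.ndarray,
    y_node: np.ndarray,
    candidate_set,
    rng: np.random.Generator,
    params: RLTParams = RLTParams(),
) -> np.ndarray:
    """Nonnegative importance score for each candidate variable at a node.

    Each of the ``embedded_trees`` internal learners is a depth-2 lookahead
    tree fit on a bootstrap bag of the node's data and scored honestly on
    the out-of-bag rows: a variable's bag score is the larger of (a) its
    centered marginal stump gain and (b) the sum of its centered gains
    inside the two children of the bag's best first split.  Branch (b) is
    the reinforcement-learning step — it credits a variable (for instance a
    treatment indicator with effects of opposite sign in different strata)
    whose value only shows one split further down.  Centering subtracts the
    null expectation of each sum-of-squares reduction, so a locally
    uninformative variable's bag scores fluctuate around zero.  A variable's
    importance is its bag-mean score when that mean exceeds
    ``importance_threshold`` bag standard errors — the signal/noise screen —
    and exactly zero otherwise; a node where every candidate screens out
    becomes a leaf.

    A single embedded learner (``embedded_trees=1``) is the deterministic
    in-sample one-step lookahead, i.e. exactly the greedy CART criterion.
    A constant response yields all-zero importances.
    """
    candidates = list(candidate_set)
    X_node = np.asarray(X_node, dtype=float)
    y_node = np.asarray(y_node, dtype=float)
    if len(np.unique(y_node)) < 2 or not candidates:
        return np.zeros(len(candidates))
    Xc = X_node[:, candidates]
    n = len(y_node)
    min_leaf = params.min_node_size
    if params.embedded_trees == 1:
        return _stump_gains(Xc, y_node, min_leaf)
    order = np.argsort(Xc, axis=0, kind="stable")
    probs = np.full(n, 1.0 / n)
    scores = np.zeros((params.embedded_trees, len(candidates)))
    for b in range(params.embedded_trees):
        w = rng.multinomial(n, probs).astype(float)
        oob = (w == 0).astype(float)
        g1, best_pos, Xs = _honest_gains(Xc, y_node, min_leaf, w, oob, order)
        bag_score = g1
        j = int(np.argmax(g1))
        if g1[j] > 0:
            # lookahead: rescore every variable inside the children of the
            # bag's best first split
            pos = best_pos[j]
            cut = (Xs[pos, j] + Xs[pos + 1, j]) / 2.0
            left = Xc[:, j] <= cut
            g2 = np.zeros(len(candidates))
            for side in (left, ~left):
                w_side = w * side
                if w_side.sum() < 2 * min_leaf:
                    continue
                g_side, _, _ = _honest_gains(
                    Xc, y_node, min_leaf, w_side, oob * side, order
                )
                g2 += g_side
            bag_score = np.maximum(g1, g2)
        scores[b] = bag_score
    mean = scores.mean(axis=0)
    se = scores.std(axis=0, ddof=1) / math.sqrt(params.embedded_trees)
    passed = mean > params.importance_threshold * se
    return np.where(passed & (mean > 0), mean, 0.0)


def _rank_candidates(candidates, importances):
    """Descending importance; ties broken by lowest variable index."""
    order = sorted(range(len(candidates)), key=lambda j: (-importances[j], candidates[j]))
    return [candidates[j] for j in order], [importances[j] for j in order]


def _grow(X, y, idx, candidates, params: RLTParams, rng) -> TreeNode:
    node_pred = float(np.mean(y[idx]))
    node = TreeNode(node_pred, len(idx), tuple(candidates))
    if len(idx) < 2 * params.min_node_size or not candidates:
        return node
    imp = embedded_importance(X[idx], y[idx], candidates, rng, params)
    if not np.any(imp > 0):
        return node
    ranked, ranked_imp = _rank_candidates(candidates, imp)
    split_var = split_cut = None
    for var, vimp in zip(ranked, ranked_imp):
        if vimp <= 0:
            break
        res = _best_cut(X[idx, var], y[idx], params.min_node_size)
        if res is not None:
            split_var, split_cut = var, res[1]
            break
    if split_var is None:
        return node

    others = [v for v in ranked if v != split_var]
    n_mute = math.ceil(params.muting_rate * len(others))
    surviving = [v for v in others[: len(others) - n_mute]] if n_mute else others
    child_candidates = sorted(surviving + [split_var])

    go_left = X[idx, split_var] <= split_cut
    node.split_var = int(split_var)
    node.split_value = float(split_cut)
    node.left = _grow(X, y, idx[go_left], child_candidates, params, rng)
    node.right = _grow(X, y, idx[~go_left], child_candidates, params, rng)
    return node


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    params: RLTParams = RLTParams(),
    rng: np.random.Generator | None = None,
    candidates=None,
) -> TreeNode:
    """Grow one muting tree on (X, y).

    Recursion stops when a node holds fewer than ``2 * min_node_size``
    samples, the response is constant, or all candidate importances are zero.
    The split variable is never muted at its own node.
    """
    params.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per response value")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if candidates is None:
        candidates = list(range(X.shape[1]))
    return _grow(X, y, np.arange(len(y)), sorted(candidates), params, rng)


@dataclass
class RLTForest:
    """Ensemble of muting trees; prediction is the unweighted tree mean."""

    trees: list[TreeNode]
    params: RLTParams
    treatment_var: int | None = None
    feature_names: list[str] | None = None
    oob_mse: list[float] = field(default_factory=list)
    n_features_in: int = 0

    @property
    def n_features(self) -> int:
        if self.n_features_in:
            return self.n_features_in
        if self.feature_names is not None:
            return len(self.feature_names)
        return 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": self.params.__dict__,
                "treatment_var": self.treatment_var,
                "feature_names": self.feature_names,
                "oob_mse": self.oob_mse,
                "n_features_in": self.n_features_in,
                "trees": [t.to_dict() for t in self.trees],
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "RLTForest":
        d = json.loads(payload)
        return cls(
            trees=[TreeNode.from_dict(t) for t in d["trees"]],
            params=RLTParams(**d["params"]),
            treatment_var=d["treatment_var"],
            feature_names=d["feature_names"],
            oob_mse=d["oob_mse"],
            n_features_in=d.get("n_features_in", 0),
        )


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    params: RLTParams = RLTParams(),
    treatment_var: int | None = None,
    feature_names=None,
) -> RLTForest:
    """Fit ``n_trees`` muting trees on independent without-replacement
    subsamples (fraction ``subsample_frac``), with per-tree sub-seeds derived
    from ``params.seed``.  Per-tree out-of-bag MSE is kept as a diagnostic."""
    params.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_sub = max(2 * params.min_node_size, int(round(params.subsample_frac * n)))
    n_sub = min(n_sub, n)
    root = np.random.SeedSequence(params.seed)
    trees: list[TreeNode] = []
    oob: list[float] = []
    for seq in root.spawn(params.n_trees):
        rng = np.random.default_rng(seq)
        sub = rng.choice(n, size=n_sub, replace=False) if n_sub < n else np.arange(n)
        tree = _grow(X, y, sub, list(range(X.shape[1])), params, rng)
        trees.append(tree)
        mask = np.ones(n, dtype=bool)
        mask[sub] = False
        if mask.any():
            resid = _predict_tree(tree, X[mask]) - y[mask]
            oob.append(float(np.mean(resid**2)))
        else:
            oob.append(float("nan"))
    names = list(feature_names) if feature_names is not None else None
    return RLTForest(trees, params, treatment_var, names, oob, X.shape[1])


def _predict_tree(node: TreeNode, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X))
    stack = [(node, np.arange(len(X)))]
    while stack:
        nd, idx = stack.pop()
        if nd.is_leaf or len(idx) == 0:
            out[idx] = nd.prediction
            continue
        go_left = X[idx, nd.split_var] <= nd.split_value
        stack.append((nd.left, idx[go_left]))
        stack.append((nd.right, idx[~go_left]))
    return out


def predict(forest: RLTForest, x) -> np.ndarray | float:
    """Expected reward: mean of per-tree leaf predictions.

    Accepts a single feature vector or a 2-D matrix; routing compares
    ``x[split_var] <= split_value`` (left) at each internal node.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    expected = forest.n_features
    if expected and X.shape[1] < expected:
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns; forest requires >= {expected}"
        )
    preds = np.mean([_predict_tree(t, X) for t in forest.trees], axis=0)
    return float(preds[0]) if single else preds


def path_variables(node: TreeNode, x: np.ndarray) -> set[int]:
    """Variables compared on the root-to-leaf routing path of one vector."""
    out: set[int] = set()
    while not node.is_leaf:
        out.add(node.split_var)
        node = node.left if x[node.split_var] <= node.split_value else node.right
    return out
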