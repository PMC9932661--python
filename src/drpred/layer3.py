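"""Third selection layer: second-order gradient-boosted regression trees.

Written from scratch so split decisions are exactly auditable.  Each round
fits a regression tree to the first/second derivatives (g_i, h_i) of the
squared-error loss at the current prediction (g_i = F(x_i) - y_i, h_i = 1),
minimizing the second-order objective with an L2 leaf penalty:

    obj = sum_i [ g_i f(x_i) + 1/2 h_i f(x_i)^2 ] + gamma * L + 1/2 lambda * ||w||^2

For a fixed leaf partition the optimal leaf weight is w* = -G/(H + lambda)
(G, H the summed gradients/hessians in the leaf), and the gain of a split is

    gain = 1/2 [ G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda)
                 - (G_L+G_R)^2/(H_L+H_R+lambda) ] - gamma

Splits use exact greedy enumeration over sorted unique values.  Samples with
a missing value at the split feature are tried on the left and on the right;
the higher-gain side is stored as the node's default direction (ties go
left), so missingness created by merging heterogeneous feature blocks is
routed natively rather than imputed.

Feature importance is the total recorded split gain per feature; the
selection rule keeps features with positive total gain, capped at the
configured maximum (default 40).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import FeatureTable, ResponseVector, SelectionReport


# ---------------------------------------------------------------------------
# Split gain
# ---------------------------------------------------------------------------

def split_gain(
    g_left: float, h_left: float, g_right: float, h_right: float,
    lam: float = 1.0, gamma_penalty: float = 0.0,
) -> float:
    """Objective reduction of a split under the second-order approximation."""
    def score(g, h):
        denom = h + lam
        return 0.0 if denom <= 0 else g * g / denom
    return 0.5 * (
        score(g_left, h_left) + score(g_right, h_right)
        - score(g_left + g_right, h_left + h_right)
    ) - gamma_penalty


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    feature: int = -1                  # -1 → leaf
    threshold: float = np.nan
    default_left: bool = True
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    weight: float = 0.0                # leaf output
    gain: float = 0.0                  # recorded split gain

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0


@dataclass
class RegressionTree:
    root: TreeNode
    n_leaves: int

    def predict(self, x: np.ndarray, miss: np.ndarray) -> np.ndarray:
        out = np.empty(x.shape[0])
        for i in range(x.shape[0]):
            node = self.root
            while not node.is_leaf:
                if miss[i, node.feature]:
                    node = node.left if node.default_left else node.right
                elif x[i, node.feature] < node.threshold:
                    node = node.left
                else:
                    node = node.right
            out[i] = node.weight
        return out

    def split_gains(self, n_features: int) -> np.ndarray:
        gains = np.zeros(n_features)
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                gains[node.feature] += node.gain
                stack.extend([node.left, node.right])
        return gains


@dataclass
class BoostedEnsemble:
    trees: list[RegressionTree]
    lam: float
    gamma_penalty: float
    shrinkage: float
    base_score: float
    n_features: int
    feature_ids: list[str] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)

    def predict(self, x: np.ndarray, miss: np.ndarray | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if miss is None:
            miss = np.isnan(x)
        pred = np.full(x.shape[0], self.base_score)
        for tree in self.trees:
            pred += self.shrinkage * tree.predict(x, miss)
        return pred


@dataclass
class SplitChoice:
    feature: int
    threshold: float
    default_left: bool
    gain: float


def find_best_split(
    x: np.ndarray,
    miss: np.ndarray,
    rows: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    lam: float,
    gamma_penalty: float,
) -> SplitChoice | None:
    """Exact greedy search over all features and thresholds at one node.

    For every candidate threshold the missing-value samples are assigned to
    the left and to the right in turn; the better assignment is the learned
    default direction (equal gains → left).  Returns None when the best gain
    is not positive.  Ties across candidates break to the lowest feature
    index, then the lowest threshold.
    """
    if rows.size < 2:
        return None
    xs = x[rows]                       # (n, F)
    ms = miss[rows]
    gs, hs = g[rows], h[rows]
    g_tot, h_tot = float(gs.sum()), float(hs.sum())
    n, n_feat = xs.shape

    # sort with missing last
    vals = np.where(ms, np.inf, xs)
    order = np.argsort(vals, axis=0, kind="stable")
    v_sorted = np.take_along_axis(vals, order, axis=0)
    g_sorted = np.take_along_axis(np.broadcast_to(gs[:, None], xs.shape), order, axis=0)
    h_sorted = np.take_along_axis(np.broadcast_to(hs[:, None], xs.shape), order, axis=0)
    n_present = (~ms).sum(axis=0)      # per feature

    cum_g = np.cumsum(g_sorted, axis=0)
    cum_h = np.cumsum(h_sorted, axis=0)

    best: SplitChoice | None = None
    for f in range(n_feat):
        p = int(n_present[f])
        if p < 2:      # all (or all but one) values missing → no threshold
            continue
        v = v_sorted[:p, f]
        valid = v[:-1] < v[1:]         # boundary between distinct values
        if not valid.any():
            continue
        t = np.flatnonzero(valid)      # split after index t
        gl = cum_g[t, f]
        hl = cum_h[t, f]
        g_pres = cum_g[p - 1, f]
        h_pres = cum_h[p - 1, f]
        g_miss = g_tot - g_pres
        h_miss = h_tot - h_pres
        thresholds = 0.5 * (v[t] + v[t + 1])

        def gains(gl_, hl_):
            gr_, hr_ = g_tot - gl_, h_tot - hl_
            return 0.5 * (
                gl_**2 / (hl_ + lam) + gr_**2 / (hr_ + lam)
                - g_tot**2 / (h_tot + lam)
            ) - gamma_penalty

        with np.errstate(divide="ignore", invalid="ignore"):
            gain_left = gains(gl + g_miss, hl + h_miss)   # missing to the left
            gain_right = gains(gl, hl)                    # missing to the right
        gain_left = np.nan_to_num(gain_left, nan=-np.inf)
        gain_right = np.nan_to_num(gain_right, nan=-np.inf)
        default_left = gain_left >= gain_right
        gain_f = np.where(default_left, gain_left, gain_right)
        k = int(np.argmax(gain_f))     # first max → lowest threshold
        if gain_f[k] > 0 and (best is None or gain_f[k] > best.gain + 1e-12):
            best = SplitChoice(
                feature=f,
                threshold=float(thresholds[k]),
                default_left=bool(default_left[k]),
                gain=float(gain_f[k]),
            )
    return best


def _grow_tree(
    x: np.ndarray, miss: np.ndarray, g: np.ndarray, h: np.ndarray,
    rows: np.ndarray, depth: int, max_depth: int, lam: float, gamma_penalty: float,
) -> tuple[TreeNode, int]:
    g_sum, h_sum = float(g[rows].sum()), float(h[rows].sum())
    if depth >= max_depth:
        return TreeNode(weight=-g_sum / (h_sum + lam)), 1
    choice = find_best_split(x, miss, rows, g, h, lam, gamma_penalty)
    if choice is None:
        return TreeNode(weight=-g_sum / (h_sum + lam)), 1
    f, thr = choice.feature, choice.threshold
    m_rows = miss[rows, f]
    go_left = np.empty(rows.size, dtype=bool)
    go_left[m_rows] = choice.default_left
    go_left[~m_rows] = x[rows[~m_rows], f] < thr
    left_rows = rows[go_left]
    right_rows = rows[~go_left]
    if left_rows.size == 0 or right_rows.size == 0:
        return TreeNode(weight=-g_sum / (h_sum + lam)), 1
    left, nl = _grow_tree(x, miss, g, h, left_rows, depth + 1, max_depth, lam, gamma_penalty)
    right, nr = _grow_tree(x, miss, g, h, right_rows, depth + 1, max_depth, lam, gamma_penalty)
    node = TreeNode(
        feature=f, threshold=thr, default_left=choice.default_left,
        left=left, right=right, gain=choice.gain,
    )
    return node, nl + nr


def fit_boosted_trees(
    table: FeatureTable | np.ndarray,
    y: ResponseVector | np.ndarray,
    rounds: int = 50,
    max_depth: int = 4,
    lam: float = 1.0,
    gamma_penalty: float = 0.0,
    shrinkage: float = 0.3,
) -> BoostedEnsemble:
    """Boost regression trees on squared error.

    ``rounds=0`` yields the constant base-score model (mean of y).  The
    training loss sequence is recorded and asserted non-increasing: exact
    greedy search only accepts positive-gain splits, and shrinkage in (0, 1]
    scales a per-leaf Newton step that cannot increase squared error.
    """
    if isinstance(table, FeatureTable):
        x = table.values
        miss = table.missing_mask
        feature_ids = list(table.feature_ids)
    else:
        x = np.asarray(table, dtype=float)
        miss = np.isnan(x)
        feature_ids = [f"f{j}" for j in range(x.shape[1])]
    yv = y.values if isinstance(y, ResponseVector) else np.asarray(y, dtype=float)
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 < shrinkage <= 1.0:
        raise ValueError("shrinkage must be in (0, 1]")

    base = float(yv.mean())
    pred = np.full(x.shape[0], base)
    trees: list[RegressionTree] = []
    losses = [float(np.mean((pred - yv) ** 2))]
    all_rows = np.arange(x.shape[0])
    for _ in range(rounds):
        g = pred - yv
        h = np.ones_like(yv)
        root, n_leaves = _grow_tree(
            x, miss, g, h, all_rows, 0, max_depth, lam, gamma_penalty
        )
        tree = RegressionTree(root=root, n_leaves=n_leaves)
        pred = pred + shrinkage * tree.predict(x, miss)
        loss = float(np.mean((pred - yv) ** 2))
        assert loss <= losses[-1] + 1e-9, "training loss increased"
        losses.append(loss)
        trees.append(tree)

    return BoostedEnsemble(
        trees=trees, lam=lam, gamma_penalty=gamma_penalty, shrinkage=shrinkage,
        base_score=base, n_features=x.shape[1], feature_ids=feature_ids,
        train_loss=losses,
    )


def feature_importance_gain(ensemble: BoostedEnsemble) -> np.ndarray:
    """Total recorded split gain per feature across all trees."""
    gains = np.zeros(ensemble.n_features)
    for tree in ensemble.trees:
        gains += tree.split_gains(ensemble.n_features)
    return gains


def select_layer3(
    table: FeatureTable,
    y: ResponseVector,
    rounds: int = 50,
    max_depth: int = 4,
    lam: float = 1.0,
    gamma_penalty: float = 0.0,
    shrinkage: float = 0.3,
    cap: int = 40,
) -> tuple[FeatureTable, SelectionReport]:
    """Keep features with positive total split gain, at most ``cap`` of them.

    Survivors are ordered by decreasing gain.  Raises when no feature ever
    earns positive gain (increase rounds/depth, or the signal is absent).
    """
    ensemble = fit_boosted_trees(
        table, y, rounds=rounds, max_depth=max_depth,
        lam=lam, gamma_penalty=gamma_penalty, shrinkage=shrinkage,
    )
    gains = feature_importance_gain(ensemble)
    if not (gains > 0).any():
        raise ValueError(
            "no feature obtained positive split gain; "
            "increase boosting rounds or tree depth"
        )
    pos = np.flatnonzero(gains > 0)
    order = pos[np.argsort(-gains[pos], kind="stable")]
    kept_idx = order[:cap]
    kept = [table.feature_ids[j] for j in kept_idx]
    dropped = {}
    for j in range(table.n_features):
        if j in set(kept_idx):
            continue
        reason = "zero split gain" if gains[j] <= 0 else f"gain below top-{cap} cap"
        dropped[table.feature_ids[j]] = reason
    report = SelectionReport(
        layer=3, kept=kept, dropped=dropped,
        scores={table.feature_ids[j]: float(gains[j]) for j in range(table.n_features)},
    )
    return table.select_features(kept), report
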