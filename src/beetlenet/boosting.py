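"""Gradient-boosted binary classification trees (Newton boosting).

A from-scratch implementation of second-order boosting with logistic loss,
the learner behind the habitat-pair migration models:

* per round, with current probabilities p: gradients g = p - y and hessians
  h = p (1 - p);
* regression trees are grown greedily to ``max_depth`` with the usual
  regularised split gain
  1/2 * [G_L^2/(H_L+lam) + G_R^2/(H_R+lam) - (G_L+G_R)^2/(H_L+H_R+lam)];
* a leaf outputs -learning_rate * G / (H + lam);
* the base score is the log-odds of the training prevalence.

Split search is histogram-based (quantile-binned features), which keeps
fitting fast without changing the model class.  An optional xgboost backend
is provided for cross-validation of predictive behaviour; the native
implementation is the default and the one documented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class BoostingError(ValueError):
    pass


try:  # optional compiled traversal kernel; numpy fallback below
    from numba import njit

    @njit(cache=False)
    def _traverse_margin(feat, thr, left, right, value, roots, X, base):
        n = X.shape[0]
        out = np.empty(n)
        for i in range(n):
            s = base
            for t in range(roots.shape[0]):
                node = roots[t]
                while feat[node] >= 0:
                    if X[i, feat[node]] <= thr[node]:
                        node = left[node]
                    else:
                        node = right[node]
                s += value[node]
            out[i] = s
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


@dataclass
class _Tree:
    """Flat-array binary tree: feature[i] < 0 marks node i as a leaf."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    depth: int
    cut_index: np.ndarray | None = None  # training-time bin cut per node

    def predict(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        node = np.zeros(n, dtype=np.int64)
        for _ in range(self.depth + 1):
            feat = self.feature[node]
            internal = feat >= 0
            if not internal.any():
                break
            f = np.maximum(feat, 0)
            go_left = X[np.arange(n), f] <= self.threshold[node]
            node = np.where(
                internal,
                np.where(go_left, self.left[node], self.right[node]),
                node,
            )
        return self.value[node]

    @property
    def used_features(self) -> set[int]:
        return set(int(f) for f in self.feature if f >= 0)


@dataclass
class BoostedEnsemble:
    """Fitted boosted-tree binary classifier on the log-odds (margin) scale."""

    base_score: float
    trees: list[_Tree]
    learning_rate: float
    feature_names: list[str] = field(default_factory=list)

    def _pack(self) -> None:
        """Concatenate all trees into flat arrays for batched traversal."""
        feats, thrs, lefts, rights, vals, roots = [], [], [], [], [], []
        offset = 0
        depth = 0
        for tree in self.trees:
            m = len(tree.feature)
            roots.append(offset)
            feats.append(tree.feature)
            thrs.append(tree.threshold)
            # child indices shifted to the global array; leaves keep -1
            lefts.append(np.where(tree.left >= 0, tree.left + offset, -1))
            rights.append(np.where(tree.right >= 0, tree.right + offset, -1))
            vals.append(tree.value)
            offset += m
            depth = max(depth, tree.depth)
        self._packed = (
            np.concatenate(feats) if feats else np.empty(0, dtype=np.int64),
            np.concatenate(thrs) if thrs else np.empty(0),
            np.concatenate(lefts) if lefts else np.empty(0, dtype=np.int64),
            np.concatenate(rights) if rights else np.empty(0, dtype=np.int64),
            np.concatenate(vals) if vals else np.empty(0),
            np.array(roots, dtype=np.int64),
            depth,
        )

    def predict_margin(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(np.asarray(X, dtype=float))
        if X.ndim == 1:
            X = X[None, :]
        if not self.trees:
            return np.full(X.shape[0], self.base_score, dtype=float)
        if not hasattr(self, "_packed"):
            self._pack()
        feat, thr, left, right, value, roots, depth = self._packed
        if _HAVE_NUMBA:
            return _traverse_margin(
                feat, thr, left, right, value, roots, X, self.base_score
            )
        n = X.shape[0]
        node = np.broadcast_to(roots, (n, len(roots))).copy()
        for _ in range(depth + 1):
            f = feat[node]
            internal = f >= 0
            if not internal.any():
                break
            xval = np.take_along_axis(X, np.maximum(f, 0), axis=1)
            go_left = xval <= thr[node]
            node = np.where(
                internal, np.where(go_left, left[node], right[node]), node
            )
        return value[node].sum(axis=1) + self.base_score

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.predict_margin(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    @property
    def used_features(self) -> set[int]:
        used: set[int] = set()
        for t in self.trees:
            used |= t.used_features
        return used


def fit_boosted_classifier(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 1000,
    max_depth: int = 10,
    learning_rate: float = 0.001,
    reg_lambda: float = 1.0,
    min_child_weight: float = 1.0,
    max_bins: int = 64,
    feature_names: list[str] | None = None,
) -> BoostedEnsemble:
    """Fit the Newton-boosted logistic ensemble.

    Raises
    ------
    BoostingError
        If only one class is present or features are non-finite.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise BoostingError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise BoostingError("features must be finite")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        if len(classes) == 1:
            raise BoostingError(
                f"both classes must be present; got only class {classes[0]:g}"
            )
        raise BoostingError(f"labels must be 0/1, got {classes}")

    n, p = X.shape
    prevalence = y.mean()
    base = float(np.log(prevalence / (1.0 - prevalence)))

    # quantile binning: cuts[f] are candidate thresholds; code = number of
    # cuts <= x, so "code <= j" is exactly "x <= cuts[f][j]"
    cuts: list[np.ndarray] = []
    codes = np.zeros((n, p), dtype=np.int32)
    max_code = 0
    for f in range(p):
        uniq = np.unique(X[:, f])
        if len(uniq) > max_bins:
            qs = np.quantile(uniq, np.linspace(0, 1, max_bins + 1)[1:-1])
            cand = np.unique(qs)
        else:
            cand = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else uniq[:0]
        cuts.append(cand)
        codes[:, f] = np.searchsorted(cand, X[:, f], side="right")
        max_code = max(max_code, len(cand))
    n_slots = max_code + 1
    offsets = (np.arange(p, dtype=np.int64) * n_slots)[None, :]
    flat_codes = (codes + offsets).astype(np.int64)

    margin = np.full(n, base)
    trees: list[_Tree] = []
    for _ in range(n_trees):
        prob = _sigmoid(margin)
        g = prob - y
        h = prob * (1.0 - prob)
        tree = _grow_tree(
            flat_codes, codes, cuts, g, h, p, n_slots,
            max_depth, learning_rate, reg_lambda, min_child_weight,
        )
        margin += _apply_tree_codes(tree, codes)
        trees.append(tree)
    return BoostedEnsemble(
        base_score=base,
        trees=trees,
        learning_rate=learning_rate,
        feature_names=list(feature_names or []),
    )


def _apply_tree_codes(tree: _Tree, codes: np.ndarray) -> np.ndarray:
    """Evaluate a tree on the training rows via their bin codes."""
    n = codes.shape[0]
    node = np.zeros(n, dtype=np.int64)
    for _ in range(tree.depth + 1):
        feat = tree.feature[node]
        internal = feat >= 0
        if not internal.any():
            break
        f = np.maximum(feat, 0)
        go_left = codes[np.arange(n), f] <= tree.cut_index[node]
        node = np.where(
            internal, np.where(go_left, tree.left[node], tree.right[node]), node
        )
    return tree.value[node]


def _grow_tree(
    flat_codes: np.ndarray,
    codes: np.ndarray,
    cuts: list[np.ndarray],
    g: np.ndarray,
    h: np.ndarray,
    p: int,
    n_slots: int,
    max_depth: int,
    learning_rate: float,
    reg_lambda: float,
    min_child_weight: float,
) -> _Tree:
    features: list[int] = []
    thresholds: list[float] = []
    cut_idx: list[int] = []
    lefts: list[int] = []
    rights: list[int] = []
    values: list[float] = []

    def new_node() -> int:
        features.append(-1)
        thresholds.append(0.0)
        cut_idx.append(-1)
        lefts.append(-1)
        rights.append(-1)
        values.append(0.0)
        return len(features) - 1

    def build(idx: np.ndarray, depth: int) -> int:
        node = new_node()
        G = g[idx].sum()
        H = h[idx].sum()
        if depth >= max_depth or len(idx) < 2:
            values[node] = -learning_rate * G / (H + reg_lambda)
            return node
        best = _best_split(
            flat_codes, codes, g, h, idx, p, n_slots,
            G, H, reg_lambda, min_child_weight,
        )
        if best is None:
            values[node] = -learning_rate * G / (H + reg_lambda)
            return node
        f, j, _gain = best
        go_left = codes[idx, f] <= j
        features[node] = f
        thresholds[node] = float(cuts[f][j])
        cut_idx[node] = j
        left_child = build(idx[go_left], depth + 1)
        right_child = build(idx[~go_left], depth + 1)
        lefts[node] = left_child
        rights[node] = right_child
        return node

    build(np.arange(len(g)), 0)
    return _Tree(
        feature=np.array(features, dtype=np.int64),
        threshold=np.array(thresholds, dtype=float),
        left=np.array(lefts, dtype=np.int64),
        right=np.array(rights, dtype=np.int64),
        value=np.array(values, dtype=float),
        depth=max_depth,
        cut_index=np.array(cut_idx, dtype=np.int64),
    )


def _best_split(
    flat_codes, codes, g, h, idx, p, n_slots,
    G, H, reg_lambda, min_child_weight,
):
    flat = flat_codes[idx].ravel()
    gw = np.repeat(g[idx], p)
    hw = np.repeat(h[idx], p)
    size = p * n_slots
    g_hist = np.bincount(flat, weights=gw, minlength=size).reshape(p, n_slots)
    h_hist = np.bincount(flat, weights=hw, minlength=size).reshape(p, n_slots)
    c_hist = np.bincount(flat, minlength=size).reshape(p, n_slots)

    GL = np.cumsum(g_hist, axis=1)[:, :-1]
    HL = np.cumsum(h_hist, axis=1)[:, :-1]
    CL = np.cumsum(c_hist, axis=1)[:, :-1]
    GR = G - GL
    HR = H - HL
    CR = len(idx) - CL
    parent = G * G / (H + reg_lambda)
    gain = 0.5 * (
        GL * GL / (HL + reg_lambda) + GR * GR / (HR + reg_lambda) - parent
    )
    valid = (
        (CL >= 1)
        & (CR >= 1)
        & (HL >= min_child_weight)
        & (HR >= min_child_weight)
    )
    gain = np.where(valid, gain, -np.inf)
    best_flat = int(np.argmax(gain))
    best_gain = gain.ravel()[best_flat]
    if not np.isfinite(best_gain) or best_gain <= 1e-12:
        return None
    f, j = divmod(best_flat, n_slots - 1)
    return f, j, float(best_gain)


def accuracy(model, X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of correct 0.5-threshold predictions."""
    return float(np.mean(model.predict(X) == np.asarray(y).ravel()))


# ---------------------------------------------------------------------------
# Optional xgboost backend (cross-validation of predictive behaviour)
# ---------------------------------------------------------------------------


class XGBoostBackend:
    """Thin wrapper giving xgboost the same predict interface.

    Used to cross-check that the native booster's predictive accuracy is in
    line with the reference library under matched hyperparameters.
    """

    def __init__(
        self,
        n_trees: int = 1000,
        max_depth: int = 10,
        learning_rate: float = 0.001,
        reg_lambda: float = 1.0,
        seed: int = 0,
    ) -> None:
        from xgboost import XGBClassifier

        self._model = XGBClassifier(
            n_estimators=n_trees,
            max_depth=max_depth,
            learning_rate=learning_rate,
            reg_lambda=reg_lambda,
            objective="binary:logistic",
            tree_method="hist",
            random_state=seed,
            n_jobs=1,
        )

    def fit(self, X, y) -> "XGBoostBackend":
        self._model.fit(np.asarray(X, dtype=float), np.asarray(y).ravel())
        return self

    def predict(self, X) -> np.ndarray:
        return self._model.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X) -> np.ndarray:
        return self._model.predict_proba(np.asarray(X, dtype=float))[:, 1]
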