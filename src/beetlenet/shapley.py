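"""Shapley-value attributions for boosted-tree margins.

The attribution of species *i* for an explained observation x is the
classic Shapley value of the coalition game with interventional value
function

    v(S) = mean over background rows b of f(x restricted to S, b elsewhere)

where f is the model's raw margin (log-odds).  Two estimators are provided:

* ``exact`` — full coalition enumeration (2^F model evaluations per
  observation batch); limited to F <= 15 features;
* ``montecarlo`` — permutation sampling: for each random feature ordering,
  features are switched from background to observed one at a time and the
  margin increments are accumulated.  The telescoping sum makes the
  efficiency identity sum_i phi_i = f(x) - mean_b f(b) hold exactly for any
  number of permutations; the permutation spread yields a standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np


class ShapleyError(ValueError):
    pass


@dataclass
class ShapleyAttribution:
    """Per-observation, per-feature Shapley values on the margin scale."""

    phi: np.ndarray  # (n_explain, n_features)
    feature_names: list[str]
    baseline: float  # mean background margin, v(empty set)
    margins: np.ndarray  # f(x) for each explained row
    mode: str
    stderr: np.ndarray | None = None  # montecarlo only

    def efficiency_gap(self) -> np.ndarray:
        """sum_i phi_i - (f(x) - baseline); ~0 by the efficiency axiom."""
        return self.phi.sum(axis=1) - (self.margins - self.baseline)


def shapley_values(
    model,
    X_explain: np.ndarray,
    background: np.ndarray,
    mode: str = "exact",
    n_permutations: int = 20,
    rng: np.random.Generator | int | None = None,
) -> ShapleyAttribution:
    """Compute Shapley values of ``model.predict_margin`` for each row.

    Parameters
    ----------
    model
        Any object with ``predict_margin(X) -> (n,)`` (log-odds scale).
    X_explain : (n_explain, F)
    background : (B, F)
        Reference distribution for the interventional value function.
    mode : "exact" | "montecarlo"
    n_permutations : int
        Permutation count for the montecarlo estimator.
    """
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ShapleyError("background must be non-empty")
    if background.shape[1] != X_explain.shape[1]:
        raise ShapleyError("background and X_explain feature counts differ")
    n_feat = X_explain.shape[1]
    names = list(getattr(model, "feature_names", []) or [])
    if len(names) != n_feat:
        names = [f"f{j}" for j in range(n_feat)]

    baseline = float(np.mean(model.predict_margin(background)))
    margins = model.predict_margin(X_explain)

    if mode == "exact":
        if n_feat > 15:
            raise ShapleyError(
                f"exact mode supports at most 15 features, got {n_feat}; "
                "use mode='montecarlo'"
            )
        phi = _exact(model, X_explain, background)
        stderr = None
    elif mode == "montecarlo":
        if isinstance(rng, (int, np.integer)) or rng is None:
            rng = np.random.default_rng(rng)
        phi, stderr = _montecarlo(
            model, X_explain, background, n_permutations, rng
        )
    else:
        raise ShapleyError(f"unknown mode {mode!r}")

    return ShapleyAttribution(
        phi=phi,
        feature_names=names,
        baseline=baseline,
        margins=margins,
        mode=mode,
        stderr=stderr,
    )


def _coalition_values(model, X_explain, background) -> np.ndarray:
    """v[mask, i] for every coalition mask and explained row i."""
    n_explain, n_feat = X_explain.shape
    B = background.shape[0]
    v = np.empty((1 << n_feat, n_explain))
    tiled_bg = np.tile(background, (n_explain, 1))
    rep_x = np.repeat(X_explain, B, axis=0)
    for mask in range(1 << n_feat):
        cols = [j for j in range(n_feat) if mask >> j & 1]
        comp = tiled_bg.copy()
        if cols:
            comp[:, cols] = rep_x[:, cols]
        v[mask] = model.predict_margin(comp).reshape(n_explain, B).mean(axis=1)
    return v


def _exact(model, X_explain, background) -> np.ndarray:
    n_explain, n_feat = X_explain.shape
    v = _coalition_values(model, X_explain, background)
    weights = np.array(
        [
            factorial(s) * factorial(n_feat - s - 1) / factorial(n_feat)
            for s in range(n_feat)
        ]
    )
    phi = np.zeros((n_explain, n_feat))
    for mask in range(1 << n_feat):
        s = bin(mask).count("1")
        for j in range(n_feat):
            if mask >> j & 1:
                continue
            phi[:, j] += weights[s] * (v[mask | (1 << j)] - v[mask])
    return phi


def _montecarlo(model, X_explain, background, n_permutations, rng):
    n_explain, n_feat = X_explain.shape
    B = background.shape[0]
    tiled_bg = np.tile(background, (n_explain, 1))
    rep_x = np.repeat(X_explain, B, axis=0)
    contrib = np.zeros((n_permutations, n_explain, n_feat))
    for k in range(n_permutations):
        order = rng.permutation(n_feat)
        comp = tiled_bg.copy()
        prev = model.predict_margin(comp).reshape(n_explain, B).mean(axis=1)
        for j in order:
            comp[:, j] = rep_x[:, j]
            cur = model.predict_margin(comp).reshape(n_explain, B).mean(axis=1)
            contrib[k, :, j] = cur - prev
            prev = cur
    phi = contrib.mean(axis=0)
    if n_permutations > 1:
        stderr = contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    else:
        stderr = np.zeros_like(phi)
    return phi, stderr
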