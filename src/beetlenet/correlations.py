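"""Pearson and partial correlations with significance-filtered networks.

The species network of one habitat is built from *full-order partial
correlations*: the correlation between two species' (autoscaled) biomass
after removing the linear effect of all other retained species.  With more
species than can be stably supported by the sample size, the correlation
matrix is regularised by analytic shrinkage toward the identity
(Schafer-Strimmer / Ledoit-Wolf style) before inversion.  Edges are kept
when the partial correlation is significant at ``alpha`` under a Fisher-z
test whose degrees of freedom account for the conditioning set.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ScaledMatrix


class CorrelationError(ValueError):
    pass


@dataclass
class CorrelationSet:
    """Pearson matrix R, partial matrix P, p-values Q for P, sample size n."""

    species: list[str]
    pearson: np.ndarray
    partial: np.ndarray
    pvalues: np.ndarray
    n: int
    shrinkage_intensity: float = 0.0


def pearson_matrix(X: ScaledMatrix | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Product-moment correlation matrix of the columns (diagonal 1)."""
    values = _as_array(X)
    if values.shape[0] < 3:
        raise CorrelationError("at least 3 samples required")
    r = np.corrcoef(values, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def shrinkage_intensity(X: np.ndarray) -> float:
    """Analytic shrinkage weight for R_shrunk = lam*I + (1-lam)*R.

    The optimal intensity estimate is the ratio of the summed sampling
    variances of the off-diagonal correlations to their summed squares,
    clipped to [0, 1] (Schafer & Strimmer 2005).
    """
    n, p = X.shape
    if p < 2:
        return 0.0
    xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    # w_kij = x_ki * x_kj ; var_hat(r_ij) = n / (n-1)^3 * sum_k (w_kij - wbar)^2
    r = (xs.T @ xs) / (n - 1)
    var_sum = 0.0
    sq_sum = 0.0
    wbar = r * (n - 1) / n
    # accumulate per pair without materialising the n x p x p tensor
    w2 = (xs**2).T @ (xs**2)  # sum_k w_kij^2
    var_r = n / (n - 1) ** 3 * (w2 - n * wbar**2)
    off = ~np.eye(p, dtype=bool)
    var_sum = var_r[off].sum()
    sq_sum = (r[off] ** 2).sum()
    if sq_sum <= 0:
        return 1.0
    return float(np.clip(var_sum / sq_sum, 0.0, 1.0))


def partial_correlation_matrix(
    X: ScaledMatrix | pd.DataFrame | np.ndarray,
    shrinkage: str | float = "auto",
) -> CorrelationSet:
    """Full-order partial correlations with Fisher-z p-values.

    P_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj) for i != j, where Omega is
    the inverse of the (optionally shrunk) correlation matrix.  The test for
    each P_ij uses z = atanh(P_ij) * sqrt(df) with df = n - (S - 2) - 3
    (conditioning on the S-2 other species), floored at 3.

    Parameters
    ----------
    shrinkage : "auto", "none", or a float in [0, 1]
        Shrinkage intensity toward the identity; "auto" chooses it
        analytically, "none" inverts the raw correlation matrix and raises a
        numerical error if it is (near-)singular.
    """
    values = _as_array(X)
    species = _species_of(X, values.shape[1])
    n, p = values.shape
    if n < 4:
        raise CorrelationError("at least 4 samples required")
    if p < 2:
        raise CorrelationError("at least 2 species required")

    r = pearson_matrix(values)
    if shrinkage == "auto":
        lam = shrinkage_intensity(values)
    elif shrinkage in ("none", None):
        lam = 0.0
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise CorrelationError(f"shrinkage must be in [0, 1], got {lam}")
    r_shrunk = lam * np.eye(p) + (1.0 - lam) * r

    try:
        omega = np.linalg.inv(r_shrunk)
    except np.linalg.LinAlgError as exc:
        raise CorrelationError(
            "correlation matrix is singular; enable shrinkage "
            "(shrinkage='auto') to regularise the inversion"
        ) from exc
    cond = np.linalg.cond(r_shrunk)
    if lam == 0.0 and cond > 1e12:
        raise CorrelationError(
            f"correlation matrix is near-singular (condition number "
            f"{cond:.2e}); enable shrinkage (shrinkage='auto')"
        )

    d = np.sqrt(np.diag(omega))
    partial = -omega / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    partial = np.clip((partial + partial.T) / 2.0, -1.0, 1.0)

    df = max(n - (p - 2) - 3, 3)
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(partial, -1 + 1e-15, 1 - 1e-15))
    pvals = 2.0 * stats.norm.sf(np.abs(z) * np.sqrt(df))
    np.fill_diagonal(pvals, 0.0)
    pvals = np.clip((pvals + pvals.T) / 2.0, 0.0, 1.0)

    return CorrelationSet(
        species=species,
        pearson=r,
        partial=partial,
        pvalues=pvals,
        n=n,
        shrinkage_intensity=lam,
    )


def build_network(
    cs: CorrelationSet,
    alpha: float = 0.05,
    fdr: bool = False,
) -> nx.Graph:
    """Keep edges with p <= alpha; drop species left without any edge.

    Edge attributes: ``partial_r``, ``pearson_r``, ``p`` and ``sign``
    ("positive"/"negative", taken from the Pearson coefficient, which is the
    relationship sign reported on network figures).  Node attribute
    ``species`` carries the id; callers may add ecological groups.

    With ``fdr=True`` the edge filter uses Benjamini-Hochberg adjusted
    p-values instead of raw ones (off by default; the reference workflow
    filters at raw p <= 0.05).
    """
    if not 0.0 < alpha < 1.0:
        raise CorrelationError(f"alpha must be in (0, 1), got {alpha}")
    p = len(cs.species)
    iu = np.triu_indices(p, k=1)
    pvals = cs.pvalues[iu]
    if fdr:
        pvals = _benjamini_hochberg(pvals)
    keep = pvals <= alpha

    g = nx.Graph()
    for idx in np.flatnonzero(keep):
        i, j = iu[0][idx], iu[1][idx]
        pr = cs.pearson[i, j]
        g.add_edge(
            cs.species[i],
            cs.species[j],
            partial_r=float(cs.partial[i, j]),
            pearson_r=float(pr),
            p=float(pvals[idx]),
            sign="positive" if pr >= 0 else "negative",
        )
    return g


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    adj[order] = pvals[order] * m / (np.arange(m) + 1)
    adj[order] = np.minimum.accumulate(adj[order][::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def _as_array(X) -> np.ndarray:
    if isinstance(X, ScaledMatrix):
        return X.data.to_numpy(dtype=float)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _species_of(X, p: int) -> list[str]:
    if isinstance(X, ScaledMatrix):
        return list(X.data.columns)
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return [f"v{j}" for j in range(p)]
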