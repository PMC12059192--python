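"""Independent brute-force oracles used by several test modules.

Everything here is deliberately naive: exhaustive path enumeration for
betweenness, the first-order recursion for partial correlation, full
permutation averaging for Shapley values.  None of it shares code with the
package implementations it checks.
"""

from itertools import permutations
from math import factorial

import networkx as nx
import numpy as np


def brute_force_betweenness(g: nx.Graph):
    """Node and edge betweenness by enumerating all shortest paths.

    Counts ordered (s, t) pairs; node betweenness excludes endpoints and is
    normalised by (n-1)(n-2); edge betweenness is the raw ordered-pair count.
    """
    n = g.number_of_nodes()
    node_b = {v: 0.0 for v in g.nodes()}
    edge_b = {tuple(sorted(e)): 0.0 for e in g.edges()}
    for s in g.nodes():
        for t in g.nodes():
            if s == t or not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            w = 1.0 / len(paths)
            for path in paths:
                for v in path[1:-1]:
                    node_b[v] += w
                for u, v in zip(path[:-1], path[1:]):
                    edge_b[tuple(sorted((u, v)))] += w
    if n > 2:
        node_b = {v: b / ((n - 1) * (n - 2)) for v, b in node_b.items()}
    return node_b, edge_b


def partial_corr_recursion(r_xy, r_xz, r_yz):
    """First-order recursion r_xy.z for a 3-variable system."""
    return (r_xy - r_xz * r_yz) / np.sqrt(
        (1.0 - r_xz**2) * (1.0 - r_yz**2)
    )


def exact_shapley_by_permutations(margin_fn, x, background):
    """Shapley values via averaging over every feature ordering.

    The interventional value v(S) is computed by direct composition for
    every subset, then marginal contributions are averaged over all |F|!
    permutations by table lookup.
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n_feat = x.shape[0]
    v = {}
    for mask in range(1 << n_feat):
        comp = background.copy()
        for j in range(n_feat):
            if mask >> j & 1:
                comp[:, j] = x[j]
        v[mask] = float(np.mean(margin_fn(comp)))
    phi = np.zeros(n_feat)
    for order in permutations(range(n_feat)):
        mask = 0
        for j in order:
            phi[j] += v[mask | (1 << j)] - v[mask]
            mask |= 1 << j
    return phi / factorial(n_feat)


def correlate_to_exact(X, target):
    """Linearly transform columns of X so the sample correlation equals
    ``target`` exactly (used to build fixtures with prescribed Pearson r)."""
    X = np.asarray(X, dtype=float)
    Xc = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    C = np.corrcoef(Xc, rowvar=False)
    L = np.linalg.cholesky(C)
    T = np.linalg.cholesky(np.asarray(target, dtype=float))
    return Xc @ np.linalg.inv(L).T @ T.T
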