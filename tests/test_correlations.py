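import itertools

import numpy as np
import pandas as pd
import pytest

from beetlenet import build_network, partial_correlation_matrix, pearson_matrix
from beetlenet.correlations import CorrelationError, CorrelationSet

from oracles import correlate_to_exact, partial_corr_recursion


def test_identical_and_negated_columns():
    x = np.random.default_rng(0).normal(size=20)
    r = pearson_matrix(np.column_stack([x, x, -x]))
    assert np.allclose(r[0, 1], 1.0)
    assert np.allclose(r[0, 2], -1.0)


def test_pearson_matches_covariance_definition():
    X = np.array(
        [[1.0, 2.0, 0.5], [3.0, 1.0, 2.0], [2.0, 4.0, 1.0], [5.0, 3.0, 0.0]]
    )
    r = pearson_matrix(X)
    for i, j in itertools.combinations(range(3), 2):
        xi, xj = X[:, i], X[:, j]
        num = np.mean((xi - xi.mean()) * (xj - xj.mean()))
        den = xi.std() * xj.std()
        assert abs(r[i, j] - num / den) < 1e-12


def test_two_species_partial_equals_pearson():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(50, 2))
    cs = partial_correlation_matrix(X, shrinkage="none")
    r = pearson_matrix(X)
    assert abs(cs.partial[0, 1] - r[0, 1]) < 1e-12


def test_equal_pairwise_half_gives_partial_one_third():
    """Three variables with all pairwise r = 0.5 -> partial r = 1/3."""
    rng = np.random.default_rng(2)
    target = np.full((3, 3), 0.5)
    np.fill_diagonal(target, 1.0)
    X = correlate_to_exact(rng.normal(size=(40, 3)), target)
    assert np.allclose(pearson_matrix(X)[0, 1], 0.5, atol=1e-12)
    cs = partial_correlation_matrix(X, shrinkage="none")
    for i, j in itertools.combinations(range(3), 2):
        assert abs(cs.partial[i, j] - 1.0 / 3.0) < 1e-10


def test_inversion_agrees_with_recursion_on_three_variables():
    """Matrix-inversion partials equal the first-order recursion, any data."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        X = rng.normal(size=(rng.integers(10, 50), 3))
        X[:, 2] += 0.5 * X[:, 0]  # induce structure
        r = pearson_matrix(X)
        cs = partial_correlation_matrix(X, shrinkage="none")
        combos = [(0, 1, 2), (0, 2, 1), (1, 2, 0)]
        for i, j, k in combos:
            expected = partial_corr_recursion(r[i, j], r[i, k], r[j, k])
            assert abs(cs.partial[i, j] - expected) < 1e-10


def test_independent_gaussian_null_partials_are_small():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(5000, 8))
    cs = partial_correlation_matrix(X, shrinkage="none")
    iu = np.triu_indices(8, 1)
    assert np.abs(cs.partial[iu]).max() < 0.08


def test_singular_without_shrinkage_raises_advice():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(10, 14))  # more species than samples
    with pytest.raises(CorrelationError, match="shrinkage"):
        partial_correlation_matrix(X, shrinkage="none")
    cs = partial_correlation_matrix(X, shrinkage="auto")  # regularised path
    assert 0.0 < cs.shrinkage_intensity <= 1.0


def _toy_cs(pvals, partial=None, pearson=None):
    p = pvals.shape[0]
    return CorrelationSet(
        species=[f"v{i}" for i in range(p)],
        pearson=pearson if pearson is not None else np.eye(p) * 0 + 0.4,
        partial=partial if partial is not None else np.eye(p) * 0 + 0.3,
        pvalues=pvals,
        n=100,
    )


def test_build_network_empty_when_nothing_significant():
    pvals = np.full((4, 4), 0.5)
    np.fill_diagonal(pvals, 0.0)
    g = build_network(_toy_cs(pvals), alpha=0.05)
    assert g.number_of_nodes() == 0 and g.number_of_edges() == 0


def test_build_network_keeps_only_significant_edges_and_their_endpoints():
    pvals = np.full((5, 5), 0.9)
    for i, j in [(0, 1), (1, 2), (3, 4)]:
        pvals[i, j] = pvals[j, i] = 0.01
    np.fill_diagonal(pvals, 0.0)
    g = build_network(_toy_cs(pvals), alpha=0.05)
    assert g.number_of_edges() == 3
    assert set(g.nodes()) == {"v0", "v1", "v2", "v3", "v4"}
    pvals[3, 4] = pvals[4, 3] = 0.9  # drop one edge; v3/v4 become isolated
    g2 = build_network(_toy_cs(pvals), alpha=0.05)
    assert set(g2.nodes()) == {"v0", "v1", "v2"}


def test_build_network_alpha_validation_and_monotonicity():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(60, 6))
    X[:, 1] += X[:, 0]
    cs = partial_correlation_matrix(X)
    with pytest.raises(CorrelationError, match="alpha"):
        build_network(cs, alpha=1.5)
    counts = [
        build_network(cs, alpha=a).number_of_edges()
        for a in (0.5, 0.2, 0.05, 0.01)
    ]
    assert counts == sorted(counts, reverse=True)


def test_network_invariant_to_column_order():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(200, 6))
    X[:, 3] += X[:, 2]
    frame = pd.DataFrame(X, columns=[f"s{j}" for j in range(6)])
    g1 = build_network(partial_correlation_matrix(frame))
    perm = frame[["s4", "s0", "s3", "s1", "s5", "s2"]]
    g2 = build_network(partial_correlation_matrix(perm))
    assert set(g1.nodes()) == set(g2.nodes())
    assert {frozenset(e) for e in g1.edges()} == {
        frozenset(e) for e in g2.edges()
    }


def test_block_design_edge_recovery():
    """rho=0.8 blocks, n=500: within-block pairs become edges, between not."""
    rng = np.random.default_rng(8)
    n, bs, k, rho = 500, 5, 4, 0.8
    cols = []
    for _ in range(k):
        f = rng.standard_normal((n, 1))
        cols.append(
            np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal((n, bs))
        )
    X = np.hstack(cols)
    cs = partial_correlation_matrix(X)
    g = build_network(cs, alpha=0.05)
    within = between = w_hit = b_hit = 0
    names = cs.species
    for i, j in itertools.combinations(range(k * bs), 2):
        same = i // bs == j // bs
        hit = g.has_edge(names[i], names[j])
        if same:
            within += 1
            w_hit += hit
        else:
            between += 1
            b_hit += hit
    assert w_hit / within >= 0.9
    assert b_hit / between <= 0.1


def test_edge_sign_comes_from_pearson():
    rng = np.random.default_rng(9)
    x = rng.normal(size=300)
    X = np.column_stack([x, -x + 0.3 * rng.normal(size=300),
                         rng.normal(size=300), rng.normal(size=300)])
    cs = partial_correlation_matrix(X, shrinkage="none")
    g = build_network(cs, alpha=0.05)
    assert g.edges["v0", "v1"]["sign"] == "negative"
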