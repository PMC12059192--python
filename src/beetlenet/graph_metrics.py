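"""Whole-network attributes and node/edge centralities.

Conventions (stated explicitly because network analysers differ):

* all path metrics treat the graph as **unweighted** and **undirected**;
  correlation magnitudes are edge attributes, not distances;
* shortest-path counting is over **ordered** node pairs (s, t), s != t:
  a connected graph on n nodes has n*(n-1) shortest paths, and the edge
  betweenness of an isolated two-node component's edge is 2;
* node betweenness is Brandes betweenness over ordered pairs normalised by
  (n-1)*(n-2) with n the global node count, so a star hub scores 1;
* closeness of a node is 1 / (mean distance to its *reachable* nodes), and
  0 for an isolated node, so both endpoints of an isolated pair score 1;
* local clustering of nodes with degree < 2 counts as 0 and is included in
  the network mean;
* characteristic path length averages distance over connected ordered pairs
  only, so it stays defined on disconnected graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd


class MetricsError(ValueError):
    pass


@dataclass
class NetworkAttributes:
    """Whole-network attribute set (one row of a Table-3-style summary)."""

    n_nodes: int
    n_edges: int
    average_neighbours: float
    density: float
    clustering_coefficient: float
    centralization: float
    heterogeneity: float
    characteristic_path_length: float
    shortest_path_count: int

    def as_dict(self) -> dict:
        return asdict(self)


def whole_network_attributes(g: nx.Graph) -> NetworkAttributes:
    """Compute the whole-network attribute set.

    density = mean degree / (n-1); centralization =
    (n/(n-2)) * (max degree/(n-1) - density) for n >= 3, else 0;
    heterogeneity = sqrt(population variance of degree) / mean degree.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise MetricsError("empty graph")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    mean_deg = degrees.mean()
    e = g.number_of_edges()

    density = mean_deg / (n - 1) if n > 1 else 0.0
    if n >= 3:
        centralization = (n / (n - 2)) * (degrees.max() / (n - 1) - density)
    else:
        centralization = 0.0
    heterogeneity = (
        float(np.sqrt(degrees.var()) / mean_deg) if mean_deg > 0 else 0.0
    )
    clustering = float(np.mean(list(nx.clustering(g).values())))

    total_dist = 0
    n_pairs = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                total_dist += d
                n_pairs += 1
    cpl = total_dist / n_pairs if n_pairs else 0.0

    return NetworkAttributes(
        n_nodes=n,
        n_edges=e,
        average_neighbours=float(mean_deg),
        density=float(density),
        clustering_coefficient=clustering,
        centralization=float(centralization),
        heterogeneity=heterogeneity,
        characteristic_path_length=float(cpl),
        shortest_path_count=int(n_pairs),
    )


def node_centralities(g: nx.Graph) -> pd.DataFrame:
    """Per-node degree (NDC), closeness (NCC) and betweenness (NBC).

    NCC uses reachable nodes only (0 for isolated nodes); NBC is ordered-pair
    Brandes betweenness normalised by (n-1)(n-2) with the global node count.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise MetricsError("at least 2 nodes required")
    ndc = dict(g.degree())
    ncc = {}
    for node in g.nodes():
        lengths = nx.single_source_shortest_path_length(g, node)
        dists = [d for d in lengths.values() if d > 0]
        ncc[node] = 1.0 / (sum(dists) / len(dists)) if dists else 0.0
    # networkx normalised betweenness for undirected graphs is exactly the
    # ordered-pair count divided by (n-1)(n-2)
    nbc = nx.betweenness_centrality(g, normalized=True)
    rows = sorted(g.nodes())
    return pd.DataFrame(
        {
            "NDC": [ndc[v] for v in rows],
            "NCC": [ncc[v] for v in rows],
            "NBC": [nbc[v] for v in rows],
        },
        index=pd.Index(rows, name="species"),
    )


def edge_centralities(g: nx.Graph) -> pd.DataFrame:
    """Raw ordered-pair edge betweenness (EBC) per edge.

    EBC counts, over ordered pairs (s, t), the fraction of shortest s-t
    paths traversing the edge; the two endpoint pairs alone contribute 2,
    which is the minimum for any edge.
    """
    if g.number_of_edges() < 1:
        raise MetricsError("at least 1 edge required")
    # networkx unnormalised EBC sums over unordered pairs; ordered = 2x
    raw = nx.edge_betweenness_centrality(g, normalized=False)
    records = []
    for (u, v), b in raw.items():
        a, b_node = sorted((u, v))
        rec = {"species_a": a, "species_b": b_node, "EBC": 2.0 * b}
        if "pearson_r" in g.edges[u, v]:
            rec["r"] = g.edges[u, v]["pearson_r"]
        if "partial_r" in g.edges[u, v]:
            rec["partial_r"] = g.edges[u, v]["partial_r"]
        records.append(rec)
    frame = pd.DataFrame(records).sort_values(
        ["species_a", "species_b"], ignore_index=True
    )
    return frame
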