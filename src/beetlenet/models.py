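"""Model / Results classes tying the pipeline stages together.

Two fit-able models, in the style of statsmodels:

* :class:`SpeciesNetworkModel` — per-habitat significance-filtered partial-
  correlation network.  ``fit()`` returns :class:`SpeciesNetworkResults`
  carrying the correlation matrices, the graph, whole-network attributes and
  node/edge centrality tables, with a ``summary()`` text report.
* :class:`MigrationModel` — habitat-pair boosted-tree classifier with
  Shapley migration read-out.  ``fit()`` returns :class:`MigrationResults`
  with the per-species SW table, directional sums, accuracies, a
  ``summary()`` report and a bar-plot helper.
"""

from __future__ import annotations

from io import StringIO

import networkx as nx
import numpy as np
import pandas as pd

from .community import CommunityTable
from .correlations import (
    CorrelationSet,
    build_network,
    partial_correlation_matrix,
)
from .graph_metrics import (
    NetworkAttributes,
    edge_centralities,
    node_centralities,
    whole_network_attributes,
)
from .migration import MigrationModelSpec, MigrationSummary, run_migration_pair
from .preprocess import ScaledMatrix, autoscale


class SpeciesNetworkModel:
    """Partial-correlation species network for one habitat.

    Parameters
    ----------
    table : CommunityTable
    habitat : str
        Habitat whose samples are analysed (autoscaling is within-habitat).
    alpha : float
        Edge significance threshold on the partial-correlation p-value.
    shrinkage : "auto" | "none" | float
        Shrinkage intensity for the correlation-matrix inversion.
    min_occurrence : int
        Minimum positive records for a species to enter the analysis.
    """

    def __init__(
        self,
        table: CommunityTable,
        habitat: str,
        alpha: float = 0.05,
        shrinkage: str | float = "auto",
        min_occurrence: int = 2,
        fdr: bool = False,
    ) -> None:
        self.table = table
        self.habitat = habitat
        self.alpha = alpha
        self.shrinkage = shrinkage
        self.min_occurrence = min_occurrence
        self.fdr = fdr

    @classmethod
    def from_dataframe(
        cls,
        biomass: pd.DataFrame,
        habitat_labels: pd.Series,
        habitat: str,
        **kwargs,
    ) -> "SpeciesNetworkModel":
        table = CommunityTable(biomass=biomass, habitat=habitat_labels)
        return cls(table, habitat, **kwargs)

    def fit(self) -> "SpeciesNetworkResults":
        scaled = autoscale(
            self.table, self.habitat, min_occurrence=self.min_occurrence
        )
        cs = partial_correlation_matrix(scaled, shrinkage=self.shrinkage)
        graph = build_network(cs, alpha=self.alpha, fdr=self.fdr)
        for node in graph.nodes():
            graph.nodes[node]["group"] = self.table.species_groups.get(
                node, "unknown"
            )
        return SpeciesNetworkResults(self, scaled, cs, graph)


class SpeciesNetworkResults:
    """Fitted network with its attribute and centrality tables."""

    def __init__(
        self,
        model: SpeciesNetworkModel,
        scaled: ScaledMatrix,
        correlations: CorrelationSet,
        graph: nx.Graph,
    ) -> None:
        self.model = model
        self.scaled = scaled
        self.correlations = correlations
        self.graph = graph
        self._attributes: NetworkAttributes | None = None

    @property
    def attributes(self) -> NetworkAttributes:
        if self._attributes is None:
            if self.graph.number_of_nodes() == 0:
                # nothing passed the significance filter: report a null row
                # rather than erroring (the metric op itself rejects empty
                # graphs)
                self._attributes = NetworkAttributes(
                    n_nodes=0, n_edges=0, average_neighbours=0.0,
                    density=0.0, clustering_coefficient=0.0,
                    centralization=0.0, heterogeneity=0.0,
                    characteristic_path_length=0.0, shortest_path_count=0,
                )
            else:
                self._attributes = whole_network_attributes(self.graph)
        return self._attributes

    def node_centralities(self) -> pd.DataFrame:
        return node_centralities(self.graph)

    def edge_centralities(self) -> pd.DataFrame:
        return edge_centralities(self.graph)

    def edge_table(self) -> pd.DataFrame:
        """Edge list with partial r, Pearson r, p and sign (lexicographic)."""
        rows = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "partial_r": data["partial_r"],
                    "pearson_r": data["pearson_r"],
                    "p": data["p"],
                    "sign": data["sign"],
                }
            )
        frame = pd.DataFrame(
            rows,
            columns=[
                "species_a", "species_b", "partial_r", "pearson_r", "p", "sign",
            ],
        )
        return frame.sort_values(
            ["species_a", "species_b"], ignore_index=True
        )

    def summary(self) -> str:
        a = self.attributes
        buf = StringIO()
        buf.write("Species partial-correlation network\n")
        buf.write("=" * 51 + "\n")
        buf.write(f"Habitat:                 {self.model.habitat}\n")
        buf.write(f"Samples:                 {self.scaled.n_samples}\n")
        buf.write(
            f"Species analysed:        {len(self.scaled.species)} "
            f"({len(self.scaled.dropped)} dropped)\n"
        )
        buf.write(f"Edge threshold (alpha):  {self.model.alpha}\n")
        buf.write(
            f"Shrinkage intensity:     "
            f"{self.correlations.shrinkage_intensity:.4f}\n"
        )
        buf.write("-" * 51 + "\n")
        for label, value in [
            ("Number of nodes", a.n_nodes),
            ("Number of edges", a.n_edges),
            ("Average number of neighbours", f"{a.average_neighbours:.3f}"),
            ("Network density", f"{a.density:.3f}"),
            ("Clustering coefficient", f"{a.clustering_coefficient:.3f}"),
            ("Network centralization", f"{a.centralization:.3f}"),
            ("Network heterogeneity", f"{a.heterogeneity:.3f}"),
            ("Characteristic path length",
             f"{a.characteristic_path_length:.3f}"),
            ("Shortest paths", a.shortest_path_count),
        ]:
            buf.write(f"{label:<38}{value}\n")
        return buf.getvalue()

    def plot_degree_distribution(self, ax=None):
        """Histogram of node degrees (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        degrees = [d for _, d in self.graph.degree()]
        ax.hist(degrees, bins=range(0, max(degrees) + 2), edgecolor="black")
        ax.set_xlabel("node degree (NDC)")
        ax.set_ylabel("species")
        ax.set_title(f"Degree distribution — {self.model.habitat}")
        return ax


class MigrationModel:
    """Boosted-tree / Shapley migration model for one habitat pair."""

    def __init__(
        self,
        table: CommunityTable,
        lake_habitat: str,
        pit_habitat: str,
        spec: MigrationModelSpec | None = None,
        **spec_overrides,
    ) -> None:
        self.table = table
        if spec is None:
            spec = MigrationModelSpec(
                lake_habitat=lake_habitat,
                pit_habitat=pit_habitat,
                **spec_overrides,
            )
        self.spec = spec

    def fit(self, seed: int = 0) -> "MigrationResults":
        summary = run_migration_pair(self.table, self.spec, seed=seed)
        return MigrationResults(self, summary, seed)


class MigrationResults:
    """Aggregated migration statistics for a fitted habitat pair."""

    def __init__(
        self, model: MigrationModel, summary: MigrationSummary, seed: int
    ) -> None:
        self.model = model
        self._summary = summary
        self.seed = seed

    @property
    def per_species(self) -> pd.DataFrame:
        return self._summary.per_species

    @property
    def sw_sum_to_pit(self) -> float:
        return self._summary.sw_sum_to_pit

    @property
    def sw_sum_to_lake(self) -> float:
        return self._summary.sw_sum_to_lake

    @property
    def sw_mean_of_sums(self) -> float:
        return self._summary.sw_mean_of_sums

    @property
    def train_accuracy(self) -> float:
        return self._summary.train_accuracy

    @property
    def test_accuracy(self) -> float:
        return self._summary.test_accuracy

    def migration_summary(self) -> MigrationSummary:
        return self._summary

    def summary(self, top: int = 10) -> str:
        s = self._summary
        spec = self.model.spec
        buf = StringIO()
        buf.write("Habitat-pair migration model\n")
        buf.write("=" * 55 + "\n")
        buf.write(
            f"Pair: {s.lake_habitat} (class 0) vs {s.pit_habitat} (class 1)\n"
        )
        buf.write(
            f"Repeats: {spec.n_repeats}   trees: {spec.n_trees}   "
            f"depth: {spec.max_depth}   lr: {spec.learning_rate}\n"
        )
        buf.write(
            f"Mean accuracy: train {s.train_accuracy:.3f}, "
            f"test {s.test_accuracy:.3f}\n"
        )
        buf.write("-" * 55 + "\n")
        buf.write(f"{'species':<16}{'SW':>10}{'SD':>10}  direction\n")
        for sp, row in s.per_species.head(top).iterrows():
            buf.write(
                f"{sp:<16}{row['SW']:>10.4f}{row['SD']:>10.4f}"
                f"  {row['direction']}\n"
            )
        buf.write("-" * 55 + "\n")
        buf.write(f"SW(sum) to {s.pit_habitat:<12}: {s.sw_sum_to_pit:.4f}\n")
        buf.write(f"SW(sum) to {s.lake_habitat:<12}: {s.sw_sum_to_lake:.4f}\n")
        buf.write(f"SW(mean of sum)          : {s.sw_mean_of_sums:.4f}\n")
        return buf.getvalue()

    def plot_shapley(self, ax=None, top: int = 20):
        """ABS_SHAP-style signed bar plot: red to-pit, blue to-lake."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * min(top, len(self.per_species)) + 1))
        frame = self.per_species.head(top).iloc[::-1]
        colors = ["crimson" if v > 0 else "steelblue" for v in frame["SW"]]
        ax.barh(frame.index, frame["SW"], xerr=frame["SD"], color=colors)
        ax.axvline(0.0, color="black", lw=0.8)
        ax.set_xlabel("signed mean Shapley value (SW)")
        ax.set_title(
            f"{self._summary.lake_habitat} ↔ {self._summary.pit_habitat}"
        )
        return ax
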