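"""Readers and writers for every pipeline artifact.

Formats: biomass tables and metric tables as RFC-4180 CSV (UTF-8), networks
as GraphML plus a flat edge-list CSV, reports as JSON.  All writers are
deterministic for identical inputs: rows are ordered lexicographically by
species / sample id, and floats are written with full repr precision.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .community import CommunityTable, HABITATS

logger = logging.getLogger("beetlenet")


class ParseError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    input_path: str | None = None
    metadata_path: str | None = None
    output_dir: str = "beetlenet_out"
    alpha: float = 0.05
    shrinkage: str | float = "auto"
    min_occurrence: int = 2
    n_trees: int = 1000
    max_depth: int = 10
    learning_rate: float = 0.001
    reg_lambda: float = 1.0
    train_fraction: float = 0.70
    n_repeats: int = 5
    n_permutations: int = 10
    background_size: int = 100
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # synthetic-generator block
    habitat_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("mesotrophic", "clay_pit"),
            ("eutrophic", "clay_pit"),
            ("dystrophic", "clay_pit"),
            ("mesotrophic", "gravel_pit"),
            ("eutrophic", "gravel_pit"),
            ("dystrophic", "gravel_pit"),
        ]
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ParseError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ParseError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )
        if self.n_repeats < 1:
            raise ParseError(f"n_repeats must be >= 1, got {self.n_repeats}")
        self.habitat_pairs = [tuple(p) for p in self.habitat_pairs]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            k: (list(map(list, v)) if k == "habitat_pairs" else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Community tables
# ---------------------------------------------------------------------------


def read_community(
    path: str | Path,
    metadata_path: str | Path | None = None,
    habitat_column: str = "habitat",
    transposed: bool = False,
) -> CommunityTable:
    """Read a biomass CSV (samples in rows, species in columns).

    The table must contain a ``habitat`` column; blank biomass cells are
    read as 0 (absence) with a logged warning count.  ``transposed=True``
    accepts species-in-rows input.
    """
    # check the raw header before pandas mangles duplicate column names
    with open(path, "r", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    names = [c.strip() for c in header[1:]]
    if not transposed and len(names) != len(set(names)):
        dups = sorted({c for c in names if names.count(c) > 1})
        raise ParseError(f"{path}: duplicate species names {dups}")

    frame = pd.read_csv(path, index_col=0)
    if transposed:
        frame = frame.T
    if habitat_column not in frame.columns:
        raise ParseError(
            f"{path}: missing required column {habitat_column!r}"
        )
    habitat = frame[habitat_column].astype(str).str.strip()
    biomass = frame.drop(columns=[habitat_column])
    biomass.columns = [str(c).strip() for c in biomass.columns]

    if pd.Index(biomass.columns).duplicated().any():
        dups = sorted(
            set(pd.Index(biomass.columns)[pd.Index(biomass.columns).duplicated()])
        )
        raise ParseError(f"{path}: duplicate species names {dups}")

    n_blank = int(biomass.isna().to_numpy().sum())
    if n_blank:
        logger.warning("%s: %d blank biomass cells read as 0", path, n_blank)
        biomass = biomass.fillna(0.0)
    try:
        biomass = biomass.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric biomass value ({exc})") from exc

    values = biomass.to_numpy()
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ParseError(
            f"{path}: negative biomass at row {biomass.index[i]!r}, "
            f"species {biomass.columns[j]!r}"
        )
    unknown = sorted(set(habitat.unique()) - set(HABITATS))
    if unknown:
        raise ParseError(
            f"{path}: unknown habitat labels {unknown}; expected one of "
            f"{list(HABITATS)}"
        )

    species_groups: dict[str, str] = {}
    species_clusters: dict[str, int] = {}
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path)
        if "species" not in meta.columns:
            raise ParseError(f"{metadata_path}: missing 'species' column")
        meta["species"] = meta["species"].astype(str).str.strip()
        if "group" in meta.columns:
            species_groups = dict(zip(meta["species"], meta["group"]))
        if "cluster" in meta.columns:
            species_clusters = dict(
                zip(meta["species"], meta["cluster"].astype(int))
            )

    return CommunityTable(
        biomass=biomass,
        habitat=habitat,
        species_groups=species_groups,
        species_clusters=species_clusters,
    )


def write_community(table: CommunityTable, path: str | Path) -> None:
    """Write biomass + habitat column as CSV (species lexicographic)."""
    frame = table.biomass[sorted(table.biomass.columns)].copy()
    frame.insert(0, "habitat", table.habitat)
    frame.to_csv(path, index_label="sample")


def write_species_metadata(table: CommunityTable, path: str | Path) -> None:
    rows = [
        {
            "species": sp,
            "group": table.species_groups.get(sp, "unknown"),
            "cluster": table.species_clusters.get(sp, -1),
        }
        for sp in sorted(table.biomass.columns)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Networks and reports
# ---------------------------------------------------------------------------


def write_network(graph: nx.Graph, path_prefix: str | Path) -> dict[str, str]:
    """Write a species network as GraphML and edge-list CSV.

    Returns the mapping of artifact name -> written path.  The edge CSV has
    columns species_a, species_b, partial_r, pearson_r, p, sign and is
    sorted lexicographically.
    """
    prefix = Path(path_prefix)
    graphml = prefix.with_suffix(".graphml")
    csv = prefix.with_suffix(".edges.csv")
    nx.write_graphml(graph, graphml)
    rows = []
    for u, v, data in graph.edges(data=True):
        a, b = sorted((str(u), str(v)))
        rows.append(
            {
                "species_a": a,
                "species_b": b,
                "partial_r": data.get("partial_r", np.nan),
                "pearson_r": data.get("pearson_r", np.nan),
                "p": data.get("p", np.nan),
                "sign": data.get("sign", ""),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["species_a", "species_b", "partial_r", "pearson_r", "p", "sign"],
    )
    frame.sort_values(["species_a", "species_b"], ignore_index=True).to_csv(
        csv, index=False
    )
    return {"graphml": str(graphml), "edges_csv": str(csv)}


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read back an edge-list CSV written by :func:`write_network`."""
    frame = pd.read_csv(path)
    g = nx.Graph()
    for _, row in frame.iterrows():
        g.add_edge(
            row["species_a"],
            row["species_b"],
            partial_r=float(row["partial_r"]),
            pearson_r=float(row["pearson_r"]),
            p=float(row["p"]),
            sign=str(row["sign"]),
        )
    return g


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_report(results: dict, path: str | Path) -> None:
    """Write the machine-readable JSON report (stable key order)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
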