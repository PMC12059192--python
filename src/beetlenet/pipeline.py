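"""End-to-end orchestration: simulate -> networks -> metrics -> migration
-> stats -> report, with full provenance in a run manifest.

All randomness derives from the single root seed in the configuration via
``numpy.random.SeedSequence`` substreams (one per stage / habitat pair), so
identical configurations produce identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .community import CommunityTable
from .migration import MigrationModelSpec
from .models import MigrationModel, SpeciesNetworkModel
from .preprocess import PreprocessError
from .stats import habitat_comparisons, summarize_community
from .synthetic import default_config, generate_community

logger = logging.getLogger("beetlenet")

STAGES = ("simulate", "network", "metrics", "migrate", "stats", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config: dict
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def check(self) -> None:
        missing = [p for p in self.outputs.values() if not Path(p).exists()]
        if missing:
            raise PipelineError(f"missing output files: {missing}")


def run_pipeline(
    config: bio.RunConfig,
    stages: list[str] | None = None,
) -> RunManifest:
    """Execute the requested stages (default: all) and return the manifest."""
    stages = list(stages or STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages {unknown}; valid: {list(STAGES)}")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dict(config.__dict__), seed=config.seed)
    seed_root = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: s for name, s in zip(STAGES, seed_root.spawn(len(STAGES)))
    }

    table: CommunityTable | None = None
    report: dict = {"seed": config.seed, "alpha": config.alpha}

    # -- simulate / load ----------------------------------------------------
    t0 = time.perf_counter()
    if "simulate" in stages and not config.input_path:
        sim_seed = int(
            np.random.default_rng(stage_seeds["simulate"]).integers(2**31 - 1)
        )
        sim_kwargs = dict(config.simulate)
        sim_kwargs["seed"] = sim_kwargs.get("seed", sim_seed)
        table = generate_community(default_config(**sim_kwargs))
        community_csv = outdir / "community.csv"
        metadata_csv = outdir / "species_metadata.csv"
        bio.write_community(table, community_csv)
        bio.write_species_metadata(table, metadata_csv)
        manifest.outputs["community_csv"] = str(community_csv)
        manifest.outputs["metadata_csv"] = str(metadata_csv)
        manifest.timings["simulate"] = time.perf_counter() - t0
    elif config.input_path:
        table = bio.read_community(
            config.input_path, metadata_path=config.metadata_path
        )
    if table is None and set(stages) - {"report"}:
        raise PipelineError(
            "no input: provide input_path or include the simulate stage"
        )

    # -- per-habitat networks + metrics -------------------------------------
    if "network" in stages or "metrics" in stages:
        t0 = time.perf_counter()
        report["networks"] = {}
        for habitat in sorted(table.habitat.unique()):
            try:
                res = SpeciesNetworkModel(
                    table,
                    habitat,
                    alpha=config.alpha,
                    shrinkage=config.shrinkage,
                    min_occurrence=config.min_occurrence,
                ).fit()
            except PreprocessError as exc:
                manifest.warnings.append(f"{habitat}: {exc}")
                continue
            paths = bio.write_network(res.graph, outdir / f"network_{habitat}")
            manifest.outputs.update(
                {f"network_{habitat}_{k}": v for k, v in paths.items()}
            )
            block = {"attributes": res.attributes.as_dict()}
            if "metrics" in stages and res.graph.number_of_nodes() >= 2:
                nodes = res.node_centralities()
                nodes_csv = outdir / f"node_centralities_{habitat}.csv"
                nodes.to_csv(nodes_csv)
                manifest.outputs[f"node_centralities_{habitat}"] = str(nodes_csv)
                block["node_centralities"] = nodes
                if res.graph.number_of_edges() >= 1:
                    edges = res.edge_centralities()
                    edges_csv = outdir / f"edge_centralities_{habitat}.csv"
                    edges.to_csv(edges_csv, index=False)
                    manifest.outputs[f"edge_centralities_{habitat}"] = str(
                        edges_csv
                    )
                    block["edge_centralities"] = edges
            report["networks"][habitat] = block
        manifest.timings["network"] = time.perf_counter() - t0

    # -- migration pairs -----------------------------------------------------
    if "migrate" in stages:
        t0 = time.perf_counter()
        report["migration"] = {}
        pair_seeds = stage_seeds["migrate"].spawn(len(config.habitat_pairs))
        rows = []
        for (lake, pit), ss in zip(config.habitat_pairs, pair_seeds):
            spec = MigrationModelSpec(
                lake_habitat=lake,
                pit_habitat=pit,
                n_trees=config.n_trees,
                max_depth=config.max_depth,
                learning_rate=config.learning_rate,
                reg_lambda=config.reg_lambda,
                train_fraction=config.train_fraction,
                n_repeats=config.n_repeats,
                n_permutations=config.n_permutations,
                background_size=config.background_size,
            )
            pair_seed = int(np.random.default_rng(ss).integers(2**31 - 1))
            res = MigrationModel(table, lake, pit, spec=spec).fit(
                seed=pair_seed
            )
            key = f"{lake}__{pit}"
            per_species_csv = outdir / f"migration_{key}.csv"
            res.per_species.to_csv(per_species_csv)
            manifest.outputs[f"migration_{key}"] = str(per_species_csv)
            report["migration"][key] = {
                "SW_sum_to_pit": res.sw_sum_to_pit,
                "SW_sum_to_lake": res.sw_sum_to_lake,
                "SW_mean_of_sums": res.sw_mean_of_sums,
                "train_accuracy": res.train_accuracy,
                "test_accuracy": res.test_accuracy,
                "per_species": res.per_species,
            }
            rows.append(
                {
                    "lake": lake,
                    "pit": pit,
                    "SW_sum_to_pit": res.sw_sum_to_pit,
                    "SW_sum_to_lake": res.sw_sum_to_lake,
                    "SW_mean_of_sums": res.sw_mean_of_sums,
                }
            )
        if rows:
            summary_csv = outdir / "migration_summary.csv"
            pd.DataFrame(rows).to_csv(summary_csv, index=False)
            manifest.outputs["migration_summary"] = str(summary_csv)
        manifest.timings["migrate"] = time.perf_counter() - t0

    # -- community stats -----------------------------------------------------
    if "stats" in stages:
        t0 = time.perf_counter()
        summary = summarize_community(table)
        per_habitat_csv = outdir / "community_summary.csv"
        summary.per_habitat.to_csv(per_habitat_csv)
        manifest.outputs["community_summary"] = str(per_habitat_csv)
        kw = habitat_comparisons(table, statistic="biomass")
        report["stats"] = {
            "per_habitat": summary.per_habitat,
            "per_group": summary.per_group,
            "total": summary.total,
            "kruskal_wallis_biomass": {
                "H": kw.H,
                "df": kw.df,
                "p": kw.p,
                "posthoc": kw.posthoc,
            },
        }
        manifest.timings["stats"] = time.perf_counter() - t0

    # -- report --------------------------------------------------------------
    if "report" in stages:
        report_path = outdir / "report.json"
        bio.write_report(report, report_path)
        manifest.outputs["report_json"] = str(report_path)

    manifest.check()
    return manifest
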