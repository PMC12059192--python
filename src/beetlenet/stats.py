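"""Descriptive community summaries and nonparametric group comparisons.

Covers the Table-1/Table-2 style machinery: per-habitat abundance (N),
species richness (S), biomass totals, ecological-group shares (D, %), the
tie-corrected Kruskal-Wallis H test, and a Dunn-type post-hoc comparison of
mean ranks with Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .community import CommunityTable


class StatsError(ValueError):
    pass


@dataclass
class KWResult:
    """Kruskal-Wallis omnibus result with optional post-hoc table."""

    H: float
    df: int
    p: float
    posthoc: pd.DataFrame | None = None


@dataclass
class CommunitySummary:
    per_habitat: pd.DataFrame
    per_group: pd.DataFrame  # one row per (habitat, group)
    total: dict = field(default_factory=dict)


def summarize_community(table: CommunityTable) -> CommunitySummary:
    """Per-habitat S / N / biomass summary with ecological-group breakdown.

    For biomass-only data, N counts positive-biomass records (presences);
    species presence in a habitat is biomass > 0 in at least one sample.
    Group percentages D are shares of the habitat's N.
    """
    if table.n_samples == 0:
        raise StatsError("empty community table")
    habitat_rows = []
    group_rows = []
    groups = table.species_groups
    for habitat in sorted(table.habitat.unique()):
        sub = table.biomass.loc[table.habitat == habitat]
        positive = sub > 0
        n_records = int(positive.to_numpy().sum())
        richness_per_sample = positive.sum(axis=1)
        habitat_rows.append(
            {
                "habitat": habitat,
                "n_samples": sub.shape[0],
                "N": n_records,
                "S": int((positive.any(axis=0)).sum()),
                "total_biomass_mg": float(sub.to_numpy().sum()),
                "richness_min": int(richness_per_sample.min()),
                "richness_max": int(richness_per_sample.max()),
                "richness_mean": float(richness_per_sample.mean()),
                "richness_sd": float(richness_per_sample.std(ddof=1))
                if sub.shape[0] > 1
                else 0.0,
            }
        )
        for group in sorted(set(groups.values())) if groups else []:
            cols = [sp for sp in sub.columns if groups.get(sp) == group]
            gp = positive[cols]
            g_n = int(gp.to_numpy().sum())
            group_rows.append(
                {
                    "habitat": habitat,
                    "group": group,
                    "N": g_n,
                    "S": int(gp.any(axis=0).sum()),
                    "D_percent": 100.0 * g_n / n_records if n_records else 0.0,
                }
            )
    per_habitat = pd.DataFrame(habitat_rows).set_index("habitat")
    per_group = (
        pd.DataFrame(group_rows).set_index(["habitat", "group"])
        if group_rows
        else pd.DataFrame(columns=["N", "S", "D_percent"])
    )
    total = {
        "N": int(per_habitat["N"].sum()),
        "S": int((table.biomass > 0).any(axis=0).sum()),
        "total_biomass_mg": float(table.biomass.to_numpy().sum()),
        "n_samples": int(table.n_samples),
    }
    return CommunitySummary(
        per_habitat=per_habitat, per_group=per_group, total=total
    )


def kruskal_wallis(groups: list[np.ndarray | list]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k - 1)."""
    if len(groups) < 2:
        raise StatsError("at least 2 groups required")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise StatsError("every group needs at least 2 values")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return KWResult(H=0.0, df=df, p=1.0)
    H, p = sps.kruskal(*arrays)
    return KWResult(H=float(H), df=df, p=float(p))


def posthoc_mean_ranks(
    groups: list[np.ndarray | list],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Dunn-type pairwise z tests on mean ranks, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)) with
    tie correction T = sum(t^3 - t) / (12 (N - 1)); adjusted p =
    min(1, raw p * k(k-1)/2).  Computed for all pairs regardless of the
    omnibus outcome (flag significance downstream).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise StatsError("at least 2 groups required")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in arrays]
    mean_ranks = []
    start = 0
    for n_i in sizes:
        mean_ranks.append(ranks[start : start + n_i].mean())
        start += n_i

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    n_pairs = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0.0:
                z, p_raw = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p_raw = 2.0 * sps.norm.sf(abs(z))
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "z": float(z),
                    "p_raw": float(p_raw),
                    "p_adjusted": float(min(1.0, p_raw * n_pairs)),
                }
            )
    return pd.DataFrame(rows)


def habitat_comparisons(
    table: CommunityTable,
    statistic: str = "biomass",
) -> KWResult:
    """Kruskal-Wallis across habitats on a per-sample statistic.

    ``statistic``: "biomass" (per-sample total biomass), "richness"
    (per-sample species count) or "abundance" (per-sample positive records,
    identical to richness for biomass-only data).
    """
    groups = []
    labels = sorted(table.habitat.unique())
    for habitat in labels:
        sub = table.biomass.loc[table.habitat == habitat]
        if statistic == "biomass":
            groups.append(sub.sum(axis=1).to_numpy())
        elif statistic in ("richness", "abundance"):
            groups.append((sub > 0).sum(axis=1).to_numpy())
        else:
            raise StatsError(f"unknown statistic {statistic!r}")
    result = kruskal_wallis(groups)
    result.posthoc = posthoc_mean_ranks(groups, labels=labels)
    return result
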