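"""Core data container for species-by-sample biomass observations.

A :class:`CommunityTable` holds wet-biomass measurements (mg) for a set of
species observed across field samples, each sample labelled with the habitat
it came from.  Zero biomass means the species was absent from that sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Habitat labels used throughout: two post-exploitation water-body classes
#: ("pits") and three natural lake classes.
HABITATS = ("clay_pit", "gravel_pit", "mesotrophic", "eutrophic", "dystrophic")

#: Habitats that constitute the "pit" class in migration models.
PIT_HABITATS = ("clay_pit", "gravel_pit")

#: Habitats that constitute the "lake" class in migration models.
LAKE_HABITATS = ("mesotrophic", "eutrophic", "dystrophic")

#: Ecological groups of water beetles by habitat preference.
ECOLOGICAL_GROUPS = (
    "eurybiont",
    "tyrphophile",
    "argilophile",
    "rheophile",
    "rheobiont",
)


class CommunityValidationError(ValueError):
    """Raised when a biomass table violates its invariants."""


@dataclass
class CommunityTable:
    """Samples x species wet-biomass matrix with habitat labels.

    Parameters
    ----------
    biomass : pandas.DataFrame
        Non-negative finite biomass in mg; rows are samples (index = sample
        ids), columns are species (unique ids).  A value of 0 encodes absence.
    habitat : pandas.Series
        Habitat label per sample, aligned with ``biomass.index``.
    species_groups : dict, optional
        Mapping species id -> ecological group label.
    species_clusters : dict, optional
        Mapping species id -> cluster (sub-network) id, when known (e.g. for
        synthetic data with planted block structure).
    """

    biomass: pd.DataFrame
    habitat: pd.Series
    species_groups: dict[str, str] = field(default_factory=dict)
    species_clusters: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        values = self.biomass.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise CommunityValidationError(
                f"non-finite biomass at sample {self.biomass.index[bad[0]]!r}, "
                f"species {self.biomass.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise CommunityValidationError(
                f"negative biomass at sample {self.biomass.index[bad[0]]!r}, "
                f"species {self.biomass.columns[bad[1]]!r}"
            )
        if self.biomass.columns.duplicated().any():
            dups = self.biomass.columns[self.biomass.columns.duplicated()]
            raise CommunityValidationError(
                f"duplicate species ids: {sorted(set(dups))}"
            )
        if not self.habitat.index.equals(self.biomass.index):
            self.habitat = self.habitat.reindex(self.biomass.index)
        if self.habitat.isna().any():
            missing = self.habitat.index[self.habitat.isna()].tolist()
            raise CommunityValidationError(
                f"samples without a habitat label: {missing}"
            )

    # -- convenience --------------------------------------------------------
    @property
    def species(self) -> list[str]:
        return list(self.biomass.columns)

    @property
    def samples(self) -> list:
        return list(self.biomass.index)

    @property
    def n_samples(self) -> int:
        return self.biomass.shape[0]

    @property
    def n_species(self) -> int:
        return self.biomass.shape[1]

    def subset_habitat(self, habitat: str | list[str]) -> "CommunityTable":
        """Return the sub-table of samples from one habitat (or several)."""
        labels = [habitat] if isinstance(habitat, str) else list(habitat)
        mask = self.habitat.isin(labels)
        if not mask.any():
            raise KeyError(f"no samples with habitat in {labels}")
        return CommunityTable(
            biomass=self.biomass.loc[mask].copy(),
            habitat=self.habitat.loc[mask].copy(),
            species_groups=dict(self.species_groups),
            species_clusters=dict(self.species_clusters),
        )

    def copy(self) -> "CommunityTable":
        return CommunityTable(
            biomass=self.biomass.copy(),
            habitat=self.habitat.copy(),
            species_groups=dict(self.species_groups),
            species_clusters=dict(self.species_clusters),
        )

    def equals(self, other: "CommunityTable") -> bool:
        return (
            self.biomass.equals(other.biomass)
            and self.habitat.equals(other.habitat)
        )
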