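"""Per-habitat normalisation ahead of correlation-network inference.

Biomass columns are *autoscaled* (centred to zero mean, scaled to unit
sample standard deviation) within each habitat's sample subset, after
dropping species that cannot support a correlation estimate there (zero
variance, or observed in fewer than ``min_occurrence`` samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityTable


class PreprocessError(ValueError):
    pass


@dataclass
class ScaledMatrix:
    """Autoscaled (z-scored) biomass for one habitat's samples.

    ``data`` columns have mean 0 and unit sample SD (denominator n-1).
    ``dropped`` maps each removed species to the reason it was removed.
    """

    data: pd.DataFrame
    habitat: str
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)


def autoscale(
    table: CommunityTable | pd.DataFrame,
    habitat: str | None = None,
    min_occurrence: int = 2,
    population_sd: bool = False,
) -> ScaledMatrix:
    """Autoscale one habitat's biomass columns.

    Parameters
    ----------
    table : CommunityTable or DataFrame
        If a CommunityTable, ``habitat`` selects the sample subset; a plain
        DataFrame is scaled as-is (``habitat`` optional, used as a label).
    min_occurrence : int
        Minimum number of positive (presence) records a species needs to be
        retained; a species seen once cannot support a correlation.
    population_sd : bool
        If True scale by the population SD (denominator n) instead of the
        conventional sample SD (n-1).
    """
    if isinstance(table, CommunityTable):
        if habitat is None:
            frame = table.biomass
        else:
            frame = table.subset_habitat(habitat).biomass
    else:
        frame = table
    label = habitat if habitat is not None else "all"
    n = frame.shape[0]
    if n < 3:
        raise PreprocessError(
            f"habitat {label!r} has {n} samples; at least 3 required"
        )

    values = frame.to_numpy(dtype=float)
    dropped: dict[str, str] = {}
    keep: list[int] = []
    sds = values.std(axis=0, ddof=0)
    occ = (values > 0).sum(axis=0)
    # the presence filter only makes sense on raw (non-negative) biomass;
    # already-centred input is filtered on variance alone, which also makes
    # autoscaling idempotent
    is_raw = not (values < 0).any()
    for j, sp in enumerate(frame.columns):
        if sds[j] == 0.0:
            dropped[sp] = "zero variance"
        elif is_raw and occ[j] < min_occurrence:
            dropped[sp] = (
                f"fewer than {min_occurrence} positive records ({occ[j]})"
            )
        else:
            keep.append(j)
    if not keep:
        raise PreprocessError(
            f"all {frame.shape[1]} species dropped in habitat {label!r}"
        )

    sub = values[:, keep]
    ddof = 0 if population_sd else 1
    scaled = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=ddof)
    return ScaledMatrix(
        data=pd.DataFrame(
            scaled, index=frame.index, columns=frame.columns[keep]
        ),
        habitat=label,
        dropped=dropped,
    )
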