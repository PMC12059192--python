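"""Habitat-pair migration inference.

For a (lake habitat, pit habitat) pair, samples from the two habitats are
labelled class 0 (lake) and class 1 (pit) and a boosted-tree classifier is
trained to separate them from species biomass alone.  Shapley attributions
of the fitted margin then say, per species, whether high biomass pushes the
model toward the pit class (species does better in the pit — read as
migration toward the pit) or toward the lake class.

The per-species migration statistic SW follows the signed-magnitude recipe
(the "ABS_SHAP" convention): per repeat, magnitude = mean |phi| over the
explained observations, signed by the correlation between the species'
biomass values and its phi values; SW is the mean of the signed values over
``n_repeats`` independent 70/30 splits.  Directional aggregates:

* SW(sum) toward the pit  = sum of SW over species with SW > 0;
* SW(sum) toward the lake = sum of |SW| over species with SW < 0;
* SW(mean of sum) = the average of the two directional sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .boosting import BoostedEnsemble, accuracy, fit_boosted_classifier
from .community import CommunityTable
from .shapley import ShapleyAttribution, shapley_values


class MigrationError(ValueError):
    pass


@dataclass
class MigrationModelSpec:
    """Hyperparameters and protocol for one habitat-pair migration model."""

    lake_habitat: str
    pit_habitat: str
    n_trees: int = 1000
    max_depth: int = 10
    learning_rate: float = 0.001
    reg_lambda: float = 1.0
    train_fraction: float = 0.70
    n_repeats: int = 5
    shapley_mode: str = "auto"  # exact if few species, else montecarlo
    n_permutations: int = 10
    background_size: int = 100
    explain: str = "test"  # or "all"
    sign_convention: str = "abs_shap"  # or "signed_mean"

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise MigrationError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )
        if self.n_repeats < 1:
            raise MigrationError("n_repeats must be >= 1")
        for name in ("n_trees", "max_depth"):
            if getattr(self, name) < 1:
                raise MigrationError(f"{name} must be positive")
        if self.learning_rate < 0 or self.reg_lambda < 0:
            raise MigrationError("learning_rate and reg_lambda must be >= 0")


@dataclass
class MigrationSummary:
    """Aggregated migration statistics for one habitat pair."""

    lake_habitat: str
    pit_habitat: str
    per_species: pd.DataFrame  # SW, SD, direction per species
    sw_sum_to_pit: float
    sw_sum_to_lake: float
    sw_mean_of_sums: float
    train_accuracy: float = float("nan")
    test_accuracy: float = float("nan")

    def __post_init__(self) -> None:
        expected = 0.5 * (self.sw_sum_to_pit + self.sw_sum_to_lake)
        assert abs(self.sw_mean_of_sums - expected) < 1e-12


def signed_species_values(
    attribution: ShapleyAttribution,
    X_explain: np.ndarray,
    convention: str = "abs_shap",
) -> np.ndarray:
    """Per-species signed value for a single repeat.

    ``abs_shap``: mean |phi| signed by corr(biomass, phi); a species whose
    phi does not co-vary with its biomass (zero variance on either side)
    gets sign 0.  ``signed_mean``: plain mean of phi.
    """
    phi = attribution.phi
    if convention == "signed_mean":
        return phi.mean(axis=0)
    if convention != "abs_shap":
        raise MigrationError(f"unknown sign convention {convention!r}")
    X_explain = np.asarray(X_explain, dtype=float)
    out = np.zeros(phi.shape[1])
    for j in range(phi.shape[1]):
        mag = np.abs(phi[:, j]).mean()
        if mag == 0.0:
            continue
        x = X_explain[:, j]
        f = phi[:, j]
        if x.std() == 0.0 or f.std() == 0.0:
            continue
        sign = np.sign(np.corrcoef(x, f)[0, 1])
        out[j] = sign * mag
    return out


def migration_summary(
    repeats: list[tuple[ShapleyAttribution, np.ndarray]],
    species: list[str],
    lake_habitat: str = "lake",
    pit_habitat: str = "pit",
    convention: str = "abs_shap",
    train_accuracy: float = float("nan"),
    test_accuracy: float = float("nan"),
) -> MigrationSummary:
    """Aggregate per-repeat attributions into the pair's migration summary."""
    if not repeats:
        raise MigrationError("at least one repeat required")
    values = []
    for attribution, X_explain in repeats:
        if attribution.phi.shape[1] != len(species):
            raise MigrationError(
                f"repeat has {attribution.phi.shape[1]} species, "
                f"expected {len(species)}"
            )
        values.append(signed_species_values(attribution, X_explain, convention))
    stacked = np.vstack(values)  # (n_repeats, n_species)
    sw = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=1) if len(repeats) > 1 else np.zeros_like(sw)
    direction = np.where(sw > 0, "to-pit", np.where(sw < 0, "to-lake", "none"))

    frame = pd.DataFrame(
        {"SW": sw, "SD": sd, "direction": direction},
        index=pd.Index(species, name="species"),
    ).sort_values("SW", ascending=False)
    return summarize_directional(
        frame,
        lake_habitat,
        pit_habitat,
        train_accuracy=train_accuracy,
        test_accuracy=test_accuracy,
    )


def summarize_directional(
    per_species: pd.DataFrame,
    lake_habitat: str,
    pit_habitat: str,
    train_accuracy: float = float("nan"),
    test_accuracy: float = float("nan"),
) -> MigrationSummary:
    """Directional sums and their mean from a per-species SW frame."""
    sw = per_species["SW"].to_numpy()
    to_pit = float(sw[sw > 0].sum())
    to_lake = float(np.abs(sw[sw < 0]).sum())
    return MigrationSummary(
        lake_habitat=lake_habitat,
        pit_habitat=pit_habitat,
        per_species=per_species,
        sw_sum_to_pit=to_pit,
        sw_sum_to_lake=to_lake,
        sw_mean_of_sums=0.5 * (to_pit + to_lake),
        train_accuracy=train_accuracy,
        test_accuracy=test_accuracy,
    )


def mean_of_directional_sums(sum_to_pit: float, sum_to_lake: float) -> float:
    """SW(mean of sum): the average of the two directional SW sums."""
    return 0.5 * (sum_to_pit + sum_to_lake)


def run_migration_pair(
    table: CommunityTable,
    spec: MigrationModelSpec,
    seed: int = 0,
) -> MigrationSummary:
    """Full repeat protocol for one habitat pair.

    Per repeat: a fresh stratified 70/30 split, a boosted-tree fit, train and
    test accuracy, and Shapley attribution of the test partition against a
    (subsampled) training background.  Repeats are aggregated by
    :func:`migration_summary`.
    """
    spec.validate()
    sub = table.subset_habitat([spec.lake_habitat, spec.pit_habitat])
    for habitat in (spec.lake_habitat, spec.pit_habitat):
        n_h = int((sub.habitat == habitat).sum())
        if n_h < 10:
            raise MigrationError(
                f"habitat {habitat!r} has {n_h} samples; at least 10 required"
            )
    # restrict to species present in the pooled samples of this pair
    present = sub.biomass.columns[(sub.biomass > 0).any(axis=0)]
    X = sub.biomass[present].to_numpy(dtype=float)
    y = (sub.habitat == spec.pit_habitat).to_numpy().astype(int)
    species = list(present)

    mode = spec.shapley_mode
    if mode == "auto":
        mode = "exact" if len(species) <= 8 else "montecarlo"

    seeds = np.random.SeedSequence(seed).spawn(spec.n_repeats)
    repeats: list[tuple[ShapleyAttribution, np.ndarray]] = []
    train_accs: list[float] = []
    test_accs: list[float] = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        split_seed = int(rng.integers(0, 2**31 - 1))
        X_train, X_test, y_train, y_test = train_test_split(
            X,
            y,
            train_size=spec.train_fraction,
            stratify=y,
            random_state=split_seed,
        )
        model = fit_boosted_classifier(
            X_train,
            y_train,
            n_trees=spec.n_trees,
            max_depth=spec.max_depth,
            learning_rate=spec.learning_rate,
            reg_lambda=spec.reg_lambda,
            feature_names=species,
        )
        train_accs.append(accuracy(model, X_train, y_train))
        test_accs.append(accuracy(model, X_test, y_test))

        X_exp = X if spec.explain == "all" else X_test
        if X_train.shape[0] > spec.background_size:
            pick = rng.choice(
                X_train.shape[0], size=spec.background_size, replace=False
            )
            background = X_train[pick]
        else:
            background = X_train
        attribution = shapley_values(
            model,
            X_exp,
            background,
            mode=mode,
            n_permutations=spec.n_permutations,
            rng=rng,
        )
        repeats.append((attribution, X_exp))

    return migration_summary(
        repeats,
        species,
        lake_habitat=spec.lake_habitat,
        pit_habitat=spec.pit_habitat,
        convention=spec.sign_convention,
        train_accuracy=float(np.mean(train_accs)),
        test_accuracy=float(np.mean(test_accs)),
    )
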