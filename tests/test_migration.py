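import numpy as np
import pandas as pd
import pytest

from beetlenet import (
    MigrationModel,
    MigrationModelSpec,
    generate_community,
    inject_migration_signal,
    migration_summary,
    run_migration_pair,
)
from beetlenet.migration import (
    MigrationError,
    mean_of_directional_sums,
    signed_species_values,
)
from beetlenet.shapley import ShapleyAttribution


def _attribution(phi):
    phi = np.asarray(phi, dtype=float)
    return ShapleyAttribution(
        phi=phi,
        feature_names=[f"sp{j}" for j in range(phi.shape[1])],
        baseline=0.0,
        margins=phi.sum(axis=1),
        mode="exact",
    )


FAST = dict(n_trees=40, max_depth=4, learning_rate=0.3, n_repeats=2,
            shapley_mode="montecarlo", n_permutations=4, background_size=25)


def test_zero_attributions_give_zero_summary():
    species = ["a", "b", "c"]
    att = _attribution(np.zeros((10, 3)))
    X = np.random.default_rng(0).random((10, 3))
    summary = migration_summary([(att, X)], species)
    assert np.allclose(summary.per_species["SW"], 0.0)
    assert summary.sw_sum_to_pit == 0.0
    assert summary.sw_sum_to_lake == 0.0
    assert summary.sw_mean_of_sums == 0.0
    assert set(summary.per_species["direction"]) == {"none"}


def test_signed_magnitude_convention():
    rng = np.random.default_rng(1)
    x = rng.random(50)
    phi_pos = 0.2 * (x - x.mean())  # phi rises with biomass -> to-pit
    phi_neg = -0.1 * (x - x.mean())
    att = _attribution(np.column_stack([phi_pos, phi_neg]))
    sw = signed_species_values(att, np.column_stack([x, x]))
    assert sw[0] == pytest.approx(np.abs(phi_pos).mean())
    assert sw[1] == pytest.approx(-np.abs(phi_neg).mean())


def test_signed_mean_alternative_convention():
    phi = np.array([[0.5, -0.2], [0.1, -0.4]])
    att = _attribution(phi)
    sw = signed_species_values(att, np.ones((2, 2)), convention="signed_mean")
    assert sw == pytest.approx(phi.mean(axis=0))


def test_aggregation_antisymmetry_under_class_swap():
    """Negating all margins/attributions flips every SW sign exactly."""
    rng = np.random.default_rng(2)
    X = rng.random((30, 4))
    phi = 0.1 * (X - X.mean(axis=0)) * np.array([1.0, -1.0, 2.0, 0.0])
    s1 = migration_summary([(_attribution(phi), X)], list("abcd"))
    s2 = migration_summary([(_attribution(-phi), X)], list("abcd"))
    merged = s1.per_species["SW"].sort_index()
    flipped = s2.per_species["SW"].sort_index()
    assert np.allclose(merged.to_numpy(), -flipped.to_numpy())
    assert s1.sw_sum_to_pit == pytest.approx(s2.sw_sum_to_lake)


def test_directional_sum_arithmetic():
    per_species = pd.DataFrame(
        {"SW": [0.5, 0.406, -0.3, -0.108], "SD": 0.0,
         "direction": ["to-pit", "to-pit", "to-lake", "to-lake"]},
        index=pd.Index(list("abcd"), name="species"),
    )
    from beetlenet.migration import summarize_directional

    s = summarize_directional(per_species, "dystrophic", "gravel_pit")
    assert s.sw_sum_to_pit == pytest.approx(0.906)
    assert s.sw_sum_to_lake == pytest.approx(0.408)
    assert s.sw_mean_of_sums == pytest.approx(0.657)
    assert mean_of_directional_sums(0.388, 0.600) == pytest.approx(0.494)


def test_mismatched_species_sets_rejected():
    att3 = _attribution(np.zeros((5, 3)))
    with pytest.raises(MigrationError, match="species"):
        migration_summary([(att3, np.zeros((5, 3)))], ["a", "b"])


def test_spec_validation():
    with pytest.raises(MigrationError, match="train_fraction"):
        MigrationModelSpec("a", "b", train_fraction=1.2).validate()
    with pytest.raises(MigrationError, match="n_repeats"):
        MigrationModelSpec("a", "b", n_repeats=0).validate()


def test_insufficient_samples_error(tiny_table):
    spec = MigrationModelSpec("mesotrophic", "clay_pit")
    with pytest.raises(MigrationError, match="at least 10"):
        run_migration_pair(tiny_table, spec)


def test_planted_shift_has_largest_positive_sw(small_community):
    table = inject_migration_signal(
        small_community, {"sp001": np.log(4.0)}, "gravel_pit"
    )
    spec = MigrationModelSpec("dystrophic", "gravel_pit", **FAST)
    res = run_migration_pair(table, spec, seed=5)
    assert res.per_species["SW"].idxmax() == "sp001"
    assert res.per_species.loc["sp001", "SW"] > 0


def _symmetric_community(seed):
    """Two habitats with identical occupancy and biomass distributions."""
    from beetlenet import SyntheticConfig

    species = [f"sp{i:03d}" for i in range(1, 13)]
    habitats = ("gravel_pit", "dystrophic")
    return generate_community(
        SyntheticConfig(
            n_species=12,
            species_groups={sp: "eurybiont" for sp in species},
            n_samples_per_habitat={h: 80 for h in habitats},
            occupancy={h: {sp: 0.6 for sp in species} for h in habitats},
            biomass_location={h: {sp: 1.5 for sp in species} for h in habitats},
            biomass_scale=1.0,
            cluster_assignment={sp: i // 4 for i, sp in enumerate(species)},
            within_cluster_rho=0.5,
            seed=seed,
        )
    )


def test_null_pair_sw_centres_on_zero():
    """Identical biomass distributions in both classes: SW stays near 0."""
    spec = MigrationModelSpec(
        "dystrophic", "gravel_pit", n_trees=40, max_depth=4,
        learning_rate=0.001, n_repeats=2, shapley_mode="montecarlo",
        n_permutations=4, background_size=25,
    )
    medians = []
    for seed in range(5):
        res = run_migration_pair(_symmetric_community(seed), spec, seed=seed)
        medians.append(res.per_species["SW"].abs().median())
    assert np.median(medians) < 0.02


def test_label_swap_flips_direction(small_community):
    table = inject_migration_signal(
        small_community, {"sp001": np.log(4.0)}, "gravel_pit"
    )
    spec_fwd = MigrationModelSpec("dystrophic", "gravel_pit", **FAST)
    spec_rev = MigrationModelSpec("gravel_pit", "dystrophic", **FAST)
    fwd = run_migration_pair(table, spec_fwd, seed=5)
    rev = run_migration_pair(table, spec_rev, seed=5)
    assert fwd.per_species.loc["sp001", "SW"] > 0
    assert rev.per_species.loc["sp001", "SW"] < 0


def test_model_results_object(small_community):
    res = MigrationModel(
        small_community, "dystrophic", "gravel_pit", **FAST
    ).fit(seed=1)
    assert res.sw_mean_of_sums == pytest.approx(
        0.5 * (res.sw_sum_to_pit + res.sw_sum_to_lake)
    )
    text = res.summary()
    assert "gravel_pit" in text and "SW(mean of sum)" in text
    assert 0.0 <= res.test_accuracy <= 1.0
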