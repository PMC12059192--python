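import numpy as np
import pytest

from beetlenet import (
    SyntheticConfig,
    default_config,
    generate_community,
    inject_migration_signal,
)
from beetlenet.synthetic import ConfigurationError


def _simple_config(**overrides):
    base = dict(
        n_species=4,
        species_groups={f"sp{i}": "eurybiont" for i in range(1, 5)},
        n_samples_per_habitat={"clay_pit": 10, "mesotrophic": 10},
        occupancy={
            h: {f"sp{i}": 1.0 for i in range(1, 5)}
            for h in ("clay_pit", "mesotrophic")
        },
        biomass_location={
            h: {f"sp{i}": float(i) for i in range(1, 5)}
            for h in ("clay_pit", "mesotrophic")
        },
        biomass_scale=1.0,
        cluster_assignment={f"sp{i}": 0 for i in range(1, 5)},
        within_cluster_rho=0.0,
        seed=7,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def test_degenerate_noise_gives_exact_exponential_of_location():
    cfg = _simple_config(biomass_scale=0.0)
    table = generate_community(cfg)
    for i in range(1, 5):
        assert np.allclose(table.biomass[f"sp{i}"], np.exp(float(i)))


def test_same_seed_same_table_different_seed_differs():
    t1 = generate_community(_simple_config())
    t2 = generate_community(_simple_config())
    assert t1.equals(t2)
    t3 = generate_community(_simple_config(seed=8))
    assert not t1.equals(t3)


def test_within_cluster_correlation_exceeds_between():
    """Monte-Carlo check of the one-factor copula block structure."""
    species = [f"sp{i:02d}" for i in range(10)]
    cfg = SyntheticConfig(
        n_species=10,
        species_groups={sp: "eurybiont" for sp in species},
        n_samples_per_habitat={"clay_pit": 2000},
        occupancy={"clay_pit": {sp: 1.0 for sp in species}},
        biomass_location={"clay_pit": {sp: 0.0 for sp in species}},
        biomass_scale=1.0,
        cluster_assignment={sp: i // 5 for i, sp in enumerate(species)},
        within_cluster_rho=0.9,
        seed=11,
    )
    table = generate_community(cfg)
    logx = np.log(table.biomass.to_numpy())
    r = np.corrcoef(logx, rowvar=False)
    within, between = [], []
    for i in range(10):
        for j in range(i + 1, 10):
            (within if i // 5 == j // 5 else between).append(r[i, j])
    assert np.mean(within) > 0.8
    assert np.mean(within) > np.mean(between) + 0.5
    assert abs(np.mean(between)) < 0.1


def test_marginal_log_mean_converges_to_location():
    cfg = _simple_config(
        n_samples_per_habitat={"clay_pit": 2000}, biomass_scale=1.0
    )
    table = generate_community(cfg)
    se = 1.0 / np.sqrt(2000)
    for i in range(1, 5):
        col = table.biomass[f"sp{i}"].to_numpy()
        assert abs(np.log(col[col > 0]).mean() - float(i)) < 3 * se


def test_inject_zero_shift_is_identity():
    table = generate_community(_simple_config())
    out = inject_migration_signal(table, {"sp1": 0.0, "sp2": 0.0}, "clay_pit")
    assert out.equals(table)


def test_inject_log2_doubles_positive_pit_cells_only():
    cfg = _simple_config(
        occupancy={
            h: {f"sp{i}": 0.5 for i in range(1, 5)}
            for h in ("clay_pit", "mesotrophic")
        }
    )
    table = generate_community(cfg)
    out = inject_migration_signal(table, {"sp1": np.log(2.0)}, "clay_pit")
    pit = (table.habitat == "clay_pit").to_numpy()
    before = table.biomass["sp1"].to_numpy()
    after = out.biomass["sp1"].to_numpy()
    assert np.allclose(after[pit], 2.0 * before[pit])
    assert np.array_equal(after[~pit], before[~pit])
    # other species untouched everywhere
    assert table.biomass[["sp2", "sp3", "sp4"]].equals(
        out.biomass[["sp2", "sp3", "sp4"]]
    )


def test_inject_unknown_species_lists_offenders():
    table = generate_community(_simple_config())
    with pytest.raises(KeyError, match="nosuch"):
        inject_migration_signal(table, {"nosuch": 1.0}, "clay_pit")


@pytest.mark.parametrize(
    "field,value,message",
    [
        ("biomass_scale", -1.0, "biomass_scale"),
        ("within_cluster_rho", 1.0, "within_cluster_rho"),
    ],
)
def test_invalid_config_names_field(field, value, message):
    with pytest.raises(ConfigurationError, match=message):
        generate_community(_simple_config(**{field: value}))


def test_invalid_occupancy_names_field():
    cfg = _simple_config()
    cfg.occupancy["clay_pit"]["sp1"] = 1.5
    with pytest.raises(ConfigurationError, match="occupancy"):
        generate_community(cfg)


def test_default_config_matches_survey_scale():
    cfg = default_config()
    assert sum(cfg.n_samples_per_habitat.values()) == 1096
    table = generate_community(cfg)
    assert table.n_species == 40
    assert set(table.habitat.unique()) == {
        "clay_pit", "gravel_pit", "mesotrophic", "eutrophic", "dystrophic",
    }
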