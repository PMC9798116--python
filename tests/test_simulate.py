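import numpy as np
import pandas as pd
import pytest

from m6ascreen import (
    SimConfig,
    classify_evidence,
    planted_profile,
    profile_features,
    simulate_experiment,
)
from m6ascreen.errors import ConfigError
from m6ascreen.simulate import NULL, PlantedGene, noise_free, planted_cohort


def test_noise_free_model_is_deterministic_arithmetic():
    planted = [PlantedGene("G", NULL, (0.4, 0.4, 0.4), (100.0, 100.0, 100.0))]
    config = noise_free(SimConfig(n_genes=1, planted=planted, seed=0))
    table, sheet, truth = simulate_experiment(config)
    np.testing.assert_array_equal(table.ip.loc["PRB_G"], 40.0)
    np.testing.assert_array_equal(table.sup.loc["PRB_G"], 60.0)
    assert truth.loc["G", "category"] == NULL
    assert sheet.group_sizes() == {"OA": 3, "HP": 3, "SOMA": 3}


def test_seed_contract():
    a1, _, _ = simulate_experiment(SimConfig(n_genes=25, seed=42))
    a2, _, _ = simulate_experiment(SimConfig(n_genes=25, seed=42))
    b, _, _ = simulate_experiment(SimConfig(n_genes=25, seed=43))
    pd.testing.assert_frame_equal(a1.ip, a2.ip)
    pd.testing.assert_frame_equal(a1.sup, a2.sup)
    pd.testing.assert_frame_equal(a1.flags, a2.flags)
    assert not a1.ip.equals(b.ip)


def test_truth_table_records_all_planted_parameters():
    planted = planted_cohort({"v": 2, "i": 1})
    _, _, truth = simulate_experiment(SimConfig(n_genes=10, planted=planted, seed=1))
    assert len(truth) == 10
    assert (truth["category"] == "v").sum() == 2
    m, t = planted_profile("v")
    row = truth.loc["PLANT_V_000"]
    assert tuple(row[["m_OA", "m_HP", "m_SOMA"]]) == m
    assert tuple(row[["t_OA", "t_HP", "t_SOMA"]]) == t


@pytest.mark.parametrize(
    "kw, fragment",
    [
        (dict(n_per_group=1), "n_per_group"),
        (dict(groups=("OA", "HP")), "groups"),
        (dict(noise_sigma=-0.1), "noise_sigma"),
        (dict(flag_absent_rate=1.5), "flag_absent_rate"),
        (dict(spikein_level=0.0), "spikein_level"),
    ],
)
def test_config_errors_name_the_field(kw, fragment):
    with pytest.raises(ConfigError, match=fragment):
        simulate_experiment(SimConfig(n_genes=5, seed=0, **kw))


def test_invalid_planted_fraction_rejected():
    bad = [PlantedGene("G", NULL, (0.0, 0.5, 0.5), (1.0, 1.0, 1.0))]
    with pytest.raises(ConfigError, match=r"\(0, 1\)"):
        simulate_experiment(SimConfig(n_genes=1, planted=bad, seed=0))
    toomany = planted_cohort({"v": 3})
    with pytest.raises(ConfigError, match="n_genes"):
        simulate_experiment(SimConfig(n_genes=2, planted=toomany, seed=0))


def test_mean_level_approaches_truth_as_noise_shrinks():
    """E[100*IP/(IP+Sup)] -> 100*m for small multiplicative noise."""
    planted = [PlantedGene("G", NULL, (0.3, 0.3, 0.3), (200.0,) * 3)]
    config = SimConfig(
        n_genes=1, planted=planted, n_per_group=200, noise_sigma=0.05,
        flag_absent_rate=0.0, absent_quantile=0.0, seed=9,
    )
    table, _, _ = simulate_experiment(config)
    level = 100.0 * table.ip.loc["PRB_G"] / (table.ip.loc["PRB_G"] + table.sup.loc["PRB_G"])
    assert level.mean() == pytest.approx(30.0, abs=0.3)
    total = table.ip.loc["PRB_G"] + table.sup.loc["PRB_G"]
    assert total.mean() == pytest.approx(200.0, rel=0.02)


def test_spikeins_constant_truth_and_always_present():
    config = noise_free(SimConfig(n_genes=5, n_spikeins=4, spikein_level=777.0, seed=0))
    table, _, _ = simulate_experiment(config)
    spike = table.is_spikein
    assert spike.sum() == 4
    np.testing.assert_array_equal(table.ip.loc[spike], 777.0)
    np.testing.assert_array_equal(table.sup.loc[spike], 777.0)
    assert (table.flags.loc[spike] == "P").all().all()


def test_absent_flags_appear_at_requested_rate():
    config = SimConfig(
        n_genes=400, seed=2, flag_absent_rate=0.3, absent_quantile=0.0, marginal_rate=0.0
    )
    table, _, _ = simulate_experiment(config)
    rate = (table.flags.loc[~table.is_spikein] == "A").to_numpy().mean()
    assert rate == pytest.approx(0.3, abs=0.02)


class TestPlantedProfiles:
    def test_null_profile_is_flat(self):
        m, t = planted_profile(NULL)
        assert len(set(m)) == 1 and len(set(t)) == 1

    def test_unknown_category_and_bad_effect(self):
        with pytest.raises(ConfigError, match="category"):
            planted_profile("vi")
        with pytest.raises(ConfigError, match="effect_size"):
            planted_profile("v", effect_size=1.0)

    @pytest.mark.parametrize("category", ["i", "ii", "iii", "iv", "v"])
    @pytest.mark.parametrize("effect", [4.0, 8.0])
    def test_round_trip_through_classifier(self, category, effect):
        m, t = planted_profile(category, effect)
        call = classify_evidence(profile_features("G", m, t))
        assert call.category == category

    def test_category_iii_expression_discordant(self):
        m, t = planted_profile("iii")
        f = profile_features("G", m, t)
        assert f.expr_hp.direction != f.expr_soma.direction

    def test_all_profiles_show_lower_inoa_level(self):
        # the candidate universe is genes whose level drops in iNOA
        for category in ("i", "ii", "iii", "iv", "v"):
            m, t = planted_profile(category)
            f = profile_features("G", m, t)
            assert f.level_inoa < f.level_oa
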