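"""The latent-factor community generator and environmental simulator."""

import datetime as dt

import numpy as np
import pytest

from zoonet import (
    ClassSpec,
    CooccurrenceNetwork,
    ScenarioConfig,
    critical_r,
    default_class_specs,
    default_scenario,
    generate_class,
    generate_environment,
    generate_scenario,
    jaccard_similarity,
)
from zoonet.synthetic import cw_like_spec, monthly_sampling_dates, ww_like_spec


def log_corr(cm, a, b):
    la, lb = np.log(cm.biomass[a]), np.log(cm.biomass[b])
    return float(np.corrcoef(la, lb)[0, 1])


class TestGenerateClass:
    def test_independence_limit(self):
        spec = ClassSpec(name="x", n_taxa=12, n_guilds=2, guild_loading=0.0,
                         antagonist_fraction=0.0, antagonist_loading=0.0)
        cm, truth = generate_class(spec, 2000, seed=5)
        assert not truth.pairs
        cols = np.log(cm.biomass.to_numpy())
        r = np.corrcoef(cols, rowvar=False)
        off = np.abs(r[np.triu_indices_from(r, k=1)])
        assert off.mean() < 0.05

    def test_noiseless_limit(self):
        spec = ClassSpec(name="x", n_taxa=2, n_guilds=1, guild_loading=1.0,
                         antagonist_fraction=0.0, noise_sd=0.0, guild_coverage=1.0)
        cm, truth = generate_class(spec, 50, seed=1)
        pair = frozenset(cm.taxa)
        assert truth.population_r[pair] == pytest.approx(1.0)
        a, b = cm.taxa
        assert np.corrcoef(cm.biomass[a], cm.biomass[b])[0, 1] == pytest.approx(1.0)

    def test_closed_form_population_r(self):
        # a_i = a_j = 1, noise 1 -> rho = 1/2; empirical log-scale r at
        # n = 1000 within 0.05
        spec = ClassSpec(name="x", n_taxa=4, n_guilds=1, guild_loading=1.0,
                         antagonist_fraction=0.0, noise_sd=1.0, guild_coverage=1.0)
        cm, truth = generate_class(spec, 1000, seed=3)
        a, b = cm.taxa[0], cm.taxa[1]
        assert truth.population_r[frozenset((a, b))] == pytest.approx(0.5)
        assert log_corr(cm, a, b) == pytest.approx(0.5, abs=0.05)

    def test_sampling_distribution_of_r(self):
        """Fisher-z: at rho=0.5, n=84, r lies within ±0.2 of 0.5 in ≥95%
        of replicates (oracle probability ≈ 0.997)."""
        spec = ClassSpec(name="x", n_taxa=2, n_guilds=1, guild_loading=1.0,
                         antagonist_fraction=0.0, noise_sd=1.0, guild_coverage=1.0)
        hits = 0
        for seed in range(500):
            cm, _ = generate_class(spec, 84, seed=seed)
            a, b = cm.taxa
            hits += abs(log_corr(cm, a, b) - 0.5) <= 0.2
        assert hits / 500 >= 0.95

    def test_antagonists_have_negative_population_r(self):
        spec = ClassSpec(name="x", n_taxa=10, n_guilds=1, antagonist_fraction=0.4,
                         guild_coverage=1.0)
        _, truth = generate_class(spec, 20, seed=0)
        assert truth.negative_pairs
        assert all(truth.population_r[p] < 0 for p in truth.negative_pairs)
        assert all(truth.population_r[p] > 0 for p in truth.positive_pairs)
        assert not truth.positive_pairs & truth.negative_pairs

    def test_biomass_scaling_exact_and_nonnegative(self):
        spec = ClassSpec(name="x", n_taxa=20, biomass_scale=28.25)
        cm, _ = generate_class(spec, 84, seed=11)
        assert (cm.biomass.to_numpy() >= 0).all()
        assert cm.biomass.sum(axis=1).mean() == pytest.approx(28.25, rel=1e-12)

    def test_degenerate_guilds_rejected(self):
        spec = ClassSpec(name="x", n_taxa=5, n_guilds=3)
        with pytest.raises(ValueError, match="non-degenerate"):
            generate_class(spec, 20, seed=0)

    def test_type_one_calibration_of_nonedges(self):
        """Independent taxa cross the α=0.05 threshold ≈5% of the time."""
        spec = ClassSpec(name="x", n_taxa=33, n_guilds=2, guild_loading=0.0,
                         antagonist_fraction=0.0)
        cm, _ = generate_class(spec, 84, seed=21)
        res = CooccurrenceNetwork(cm).fit()
        n_pairs = 33 * 32 / 2
        rate = res.network.n_edges / n_pairs
        assert 0.03 <= rate <= 0.07


class TestEnvironment:
    def test_winter_temperature_matches_class_mean(self):
        spec = default_class_specs()[0]  # CW
        dates = [dt.date(2014, m, 15) for m in range(1, 13)]
        env = generate_environment(spec, 1200, seed=2, dates=dates)
        months = np.tile(np.arange(1, 13), 100)
        temps = env.values["Temperature"].to_numpy()
        winter = temps[np.isin(months, (12, 1, 2))]
        assert abs(winter.mean() - 5.63) <= 1.0

    def test_annual_mean_matches(self):
        for spec in default_class_specs():
            dates = [dt.date(2014, m, 15) for m in range(1, 13)]
            env = generate_environment(spec, 2400, seed=4, dates=dates)
            assert env.values["Temperature"].mean() == pytest.approx(
                spec.annual_temp_mean, abs=0.5
            )

    def test_degenerate_flat_profile_constant(self):
        spec = ClassSpec(name="x", n_taxa=5, winter_temp_mean=10.0,
                         winter_temp_sd=0.0, annual_temp_mean=10.0)
        env = generate_environment(spec, 24, seed=0)
        assert env.values["Temperature"].std() == pytest.approx(0.0)

    def test_do_negatively_coupled_to_temperature(self):
        from scipy.stats import spearmanr

        spec = default_class_specs()[0]
        neg = 0
        for seed in range(200):
            env = generate_environment(spec, 84, seed=seed)
            rho, _ = spearmanr(env.values["Temperature"], env.values["DO"])
            neg += rho < 0
        assert neg / 200 >= 0.95

    def test_profile_variables_present_and_nonnegative(self):
        spec = default_class_specs()[1]
        env = generate_environment(spec, 84, seed=9)
        assert set(spec.env_profile) <= set(env.variables)
        conc = env.values.drop(columns=["Temperature", "pH"])
        assert (conc.to_numpy() >= 0).all()


class TestScenario:
    def test_default_scenario_shape(self):
        com, env, truths = generate_scenario(default_scenario(3))
        assert com.n_samples == 252
        assert com.classes() == ["CW", "MW", "WW"]
        assert all((com.class_label == c).sum() == 84 for c in ("CW", "MW", "WW"))
        assert set(truths) == {"CW", "MW", "WW"}
        assert env.values.shape[0] == 252
        core = sum(t.startswith("taxon_core") for t in com.taxa)
        assert 0.24 <= core / com.n_taxa <= 0.28

    def test_shared_fraction_limits(self):
        classes = tuple(
            ClassSpec(name=n, n_taxa=20, n_guilds=2) for n in ("A", "B", "C")
        )
        com1, _, _ = generate_scenario(
            ScenarioConfig(classes=classes, n_samples_per_class=10, shared_fraction=1.0)
        )
        sets = {c: com1.subset_class(c).observed_taxa() for c in ("A", "B", "C")}
        assert jaccard_similarity(sets["A"], sets["B"]) == 100.0
        com0, _, _ = generate_scenario(
            ScenarioConfig(classes=classes, n_samples_per_class=10, shared_fraction=0.0)
        )
        sets0 = {c: com0.subset_class(c).observed_taxa() for c in ("A", "B", "C")}
        assert jaccard_similarity(sets0["A"], sets0["C"]) == 0.0

    def test_class_streams_independent_of_order(self):
        classes = tuple(ClassSpec(name=n, n_taxa=12, n_guilds=2) for n in ("A", "B"))
        cfg_ab = ScenarioConfig(classes=classes, n_samples_per_class=12, rng_seed=5)
        cfg_ba = ScenarioConfig(classes=classes[::-1], n_samples_per_class=12, rng_seed=5)
        com_ab, _, _ = generate_scenario(cfg_ab)
        com_ba, _, _ = generate_scenario(cfg_ba)
        a1 = com_ab.subset_class("A").biomass
        a2 = com_ba.subset_class("A").biomass
        np.testing.assert_allclose(a1.to_numpy(), a2[a1.columns].to_numpy())

    def test_presets_produce_cohesion_gradient(self):
        """CW-like preset beats WW-like on clustering and centralization and
        has shorter characteristic paths in most seeded runs."""
        wins = 0
        for seed in range(10):
            cm_a, _ = generate_class(cw_like_spec(), 84, seed)
            cm_b, _ = generate_class(ww_like_spec(), 84, seed + 9999)
            ga = CooccurrenceNetwork(cm_a).fit().global_attributes()
            gb = CooccurrenceNetwork(cm_b).fit().global_attributes()
            wins += (
                ga.clustering_coefficient > gb.clustering_coefficient
                and ga.network_centralization > gb.network_centralization
                and ga.characteristic_path_length < gb.characteristic_path_length
            )
        assert wins >= 8

    def test_sampling_calendar(self):
        dates = monthly_sampling_dates(84)
        assert len(dates) == 84
        assert len(set(dates)) == 28  # 28 months × 3 stations
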