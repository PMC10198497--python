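"""Population generator: marginals, the four-quantile joint sampler,
screening assignment, mortality and the CSV configuration layer."""

import numpy as np
import pandas as pd
import pytest

import mammosim as m
from mammosim.synthetic_population import (
    ConfigError,
    assign_screening,
    conditional_quantile_sample,
    gompertz_life_table,
    load_population_tables,
    quantile_joint_sample,
    sample_death_ages,
    save_population_tables,
)


class TestSamplePopulation:
    def test_empty(self, config):
        assert m.sample_population(config, 0, seed=1) == []

    def test_deterministic_given_seed(self, config):
        a = m.sample_population(config, 300, seed=11)
        b = m.sample_population(config, 300, seed=11)
        assert a == b

    def test_different_seeds_differ(self, config):
        a = m.sample_population(config, 300, seed=11)
        b = m.sample_population(config, 300, seed=12)
        assert a != b

    def test_every_individual_satisfies_invariants(self, config):
        # Individual.__post_init__ validates; sampling 5,000 without raising
        # plus explicit re-validation is the check
        pop = m.sample_population(config, 5_000, seed=2)
        for ind in pop:
            ind.validate()

    def test_marginals_within_three_binomial_sds(self, config):
        n = 30_000
        pop = m.sample_population(config, n, seed=3)

        def check(observed_frac, p):
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(observed_frac - p) < 3 * sd

        check(np.mean([i.smoker for i in pop]), config.smoker_prob)
        check(
            np.mean([i.bmi_category == "obese" for i in pop]),
            config.bmi_category_probs["obese"],
        )
        check(
            np.mean([i.race_ethnicity == "white" for i in pop]),
            config.race_ethnicity_probs["white"],
        )
        check(
            np.mean([i.oc_start_age is not None for i in pop]),
            config.oc_ever_prob,
        )

    def test_prs_standard_normal(self, config):
        pop = m.sample_population(config, 30_000, seed=4)
        prs = np.array([i.prs for i in pop])
        assert np.mean(prs) == pytest.approx(0.0, abs=0.02)
        assert np.std(prs) == pytest.approx(1.0, abs=0.02)

    def test_ht_use_begins_at_menopause_by_construction(self, config):
        # HT is represented as a duration only; the engine and modifiers
        # anchor the window at each woman's menopause age
        pop = m.sample_population(config, 2_000, seed=5)
        users = [i for i in pop if i.ht_duration > 0]
        assert users
        assert all(i.ht_duration >= 1 for i in users)

    def test_inconsistent_config_rejected(self, config):
        import copy

        bad = copy.deepcopy(config)
        bad.menarche_dist = {45: 0.5, 46: 0.5}  # overlaps menopause support
        with pytest.raises(ConfigError):
            m.sample_population(bad, 10, seed=0)


class TestQuantileJointSample:
    def test_identical_pairs_always_returned(self, rng):
        pairs = np.tile([(23.0, 31.0)], (40, 1))
        out = quantile_joint_sample(pairs, 4, rng, size=50)
        assert np.all(out[:, 0] == 23.0)
        assert np.all(out[:, 1] == 31.0)

    def test_empty_input_rejected(self, rng):
        with pytest.raises(ValueError):
            quantile_joint_sample(np.empty((0, 2)), 4, rng)

    def test_uniform_margins_have_quartile_median_support(self, rng):
        pairs = rng.random((200_000, 2))
        out = quantile_joint_sample(pairs, 4, rng, size=5_000)
        support = np.unique(out[:, 0])
        assert len(support) == 4
        # quartile medians of U(0,1) are the 12.5/37.5/62.5/87.5 centiles
        np.testing.assert_allclose(
            support, [0.125, 0.375, 0.625, 0.875], atol=0.01
        )

    def test_cell_probabilities_match_empirical_joint(self, rng):
        # correlated input: cells must be drawn with their empirical freq
        x = rng.random(4_000)
        y = np.clip(x + rng.normal(0, 0.2, 4_000), 0, 1)
        pairs = np.column_stack([x, y])
        n_draw = 100_000
        out = quantile_joint_sample(pairs, 4, rng, size=n_draw)

        s_support = np.sort(np.unique(out[:, 0]))
        t_support = np.sort(np.unique(out[:, 1]))
        # reconstruct empirical cell frequencies from the input
        from mammosim.synthetic_population import _quantile_bins

        sb, _ = _quantile_bins(pairs[:, 0], 4)
        tb, _ = _quantile_bins(pairs[:, 1], 4)
        for i, sv in enumerate(s_support):
            for j, tv in enumerate(t_support):
                p_emp = np.mean((sb == i) & (tb == j))
                p_draw = np.mean((out[:, 0] == sv) & (out[:, 1] == tv))
                sd = np.sqrt(max(p_emp, 1e-9) * (1 - p_emp) / n_draw)
                assert abs(p_draw - p_emp) < 4 * sd + 1e-3

    def test_conditional_sampler_respects_start_quantile(self, rng):
        # durations increase with starting age in this synthetic input;
        # conditioning on a high start must shift durations upward
        start = np.repeat([10.0, 20.0, 30.0, 40.0], 25)
        dur = start / 10.0 + rng.normal(0, 0.1, 100)
        pairs = np.column_stack([start, dur])
        low = conditional_quantile_sample(pairs, np.full(500, 10.0), 4, rng)
        high = conditional_quantile_sample(pairs, np.full(500, 40.0), 4, rng)
        assert low.mean() < high.mean()


class TestAssignScreening:
    def test_degenerate_distribution(self, config, rng):
        import copy

        cfg = copy.deepcopy(config)
        key = next(iter(cfg.screening_freq_dist))
        dist = np.zeros(8)
        dist[7] = 1.0
        cfg.screening_freq_dist[key] = dist
        draws = [assign_screening(key[0], key[1], cfg, rng) for _ in range(20)]
        assert draws == [7] * 20

    def test_half_never_half_annual_gives_mean_3_5(self, config, rng):
        import copy

        cfg = copy.deepcopy(config)
        key = next(iter(cfg.screening_freq_dist))
        dist = np.zeros(8)
        dist[0] = 0.5
        dist[7] = 0.5
        cfg.screening_freq_dist[key] = dist
        draws = np.array(
            [assign_screening(key[0], key[1], cfg, rng) for _ in range(20_000)]
        )
        assert draws.mean() == pytest.approx(3.5, abs=0.1)

    def test_unknown_stratum_and_bad_probabilities(self, config, rng):
        with pytest.raises(KeyError):
            assign_screening("martian", False, config, rng)
        import copy

        cfg = copy.deepcopy(config)
        key = next(iter(cfg.screening_freq_dist))
        cfg.screening_freq_dist[key] = np.full(8, 0.2)
        with pytest.raises(ConfigError):
            assign_screening(key[0], key[1], cfg, rng)


class TestMortality:
    def test_gompertz_life_expectancy_near_81(self):
        surv = gompertz_life_table()
        le = np.cumprod(surv).sum()
        assert le == pytest.approx(81.0, abs=1.5)

    def test_death_ages_within_table(self, rng):
        surv = gompertz_life_table(max_age=100)
        deaths = sample_death_ages(surv, 10_000, rng)
        assert deaths.min() >= 1
        assert deaths.max() <= 100
        assert 70 < deaths.mean() < 90


class TestCsvConfigLayer:
    def test_round_trip(self, config, tmp_path):
        save_population_tables(config, tmp_path)
        loaded = load_population_tables(tmp_path)
        assert loaded.age_pyramid == config.age_pyramid
        assert loaded.menarche_dist == config.menarche_dist
        np.testing.assert_allclose(loaded.oc_pairs, config.oc_pairs)
        np.testing.assert_allclose(
            loaded.mortality_table, config.mortality_table
        )
        for key, dist in config.screening_freq_dist.items():
            np.testing.assert_allclose(
                loaded.screening_freq_dist[key], dist
            )

    def test_missing_table_reported_by_name(self, tmp_path):
        with pytest.raises(ConfigError, match="age_pyramid"):
            load_population_tables(tmp_path)

    def test_zero_weight_pyramid_rejected(self, config, tmp_path):
        save_population_tables(config, tmp_path)
        pyr = pd.read_csv(tmp_path / "age_pyramid.csv")
        pyr["weight"] = 0.0
        pyr.to_csv(tmp_path / "age_pyramid.csv", index=False)
        with pytest.raises(ConfigError, match="weights"):
            load_population_tables(tmp_path)
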