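"""Stochastic visit simulator: conservation, determinism, allocation."""

import numpy as np
import pytest
from scipy import stats

from floralscape import (
    ConfigurationError,
    EnvironmentConfig,
    FlowerPopulation,
    PollinatorSpec,
    additive_baseline,
    build_population,
    calibrate_gaussian_curve,
    fig_environment,
    fig_guild,
    fig_population,
    make_flat_curve,
    simulate_environment,
)


class TestBuildPopulation:
    def test_canonical_population(self):
        pop = build_population(100, 0, 1, 160_000)
        assert pop.n_flowers == 100
        np.testing.assert_allclose(pop.phenotype_array, np.linspace(0, 1, 100))
        assert pop.pollen_budget == 160_000

    def test_two_flower_endpoints(self):
        pop = build_population(2, 0, 1, 10)
        assert pop.phenotypes == (0.0, 1.0)

    @pytest.mark.parametrize(
        "args", [(1, 0, 1, 10), (5, 1, 0, 10), (5, 0, 1, 0), (5, 0.5, 0.5, 10)]
    )
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            build_population(*args)


class TestSimulateEnvironment:
    def test_visit_counts_sum_to_total_every_iteration(self, mixed_result, mixed_env):
        per_iter = mixed_result.visits.sum(axis=(1, 2))
        assert np.all(per_iter == mixed_env.total_visits)

    def test_pollen_conservation(self, mixed_result, population):
        removed = mixed_result.removed.sum(axis=2)
        assert np.all(removed >= 0)
        assert np.all(removed <= population.pollen_budget)
        max_eff = max(p.transfer_efficiency for p in mixed_result.env.guild)
        exported = mixed_result.exported.sum(axis=2)
        assert np.all(exported <= removed * max_eff + 1e-6)
        assert np.all(mixed_result.exported <= mixed_result.removed * max_eff + 1e-9)

    def test_single_visit_removes_printed_peak_and_exports_four_percent(self):
        """One hummingbird visit to a fresh flower at its optimum: 10000 removed, 400 exported."""
        _, bird = fig_guild()
        pop = FlowerPopulation(phenotypes=(0.75, 0.75), pollen_budget=160_000)
        env = EnvironmentConfig(guild=(bird,), mixture=(1.0,), total_visits=1, n_iterations=1, seed=5)
        res = simulate_environment(pop, env)
        assert res.removed.sum() == pytest.approx(10_000, rel=1e-12)
        assert res.exported.sum() == pytest.approx(400, rel=1e-12)

    def test_removal_capped_by_remaining_pollen(self):
        """A nearly empty flower yields only what it has left."""
        spec = PollinatorSpec(
            label="p",
            attraction=make_flat_curve(1.0),
            removal=make_flat_curve(7_071.0),
            transfer_efficiency=0.04,
        )
        pop = FlowerPopulation(phenotypes=(0.5, 0.5), pollen_budget=1_000)
        env = EnvironmentConfig(guild=(spec,), mixture=(1.0,), total_visits=50, n_iterations=1, seed=0)
        res = simulate_environment(pop, env)
        per_flower = res.removed[0].sum(axis=1)
        assert np.all(per_flower <= 1_000)
        assert res.removed.sum() == pytest.approx(2_000)  # both flowers fully drained

    def test_seed_determinism_and_divergence(self, population):
        r1 = simulate_environment(population, fig_environment(seed=42, n_iterations=2))
        r2 = simulate_environment(population, fig_environment(seed=42, n_iterations=2))
        r3 = simulate_environment(population, fig_environment(seed=43, n_iterations=2))
        np.testing.assert_array_equal(r1.visits, r2.visits)
        np.testing.assert_array_equal(r1.removed, r2.removed)
        np.testing.assert_array_equal(r1.exported, r2.exported)
        assert np.any(r1.visits != r3.visits)

    def test_degenerate_mixture_equals_single_pollinator_run(self, population):
        """Weights (1, 0) reproduce the one-pollinator environment bit for bit."""
        bee, bird = fig_guild()
        mixed = EnvironmentConfig(
            guild=(bee, bird), mixture=(1.0, 0.0), total_visits=500, n_iterations=3, seed=9
        )
        single = EnvironmentConfig(
            guild=(bee,), mixture=(1.0,), total_visits=500, n_iterations=3, seed=9
        )
        rm = simulate_environment(population, mixed)
        rs = simulate_environment(population, single)
        np.testing.assert_array_equal(rm.visits[:, :, 0], rs.visits[:, :, 0])
        np.testing.assert_array_equal(rm.removed[:, :, 0], rs.removed[:, :, 0])
        assert rm.visits[:, :, 1].sum() == 0

    def test_visit_allocation_follows_attraction_weights(self):
        """With depletion off, visit counts match attraction by chi-square."""
        bee, bird = fig_guild()
        no_removal = make_flat_curve(0.0)
        guild = (
            PollinatorSpec("bee", bee.attraction, no_removal, 0.02),
            PollinatorSpec("bird", bird.attraction, no_removal, 0.04),
        )
        pop = build_population(10, 0, 1, 1.0)
        env = EnvironmentConfig(
            guild=guild, mixture=(0.5, 0.5), total_visits=3_500, n_iterations=4, seed=11
        )
        res = simulate_environment(pop, env)
        z = pop.phenotype_array
        expected_p = np.zeros(10)
        for w, spec in zip(env.mixture, guild):
            a = np.asarray(spec.attraction(z))
            expected_p += w * a / a.sum()
        observed = res.visits.sum(axis=(0, 2)).astype(float)
        expected = expected_p * observed.sum()
        assert expected.min() >= 5
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_zero_attraction_guild_member_rejected(self, population):
        spec = PollinatorSpec(
            "ghost", make_flat_curve(0.0), make_flat_curve(100.0), 0.05
        )
        env = EnvironmentConfig(guild=(spec,), mixture=(1.0,), total_visits=10, n_iterations=1)
        with pytest.raises(ConfigurationError):
            simulate_environment(population, env)

    def test_attraction_above_one_rejected(self, population):
        from floralscape import make_tabulated_curve

        bad = PollinatorSpec(
            "bad",
            make_tabulated_curve([0.0, 1.0], [1.5, 1.5]),  # not a probability
            make_flat_curve(1.0),
            0.05,
        )
        env = EnvironmentConfig(guild=(bad,), mixture=(1.0,), total_visits=10, n_iterations=1)
        with pytest.raises(ValueError, match="outside"):
            simulate_environment(population, env)


class TestAdditiveBaseline:
    def test_sums_single_environment_means(self, population):
        env = fig_environment(seed=3, n_iterations=2)
        base = additive_baseline(population, env)
        assert len(base.components) == 2
        for metric in ("visits", "removal", "export"):
            expected = sum(c.per_flower_mean(metric) for c in base.components)
            np.testing.assert_allclose(base.per_flower_mean(metric), expected, rtol=1e-12)
        assert base.notice is None

    def test_additive_removal_can_exceed_the_budget(self, population):
        """No shared pollen pool: summed removal tops 160 000 by design."""
        base = additive_baseline(population, fig_environment(seed=0))
        assert base.per_flower_mean("removal").max() > population.pollen_budget

    def test_single_pollinator_guild_returns_notice(self, population):
        bee, _ = fig_guild()
        env = EnvironmentConfig(
            guild=(bee,), mixture=(1.0,), total_visits=200, n_iterations=2, seed=1
        )
        base = additive_baseline(population, env)
        assert base.notice is not None
        single = simulate_environment(population, env)
        np.testing.assert_allclose(
            base.per_flower_mean("export"), single.per_flower_mean("export"), rtol=1e-12
        )


class TestResultContainers:
    def test_dataframe_shape_and_totals(self, mixed_result, mixed_env):
        df = mixed_result.to_dataframe()
        assert set(df.columns) == {
            "iteration", "flower_id", "phenotype", "pollinator",
            "visits", "pollen_removed", "pollen_exported",
        }
        assert len(df) == mixed_env.n_iterations * 100 * 2
        assert df["visits"].sum() == mixed_env.n_iterations * mixed_env.total_visits

    def test_metadata_echoes_configuration(self, mixed_result, mixed_env):
        md = mixed_result.metadata
        assert md["seed"] == mixed_env.seed
        assert md["total_visits"] == mixed_env.total_visits
        assert md["guild"] == ["bee", "hummingbird"]
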