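import numpy as np
import pytest

from assemblage.raupcrick import bray_curtis
from assemblage.simulate import (
    ScenarioConfig,
    evolve_trait,
    guild_conservatism,
    simulate_communities,
    simulate_dataset,
    simulate_tree,
    write_dataset,
)


class TestSimulateTree:
    def test_two_tips(self):
        tree = simulate_tree(2, seed=0)
        assert tree.n_tips == 2
        for leaf in tree.tree.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(1.0)

    def test_ultrametric(self):
        tree = simulate_tree(40, seed=3)
        depths = [leaf.distance_from_root() for leaf in tree.tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9
        assert max(depths) == pytest.approx(1.0)

    def test_seed_determinism(self):
        assert simulate_tree(16, seed=5).as_newick() == simulate_tree(16, seed=5).as_newick()
        assert simulate_tree(16, seed=5).as_newick() != simulate_tree(16, seed=6).as_newick()

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)


class TestEvolveTrait:
    def test_degenerate_sigma_zero(self):
        tree = simulate_tree(8, seed=1)
        traits = evolve_trait(tree, 0.0, seed=0)
        assert (traits == 0).all()

    def test_variance_matches_brownian_closed_form(self):
        # var(tip trait) = sigma^2 * root-to-tip length = sigma^2 on a
        # depth-1 tree; checked over replicate evolutions
        tree = simulate_tree(12, seed=2)
        sigma = 1.3
        reps = np.array(
            [evolve_trait(tree, sigma, seed=s).to_numpy() for s in range(2000)]
        )
        per_tip_var = reps.var(axis=0)
        assert abs(per_tip_var.mean() - sigma**2) / sigma**2 < 0.05

    def test_sister_tips_more_correlated_than_distant(self):
        from assemblage.phylo import cophenetic_matrix

        tree = simulate_tree(16, seed=4)
        dm = cophenetic_matrix(tree, labels=tree.tip_labels)
        iu = np.triu_indices(16, 1)
        closest = np.argmin(dm.d[iu])
        farthest = np.argmax(dm.d[iu])
        reps = np.array(
            [evolve_trait(tree, 1.0, seed=s).loc[tree.tip_labels].to_numpy() for s in range(300)]
        )
        corr = np.corrcoef(reps.T)
        assert corr[iu[0][closest], iu[1][closest]] > corr[iu[0][farthest], iu[1][farthest]]


class TestSimulateCommunities:
    def test_column_sums_equal_depth(self):
        for scenario in ["neutral", "drift", "homogeneous_selection", "variable_selection",
                         "homogenizing_dispersal", "dispersal_limitation"]:
            cfg = ScenarioConfig(scenario=scenario, n_taxa=32, n_groups=2,
                                 n_samples_per_group=3, depth=211, guild_size=8, seed=1)
            _, _, table, meta, _ = simulate_dataset(cfg)
            assert (table.counts.sum(axis=0) == 211).all()
            assert set(meta.groups()) == {"Oi", "Oe"}

    def test_wide_filter_limit_is_uniform(self):
        # as sigma_f grows the Gaussian filter flattens and expected
        # abundances become uniform (non-guild mode, no demographic noise)
        cfg = ScenarioConfig(
            scenario="homogeneous_selection", n_taxa=64, n_groups=1,
            n_samples_per_group=8, depth=50_000, filter_width=1e9,
            guild_size=None, conservatism_ratio=None, noise_sigma=0.0, seed=2,
        )
        _, _, table, _, _ = simulate_dataset(cfg)
        freq = table.counts.sum(axis=1) / table.counts.sum()
        assert freq.max() / freq.min() < 1.3  # multinomial noise only

    def test_separated_groups_diverge_compositionally(self):
        # two groups 6 sigma_f apart: between-group Bray-Curtis exceeds
        # within-group in (at least) 19 of 20 seed replicates
        wins = 0
        for seed in range(20):
            cfg = ScenarioConfig(
                scenario="variable_selection", n_taxa=64, n_groups=2,
                n_samples_per_group=3, depth=500, filter_width=0.3,
                env_separation=6.0, guild_size=None, conservatism_ratio=None,
                noise_sigma=0.5, seed=seed,
            )
            _, _, table, meta, _ = simulate_dataset(cfg)
            counts = table.counts
            groups = meta.groups().to_numpy()
            within, between = [], []
            for i in range(counts.shape[1]):
                for j in range(i + 1, counts.shape[1]):
                    bc = bray_curtis(counts[:, i], counts[:, j])
                    (within if groups[i] == groups[j] else between).append(bc)
            wins += np.mean(between) > np.mean(within)
        assert wins >= 19

    def test_dataset_determinism(self, tmp_path):
        cfg = ScenarioConfig(scenario="neutral", n_taxa=24, n_groups=2,
                             n_samples_per_group=2, depth=100, guild_size=8, seed=9)
        write_dataset(cfg, tmp_path / "a")
        write_dataset(cfg, tmp_path / "b")
        for name in ["tree.nwk", "table.tsv", "metadata.tsv", "traits.tsv"]:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_guild_conservatism_diagnostic(self):
        from assemblage.phylo import cophenetic_matrix

        tree = simulate_tree(64, seed=3)
        dm = cophenetic_matrix(tree, labels=tree.tip_labels)
        traits = evolve_trait(tree, 1.0, seed=3)
        tv = traits.loc[tree.tip_labels].to_numpy()
        env, ratio = guild_conservatism(tv, dm.d, 12)
        assert tv.min() <= env <= tv.max()
        assert 0 < ratio < 1.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(scenario="nope"),
            dict(n_taxa=0),
            dict(filter_width=0.0),
            dict(migration_rate=1.5),
            dict(guild_size=1),
        ],
    )
    def test_config_validation(self, kwargs):
        with pytest.raises(ValueError):
            ScenarioConfig(**kwargs)
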