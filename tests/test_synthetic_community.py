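import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hadal.synthetic_community import (
    SimulationConfig,
    brownian_optima,
    depth_gradient,
    logseries_metacommunity,
    simulate_metadata,
    simulate_neutral,
    simulate_niche,
    simulate_study,
    simulate_tree,
    _niche_weights,
)


class TestTree:
    def test_two_tip_cherry_is_ultrametric(self):
        tree = simulate_tree(2, seed=0)
        depths = [t.accumulate_to_ancestor(tree) for t in tree.tips()]
        assert depths[0] == pytest.approx(depths[1], abs=1e-9)

    def test_binary_tree_internal_node_count(self):
        tree = simulate_tree(50, seed=1)
        internal = sum(1 for n in tree.non_tips(include_self=True))
        assert internal == 49
        assert sum(1 for _ in tree.tips()) == 50

    def test_ultrametric_for_any_size(self):
        tree = simulate_tree(20, seed=3)
        depths = np.array([t.accumulate_to_ancestor(tree) for t in tree.tips()])
        assert depths.std() < 1e-9

    def test_yule_height_expectation(self):
        # pure birth, rate 1: E[height] = sum_{k=2}^{n} 1/k once the
        # stem is excluded; check the empirical mean over many trees
        n = 16
        heights = []
        for seed in range(300):
            tree = simulate_tree(n, seed=seed)
            tips = list(tree.tips())
            heights.append(tips[0].accumulate_to_ancestor(tree))
        expected = sum(1.0 / k for k in range(2, n + 1))
        assert np.mean(heights) == pytest.approx(expected, rel=0.15)

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            simulate_tree(1)


class TestMetacommunity:
    def test_logseries_shape(self):
        p = logseries_metacommunity(500, seed=0)
        assert p.sum() == pytest.approx(1.0)
        assert (p > 0).all()
        # heavy-tailed: the top decile holds most of the mass
        top = np.sort(p)[::-1][:50].sum()
        assert top > 0.5


class TestNeutral:
    def test_fixed_seed_bit_identical(self):
        cfg = SimulationConfig(n_taxa=60, local_size=500, sequencing_depth=1000,
                               generations=10, seed=9)
        a, _ = simulate_neutral(cfg)
        b, _ = simulate_neutral(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_column_sums_equal_sequencing_depth(self):
        cfg = SimulationConfig(n_taxa=60, local_size=500, sequencing_depth=1234,
                               generations=10, seed=2)
        table, _ = simulate_neutral(cfg)
        assert (table.sample_sums() == 1234).all()

    def test_full_immigration_matches_metacommunity(self):
        # m = 1: every sample is an iid multinomial draw from p, so the
        # mean relative abundance of each taxon sits within 3 SE of p_i
        depths = tuple(np.linspace(10, 9000, 100))
        cfg = SimulationConfig(
            n_taxa=50, depths=depths, pore_sizes=(0.22, 3.0),
            m=1.0, local_size=400, sequencing_depth=800, generations=10, seed=5,
        )
        table, truth = simulate_neutral(cfg)
        rel = table.relative().mean(axis=1)
        p = truth.metacommunity
        # two sampling layers: the local community of N_L individuals,
        # then S reads drawn from it
        var_per_sample = p * (1 - p) * (1.0 / 400 + 1.0 / 800)
        se = np.sqrt(var_per_sample / table.n_samples)
        z = (rel - p) / se.clip(lower=1e-9)
        assert (np.abs(z) < 3).mean() > 0.95

    def test_drift_to_monodominance_at_tiny_m(self):
        cfg = SimulationConfig(
            n_taxa=40, depths=(100.0, 1000.0), pore_sizes=(0.22,),
            m=0.001, local_size=300, sequencing_depth=1000, generations=300, seed=8,
        )
        table, _ = simulate_neutral(cfg)
        max_rel = table.relative().max(axis=0)
        assert (max_rel > 0.6).all()

    def test_occurrence_frequency_tracks_metacommunity_abundance(self):
        depths = tuple(np.linspace(10, 9000, 50))
        cfg = SimulationConfig(
            n_taxa=50, depths=depths, pore_sizes=(0.22, 3.0),
            m=0.3, local_size=500, sequencing_depth=500, generations=15, seed=3,
        )
        table, truth = simulate_neutral(cfg)
        freq = (table.counts > 0).mean(axis=1)
        rho, _ = stats.spearmanr(freq, truth.metacommunity)
        assert rho > 0.9


class TestNiche:
    def test_infinite_sigma_reduces_to_metacommunity_sampling(self):
        depths = tuple(np.linspace(10, 9000, 100))
        cfg = SimulationConfig(
            n_taxa=50, depths=depths, pore_sizes=(0.22,), mode="niche",
            sigma=1e6, sequencing_depth=800, seed=4,
        )
        table, truth = simulate_niche(cfg)
        rel = table.relative().mean(axis=1)
        p = truth.metacommunity
        se = np.sqrt(p * (1 - p) / (800 * table.n_samples))
        z = (rel - p) / se.clip(lower=1e-9)
        assert (np.abs(z) < 3).mean() > 0.95

    def test_niche_weights_flatten_with_wide_filter(self):
        p = np.array([0.5, 0.3, 0.2])
        w = _niche_weights(p, np.array([-1.0, 0.0, 1.0]), np.array([0.0]), 1e9)
        np.testing.assert_allclose(w[:, 0], p, atol=1e-9)

    def test_environmental_similarity_drives_composition(self, small_niche):
        # samples at the same depth are more alike than gradient extremes
        from hadal.beta_diversity import distance_matrix

        table, truth = small_niche
        d = distance_matrix(table, "braycurtis")
        ids = d.sample_ids
        e = truth.gradient
        same = [
            d.data[i, j]
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if abs(e[ids[i]] - e[ids[j]]) < 1e-9
        ]
        extreme = [
            d.data[i, j]
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if abs(e[ids[i]] - e[ids[j]]) > 2.0
        ]
        assert np.mean(same) < np.mean(extreme)

    def test_conserved_optima_have_phylogenetic_signal(self):
        tree = simulate_tree(64, seed=0)
        conserved = brownian_optima(tree, 1.0, seed=1)
        free = brownian_optima(tree, 0.0, seed=1)
        d = tree.tip_tip_distances()
        ids = list(conserved.index)
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
        dist = np.array([d[d.index(a), d.index(b)] for a, b in pairs])
        for series, expect_signal in ((conserved, True), (free, False)):
            diff = np.array([abs(series[a] - series[b]) for a, b in pairs])
            rho, p = stats.spearmanr(dist, diff)
            if expect_signal:
                assert rho > 0.15 and p < 0.01
            else:
                assert abs(rho) < 0.15

    def test_mixed_mode_interpolates(self):
        base = dict(n_taxa=40, depths=(10.0, 8000.0), pore_sizes=(0.22,),
                    sigma=0.3, sequencing_depth=2000, seed=6)
        niche, _ = simulate_niche(SimulationConfig(mode="niche", **base))
        mixed, _ = simulate_niche(
            SimulationConfig(mode="mixed", mix_weight=0.2, **base)
        )
        # depth-driven compositional contrast is weaker once 80% of the
        # expectation is the flat metacommunity
        def contrast(t):
            rel = t.relative()
            return np.abs(rel.iloc[:, 0] - rel.iloc[:, 1]).sum() / 2

        assert contrast(mixed) < contrast(niche)


class TestStudyScale:
    def test_multi_domain_assembly(self):
        sc = simulate_study(
            3,
            n_taxa={"bacteria": 50, "archaea": 30, "microeukaryote": 40},
            local_size=400,
            sequencing_depth=1000,
            generations=10,
        )
        assert sc.table.n_taxa == 120
        assert sc.table.taxonomy["domain"].value_counts().to_dict() == {
            "bacteria": 50, "microeukaryote": 40, "archaea": 30
        }
        assert sc.metadata.data.shape[0] == sc.table.n_samples == 16
        for domain, truth in sc.truths.items():
            tips = {t.name for t in truth.tree.tips()}
            assert tips == set(truth.metacommunity.index)

    def test_metadata_profiles_are_physical(self):
        meta = simulate_metadata(seed=0).data
        surface = meta[meta["depth"] == 2.0].iloc[0]
        deep = meta[meta["depth"] == 8727.0].iloc[0]
        assert surface["temperature"] > deep["temperature"]
        assert deep["NO3"] > surface["NO3"]
        assert (meta["depth"] > 0).all()

    def test_gradient_is_standardized(self):
        e = depth_gradient((2, 500, 1000, 1759, 3699, 5367, 7200, 8727))
        assert e.mean() == pytest.approx(0.0, abs=1e-12)
        assert e.std() == pytest.approx(1.0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"m": 0.0},
            {"m": 1.5},
            {"sigma": -1.0},
            {"conservatism": 1.5},
            {"mode": "magic"},
            {"n_taxa": 1},
            {"generations": 5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
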