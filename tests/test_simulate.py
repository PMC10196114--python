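"""Synthetic-data generator: tree simulation, presence evolution, planted
structure, and negative controls."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from phylosym.congruence import TreeCongruence
from phylosym.datamodel import collapse_by_species
from phylosym.phylobiome import PhylobiomeSpec, build_phylobiome
from phylosym.simulate import (
    Association, EnvironmentalGenus, HeritableGenus, SimulationConfig,
    evolve_presence, simulate_dataset, simulate_host_tree,
    strong_phylosymbiosis_config,
)


class TestHostTree:
    def test_two_species_is_a_cherry(self):
        tree, clades = simulate_host_tree(2, 1, seed=0)
        assert {x.name for x in tree.tips()} == {"sp01", "sp02"}
        assert set(clades.values()) == {"clade1"}

    @pytest.mark.parametrize("n_species,n_clades", [(14, 5), (8, 3), (6, 6)])
    def test_clades_partition_species(self, n_species, n_clades):
        tree, clades = simulate_host_tree(n_species, n_clades, seed=3)
        assert len(clades) == n_species
        assert len(set(clades.values())) == n_clades
        # clades are monophyletic: each clade's leaves form a clade or tip
        for label in set(clades.values()):
            members = {sp for sp, c in clades.items() if c == label}
            node = tree.lca([tree.find(m) for m in members]) \
                if len(members) > 1 else tree.find(next(iter(members)))
            below = {x.name for x in node.tips()} if not node.is_tip() \
                else {node.name}
            assert below == members

    def test_seed_determinism(self):
        a, ca = simulate_host_tree(10, 4, seed=7)
        b, cb = simulate_host_tree(10, 4, seed=7)
        assert str(a) == str(b)
        assert ca == cb

    def test_ultrametric(self):
        tree, _ = simulate_host_tree(9, 3, seed=5)
        depths = []
        for tip in tree.tips():
            d, node = 0.0, tip
            while node.parent is not None:
                d += node.length or 0.0
                node = node.parent
            depths.append(d)
        assert np.ptp(depths) < 1e-9


class TestEvolvePresence:
    def _tree(self):
        return simulate_host_tree(10, 2, seed=1)[0]

    def test_frozen_process_keeps_root_state(self):
        tree = self._tree()
        states = evolve_presence(tree, 0.0, 0.0, True, seed=0)
        assert all(states.values())
        states = evolve_presence(tree, 0.0, 0.0, False, seed=0)
        assert not any(states.values())

    def test_absorbing_loss_limit(self):
        tree = self._tree()
        states = evolve_presence(tree, 0.0, 1e9, True, seed=0)
        assert not any(states.values())

    def test_stationary_frequency(self):
        # star tree with very long branches: leaves are iid draws from the
        # stationary distribution gain/(gain+loss) = 0.5
        star = TreeNode(children=[TreeNode(name=f"L{i}", length=100.0)
                                  for i in range(400)])
        rng = np.random.default_rng(2)
        freqs = [np.mean(list(evolve_presence(star, 1.0, 1.0, True,
                                              seed=rng).values()))
                 for _ in range(25)]
        n = 400 * 25
        assert abs(np.mean(freqs) - 0.5) < 3 * np.sqrt(0.25 / n)


class TestSimulateDataset:
    def test_emitted_tables_satisfy_invariants(self, default_dataset):
        table, tax, meta, truth = default_dataset
        # CountTable/SampleMetadata constructors enforce their invariants;
        # here: consistency between the three tables and the truth
        assert set(table.sample_ids) <= set(meta.sample_ids)
        assert all(tid in tax for tid in table.taxon_ids)
        assert truth.expected_removed_taxa <= set(table.taxon_ids)
        assert (table.counts() >= 0).all()

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=21)
        a = simulate_dataset(cfg)[0]
        b = simulate_dataset(SimulationConfig(seed=21))[0]
        assert a == b

    def test_noiseless_single_genus_limit(self):
        cfg = SimulationConfig(
            n_species=4, n_clades=2, queens_per_species=(3, 3),
            heritable=[HeritableGenus("OnlyOne", 0.0, 0.0, 1.0, n_asvs=2,
                                      root_present=True,
                                      infection_prob=1.0)],
            environmental=[], associations=[], contaminants=[],
            n_trace_asvs=0, mito_abundance=0.0, include_chloroplast=False,
            include_eukaryote=False, depth_range=(5000, 6000),
            n_low_depth_samples=0, runs=1, controls_per_run=0,
            batch_effect_sd=0.0, dirichlet_concentration=None, seed=2,
        )
        table, tax, meta, truth = simulate_dataset(cfg)
        assert truth.species_presence["OnlyOne"].all()
        for tid in table.taxon_ids:
            assert tax.genus(tid) == "OnlyOne"
        assert (table.sample_totals() >= 5000).all()

    def test_planted_shallow_samples_sit_below_threshold(self,
                                                         default_dataset):
        table, _, _, truth = default_dataset
        totals = table.sample_totals()
        for s in truth.shallow_samples:
            assert totals[s] < 3000
        for s in truth.control_samples:
            assert totals[s] < 3000

    def test_independence_when_no_association_planted(self):
        """With all odds multipliers at 1 the planted presences of two
        facultative genera are independent (chi-square on the pooled 2x2)."""
        cfg = SimulationConfig(
            n_species=2, n_clades=1, queens_per_species=(60, 60),
            heritable=[],
            environmental=[EnvironmentalGenus("X", 0.5, 0.2),
                           EnvironmentalGenus("Y", 0.5, 0.2),
                           EnvironmentalGenus("Enterobacter", 1.0, 0.1)],
            associations=[], contaminants=[], n_trace_asvs=0,
            mito_abundance=0.0, include_chloroplast=False,
            include_eukaryote=False, depth_range=(4000, 5000),
            n_low_depth_samples=0, runs=1, controls_per_run=0,
            batch_effect_sd=0.0, seed=31,
        )
        pres = simulate_dataset(cfg)[3].sample_presence
        import scipy.stats
        ct = pd.crosstab(pres["X"], pres["Y"])
        p = scipy.stats.chi2_contingency(ct).pvalue
        assert p > 0.01

    def test_association_direction_matches_multiplier(self):
        cfg = SimulationConfig(
            n_species=2, n_clades=1, queens_per_species=(100, 100),
            heritable=[],
            environmental=[EnvironmentalGenus("P", 0.5, 0.2),
                           EnvironmentalGenus("Q", 0.5, 0.2),
                           EnvironmentalGenus("Enterobacter", 1.0, 0.1)],
            associations=[Association("P", "Q", 10.0)],
            contaminants=[], n_trace_asvs=0, mito_abundance=0.0,
            include_chloroplast=False, include_eukaryote=False,
            depth_range=(4000, 5000), n_low_depth_samples=0, runs=1,
            controls_per_run=0, batch_effect_sd=0.0, seed=5,
        )
        pres = simulate_dataset(cfg)[3].sample_presence
        both = (pres["P"] & pres["Q"]).mean()
        assert both > pres["P"].mean() * pres["Q"].mean() + 0.05

    def test_shuffled_species_labels_destroy_phylosymbiosis(self):
        """Negative control: permuting which microbiome belongs to which
        species leaves no congruence signal."""
        rng = np.random.default_rng(0)
        ps = []
        for rep in range(10):
            cfg = strong_phylosymbiosis_config(seed=600 + rep)
            table, tax, meta, truth = simulate_dataset(cfg)
            by_sp = collapse_by_species(table, meta)
            shuffled = by_sp.df.copy()
            shuffled.index = list(rng.permutation(shuffled.index))
            from phylosym.datamodel import CountTable
            pb = build_phylobiome(CountTable(shuffled),
                                  PhylobiomeSpec(depth=3000, iterations=10,
                                                 seed=rep))
            res = TreeCongruence(pb.tree, truth.host_tree).fit(
                metrics=("MC",), n_random=99, seed=rep)
            ps.append(res.p_value("MC"))
        assert np.mean(ps) > 0.2
        assert max(ps) > 0.5


class TestStrongScenario:
    def test_phylobiome_tracks_host_tree(self):
        cfg = strong_phylosymbiosis_config(seed=123)
        table, tax, meta, truth = simulate_dataset(cfg)
        by_sp = collapse_by_species(table, meta)
        pb = build_phylobiome(by_sp, PhylobiomeSpec(depth=3000,
                                                    iterations=25, seed=1))
        res = TreeCongruence(pb.tree, truth.host_tree).fit(
            metrics=("RFC", "MC"), n_random=500, seed=2)
        assert res.p_value("RFC") < 0.01
        assert res.p_value("MC") < 0.01
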