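import numpy as np
import pytest

from proxirep.connectivity import combined_es, ks_enrichment
from proxirep.interactome import NodeSet
from proxirep.proximity import proximity
from proxirep.signatures import DiseaseSignature
from proxirep.synthetic import (
    plant_modules,
    simulate_drug_profiles,
    simulate_expression,
    simulate_interactome,
)


class TestInteractomeGenerator:
    def test_same_seed_identical(self):
        a = simulate_interactome(500, 6, seed=1)
        b = simulate_interactome(500, 6, seed=1)
        assert a.edges() == b.edges()

    def test_connected_with_requested_size(self):
        import networkx as nx
        g = simulate_interactome(500, 6, seed=2)
        assert g.n_nodes == 500
        assert nx.is_connected(g.graph)

    def test_heavy_tailed_degrees(self):
        # hub degree dwarfs the median across seeds
        for seed in range(10):
            g = simulate_interactome(2000, 6, seed=seed)
            degs = np.array(sorted(g.degrees().values()))
            assert degs.max() / np.median(degs) > 5

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            simulate_interactome(10, 6, seed=0)


class TestPlantModules:
    def test_true_drugs_within_one_hop(self):
        g = simulate_interactome(500, 6, seed=3)
        truth = plant_modules(g, disease_size=40, n_true=5, n_decoy=5,
                              targets_per_drug=4, seed=4)
        S = NodeSet(set(truth.disease_modules["DIS00"]))
        for drug, targets in truth.true_drugs.items():
            assert proximity(g, NodeSet(set(targets), drug), S) <= 1.0

    def test_decoys_farther_on_average(self):
        gaps = []
        for seed in range(10):
            g = simulate_interactome(1000, 6, seed=seed)
            truth = plant_modules(g, disease_size=40, n_true=5, n_decoy=10,
                                  targets_per_drug=4, seed=seed)
            S = NodeSet(set(truth.disease_modules["DIS00"]))
            p_true = np.mean([proximity(g, NodeSet(set(t)), S)
                              for t in truth.true_drugs.values()])
            p_decoy = np.mean([proximity(g, NodeSet(set(t)), S)
                               for t in truth.decoy_drugs.values()])
            gaps.append(p_decoy - p_true)
        assert np.mean(gaps) > 0

    def test_same_seed_identical_truth(self):
        g = simulate_interactome(300, 6, seed=5)
        a = plant_modules(g, 30, 3, 3, 4, seed=6)
        b = plant_modules(g, 30, 3, 3, 4, seed=6)
        assert a.disease_modules == b.disease_modules
        assert a.true_drugs == b.true_drugs and a.decoy_drugs == b.decoy_drugs

    def test_disease_module_connected(self):
        import networkx as nx
        g = simulate_interactome(300, 6, seed=7)
        truth = plant_modules(g, 30, 2, 2, 3, seed=8, n_diseases=3)
        for genes in truth.disease_modules.values():
            assert nx.is_connected(g.graph.subgraph(genes))

    def test_infeasible_size_raises(self):
        g = simulate_interactome(100, 6, seed=0)
        with pytest.raises(ValueError):
            plant_modules(g, disease_size=90, n_true=1, n_decoy=1,
                          targets_per_drug=2, seed=0)


class TestExpressionGenerator:
    def test_same_seed_identical(self):
        a, _ = simulate_expression(100, 10, 10, 0.1, 1.5, seed=1)
        b, _ = simulate_expression(100, 10, 10, 0.1, 1.5, seed=1)
        assert a.values.equals(b.values)

    def test_planted_fraction_and_directions(self):
        ds, truth = simulate_expression(1000, 20, 20, 0.1, 1.5, seed=2)
        assert len(truth) == 100
        up = [g for g, d in truth.items() if d == "up"]
        dn = [g for g, d in truth.items() if d == "down"]
        case = ds.class_columns("case")
        ctrl = ds.class_columns("control")
        diff_up = (ds.values.loc[up, case].mean(axis=1)
                   - ds.values.loc[up, ctrl].mean(axis=1)).mean()
        diff_dn = (ds.values.loc[dn, case].mean(axis=1)
                   - ds.values.loc[dn, ctrl].mean(axis=1)).mean()
        assert diff_up == pytest.approx(1.5, abs=0.3)
        assert diff_dn == pytest.approx(-1.5, abs=0.3)

    def test_no_effect_calibrated_false_positive_rate(self):
        from proxirep.signatures import differential_expression
        ds, _ = simulate_expression(4000, 25, 25, 0.1, effect_size=0.0, seed=3)
        de = differential_expression(ds)
        frac = (de["pval"] < 0.05).mean()
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 4000)
        assert abs(frac - 0.05) < half_width

    def test_shared_planted_signal(self):
        _, t1 = simulate_expression(500, 10, 10, 0.1, 1.5, seed=4)
        _, t2 = simulate_expression(500, 10, 10, 0.1, 1.5, seed=5, planted=t1)
        assert t1 == t2

    def test_degenerate_groups_raise(self):
        with pytest.raises(ValueError):
            simulate_expression(100, 1, 10, 0.1, 1.5, seed=0)


class TestDrugProfileGenerator:
    UNIVERSE = [f"G{i:05d}" for i in range(500)]
    SIG = DiseaseSignature("planted", [f"G{i:05d}" for i in range(10)],
                           [f"G{i:05d}" for i in range(10, 20)])

    def profile_es(self, prof):
        return combined_es(ks_enrichment(self.SIG.up_genes, prof),
                           ks_enrichment(self.SIG.down_genes, prof))

    def test_noiseless_reverser_scores_negative(self):
        profiles, truth = simulate_drug_profiles(
            self.SIG, self.UNIVERSE, n_reversers=1, n_neutrals=0,
            noise_sd=0.0, seed=1)
        assert all(self.profile_es(p) < 0 for p in profiles)

    def test_neutral_mean_es_near_zero(self):
        vals = []
        for seed in range(50):
            profiles, _ = simulate_drug_profiles(
                self.SIG, self.UNIVERSE, n_reversers=0, n_neutrals=1,
                noise_sd=0.25, seed=seed, cell_lines=("NPC",))
            vals.append(self.profile_es(profiles[0]))
        assert abs(np.mean(vals)) < 0.1

    def test_same_seed_identical(self):
        a, _ = simulate_drug_profiles(self.SIG, self.UNIVERSE, 2, 2, 0.25, seed=9)
        b, _ = simulate_drug_profiles(self.SIG, self.UNIVERSE, 2, 2, 0.25, seed=9)
        assert all(x.scores.equals(y.scores) for x, y in zip(a, b))

    def test_profiles_cover_universe(self):
        profiles, _ = simulate_drug_profiles(self.SIG, self.UNIVERSE, 1, 1,
                                             0.25, seed=2)
        for p in profiles:
            assert sorted(p.scores.index) == sorted(self.UNIVERSE)

    def test_empty_signature_raises(self):
        with pytest.raises(ValueError):
            simulate_drug_profiles(DiseaseSignature("e", [], []),
                                   self.UNIVERSE, 1, 1, 0.25, seed=0)
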