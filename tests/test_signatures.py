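import numpy as np
import pandas as pd
import pytest

from proxirep.signatures import (
    CASE,
    CONTROL,
    batch_correct,
    differential_expression,
    iqr_filter,
    make_disease_signature,
    merge_batches,
    preprocess_expression,
    write_gmt,
)
from proxirep.synthetic import simulate_expression

from conftest import make_expression


class TestPreprocess:
    def test_probe_collapse_by_mean(self):
        ds = make_expression({"G": [2, 2], "H": [1, 1]}, case_samples=["s0"])
        ds.values.index = ["G", "G"]  # two probes for the same gene
        out = preprocess_expression(ds, log2=False)
        assert out.values.loc["G"].tolist() == [1.5, 1.5]

    def test_log2_plus_one_convention(self):
        ds = make_expression({"G": [7, 7]}, case_samples=["s0"])
        out = preprocess_expression(ds, log2=True)
        assert out.values.loc["G", "s0"] == pytest.approx(3.0)

    def test_identity_without_flags(self):
        ds = make_expression({"G": [1, 2], "H": [3, 4]}, case_samples=["s0"])
        out = preprocess_expression(ds, log2=False, collapse=False)
        assert out.values.equals(ds.values)

    def test_nonfinite_raises(self):
        ds = make_expression({"G": [1, np.inf]}, case_samples=["s0"])
        with pytest.raises(ValueError, match="G"):
            preprocess_expression(ds, log2=False)

    def test_log2_rejects_values_at_or_below_minus_one(self):
        ds = make_expression({"G": [-1.5, 0]}, case_samples=["s0"])
        with pytest.raises(ValueError):
            preprocess_expression(ds, log2=True)


class TestMergeBatches:
    def test_gene_intersection(self):
        a = make_expression({"A": [1, 2], "B": [3, 4], "C": [5, 6]}, ["s0"])
        b = make_expression({"B": [1, 2], "C": [3, 4], "D": [5, 6]}, ["s0"])
        merged = merge_batches([a, b])
        assert sorted(merged.values.index) == ["B", "C"]
        assert merged.n_samples == 4
        assert merged.batch.nunique() == 2

    def test_identical_datasets_double_columns(self):
        a = make_expression({"A": [1, 2], "B": [3, 4]}, ["s0"])
        merged = merge_batches([a, a])
        assert merged.n_samples == 4
        assert sorted(merged.values.index) == ["A", "B"]

    def test_three_batches_match_set_oracle(self, rng):
        sets = [set(rng.choice(50, size=30, replace=False).tolist())
                for _ in range(3)]
        dss = [make_expression({f"G{g}": [1.0, 2.0] for g in s}, ["s0"])
               for s in sets]
        merged = merge_batches(dss)
        oracle = {f"G{g}" for g in sets[0] & sets[1] & sets[2]}
        assert set(merged.values.index) == oracle

    def test_disjoint_gene_sets_raise(self):
        a = make_expression({"A": [1, 2]}, ["s0"])
        b = make_expression({"B": [1, 2]}, ["s0"])
        with pytest.raises(ValueError):
            merge_batches([a, b])

    def test_single_dataset_raises(self):
        a = make_expression({"A": [1, 2]}, ["s0"])
        with pytest.raises(ValueError):
            merge_batches([a])


class TestBatchCorrect:
    def test_constant_shift_removed(self):
        ds = make_expression(
            {"G": [1.0, 2.0, 6.0, 7.0], "H": [0.0, 4.0, 5.0, 9.0]},
            case_samples=["s0", "s2"],
            batch={"s0": "b1", "s1": "b1", "s2": "b2", "s3": "b2"})
        # batch b2 = batch b1 + 5 for gene G
        out = batch_correct(ds)
        x = out.values
        for gene in ["G", "H"]:
            m1 = x.loc[gene, ["s0", "s1"]].mean()
            m2 = x.loc[gene, ["s2", "s3"]].mean()
            assert abs(m1 - m2) < 1e-8

    def test_single_batch_raises(self):
        ds = make_expression({"G": [1, 2]}, ["s0"], batch={"s0": "b", "s1": "b"})
        with pytest.raises(ValueError):
            batch_correct(ds)

    def test_planted_shift_recovery(self):
        # additive batch shift removed while case/control effect survives
        ds, truth = simulate_expression(
            n_genes=400, n_case=40, n_control=40, de_fraction=0.1,
            effect_size=1.5, batch_shift=2.0, n_batches=2, seed=7)
        out = batch_correct(ds)
        x = out.values.to_numpy()
        b = (out.batch == "batch1").to_numpy()
        between = np.abs(x[:, b].mean(axis=1).mean() - x[:, ~b].mean(axis=1).mean())
        assert between < 0.01
        up = [g for g, d in truth.items() if d == "up"]
        cases = out.class_columns(CASE)
        ctrls = out.class_columns(CONTROL)
        effect = (out.values.loc[up, cases].mean(axis=1)
                  - out.values.loc[up, ctrls].mean(axis=1)).mean()
        assert effect == pytest.approx(1.5, rel=0.10)


class TestIqrFilter:
    @staticmethod
    def dataset_with_iqrs():
        # gene i has values spread so its IQR is i+1 (i = 0..9)
        rows = {}
        for i in range(10):
            w = float(i + 1)
            rows[f"G{i}"] = [-w, -w / 3, w / 3, w]  # IQR = i+1 (linear interp)
        return make_expression(rows, case_samples=["s0", "s1"])

    def test_tenth_percentile_threshold(self):
        ds = self.dataset_with_iqrs()
        out = iqr_filter(ds, percentile=10)
        # 10th percentile of IQRs {1..10} is 1.9 -> only the IQR=1 gene drops
        assert "G0" not in out.values.index
        assert out.n_genes == 9

    def test_equal_iqrs_nothing_removed(self):
        ds = make_expression({f"G{i}": [0.0, 1.0, 2.0, 3.0] for i in range(12)},
                             case_samples=["s0", "s1"])
        out = iqr_filter(ds)
        assert out.n_genes == 12

    def test_constant_gene_removed(self):
        rows = {f"G{i}": [0.0, 1.0, 2.0, 3.0] for i in range(11)}
        rows["FLAT"] = [5.0, 5.0, 5.0, 5.0]
        ds = make_expression(rows, case_samples=["s0", "s1"])
        out = iqr_filter(ds)
        assert "FLAT" not in out.values.index

    def test_bad_percentile_raises(self):
        with pytest.raises(ValueError):
            iqr_filter(self.dataset_with_iqrs(), percentile=0)


class TestDifferentialExpression:
    def test_hand_computed_pooled_t(self):
        ds = make_expression({"G": [1, 2, 3, 4, 5, 6]},
                             case_samples=["s0", "s1", "s2"])
        de = differential_expression(ds)
        assert de.loc["G", "fold_change"] == pytest.approx(-3.0)
        assert de.loc["G", "t"] == pytest.approx(-3.0 / np.sqrt(2 / 3), abs=1e-6)
        assert de.loc["G", "direction"] == "down"

    def test_identical_groups_null_result(self):
        ds = make_expression({"G": [2, 2, 2, 2]}, case_samples=["s0", "s1"])
        de = differential_expression(ds)
        assert de.loc["G", "t"] == 0.0
        assert de.loc["G", "pval"] == 1.0

    def test_null_simulation_calibrated(self):
        # no signal: raw p < 0.05 fraction inside binomial 99% CI of 0.05
        rng = np.random.default_rng(11)
        n_genes, n = 5000, 20
        x = rng.standard_normal((n_genes, 2 * n))
        ds = make_expression(
            {f"G{i}": x[i].tolist() for i in range(n_genes)},
            case_samples=[f"s{i}" for i in range(n)])
        de = differential_expression(ds)
        frac = (de["pval"] < 0.05).mean()
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(frac - 0.05) < half_width

    def test_small_class_raises(self):
        ds = make_expression({"G": [1, 2, 3]}, case_samples=["s0"])
        with pytest.raises(ValueError):
            differential_expression(ds)

    def test_moderated_t_shrinks_variance_outliers(self):
        # a gene with a tiny sample variance should not dominate moderated stats
        rng = np.random.default_rng(3)
        x = rng.standard_normal((300, 8))
        x[0] = np.array([0.0, 1e-4, 0.0, 1e-4, 0.02, 0.0201, 0.02, 0.0201])
        ds = make_expression({f"G{i}": x[i].tolist() for i in range(300)},
                             case_samples=[f"s{i}" for i in range(4)])
        plain = differential_expression(ds, method="pooled_t")
        mod = differential_expression(ds, method="moderated_t")
        assert abs(mod.loc["G0", "t"]) < abs(plain.loc["G0", "t"])

    def test_direction_matches_mean_difference(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((50, 10))
        ds = make_expression({f"G{i}": x[i].tolist() for i in range(50)},
                             case_samples=[f"s{i}" for i in range(5)])
        de = differential_expression(ds)
        up = de["direction"] == "up"
        assert ((de["mean_case"] - de["mean_control"] >= 0) == up).all()


class TestSignature:
    @staticmethod
    def de_table():
        return pd.DataFrame({
            "fold_change": [1.2, -0.8, 0.5],
            "pval": [0.005, 0.005, 0.02],
            "adj_pval": [0.005, 0.005, 0.02],
            "direction": ["up", "down", "up"],
        }, index=["U1", "D1", "U2"])

    def test_adjusted_mode_counts(self):
        sig = make_disease_signature(self.de_table(), "AD", mode="adjusted",
                                     alpha=0.01)
        assert sig.up_genes == ["U1"] and sig.down_genes == ["D1"]

    def test_raw_mode_counts(self):
        sig = make_disease_signature(self.de_table(), "AD", mode="raw",
                                     alpha=0.01)
        assert sig.up_genes == ["U1"] and sig.down_genes == ["D1"]

    def test_lists_ordered_by_increasing_fold_change(self):
        de = pd.DataFrame({
            "fold_change": [2.0, 0.5, 1.0, -0.2, -1.5],
            "pval": [0.001] * 5, "adj_pval": [0.001] * 5,
            "direction": ["up", "up", "up", "down", "down"],
        }, index=list("ABCDE"))
        sig = make_disease_signature(de, "AD")
        assert sig.up_genes == ["B", "C", "A"]
        assert sig.down_genes == ["E", "D"]

    def test_up_down_disjoint_and_complete(self):
        sig = make_disease_signature(self.de_table(), "AD", alpha=0.05)
        passing = set(self.de_table().index)
        assert set(sig.up_genes) | set(sig.down_genes) == passing
        assert not set(sig.up_genes) & set(sig.down_genes)

    def test_gmt_export(self, tmp_path):
        sig = make_disease_signature(self.de_table(), "AD", alpha=0.05)
        path = tmp_path / "sig.gmt"
        write_gmt([sig], path)
        lines = path.read_text().strip().split("\n")
        assert lines[0].startswith("AD_UP\t")
        assert lines[1].startswith("AD_DN\t")
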