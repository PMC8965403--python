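"""Marginal ancestral reconstruction and reconstructability summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_tree, random_binary_tree
from oracles import enumerate_likelihood
from phylostab import asr, hmm
from phylostab._treeindex import as_indexed
from phylostab.hmm import RateMatrix
from phylostab.matrix import FeatureMatrix
from phylostab.trees import sample_trees, taxonomy_from_string


def rand_rates(rng):
    return RateMatrix.from_vector(np.exp(rng.uniform(np.log(0.05), np.log(5.0), 8)))


class TestMarginalASR:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration(self, seed):
        """Node marginals equal the exhaustive sum over all other nodes'
        states on 4-6 tip trees."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        idx = as_indexed(random_binary_tree(rng, n))
        Q = rand_rates(rng)
        states = ["present", "absent", "missing"]
        trait = {l: states[rng.integers(0, 3)] for l in idx.tip_labels}
        trait[idx.tip_labels[0]] = "present"
        _, marg = enumerate_likelihood(idx, trait, Q.generator())
        rec = asr.marginal_asr(idx, trait, Q)
        for i in range(idx.n_nodes):
            assert np.allclose(rec.node_probs[i], marg[i], atol=1e-9)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        idx = as_indexed(random_binary_tree(rng, 20))
        Q = rand_rates(rng)
        trait = {l: ("present" if rng.uniform() < 0.4 else "absent") for l in idx.tip_labels}
        rec = asr.marginal_asr(idx, trait, Q)
        assert np.allclose(rec.node_probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(rec.p_present >= 0) and np.all(rec.p_present <= 1)

    def test_marginal_identity(self):
        """At every node, down x up recombines to the same full-tree
        likelihood the pruning pass computed."""
        rng = np.random.default_rng(8)
        idx = as_indexed(random_binary_tree(rng, 30))
        Q = rand_rates(rng)
        trait = {l: ("present" if rng.uniform() < 0.5 else "absent") for l in idx.tip_labels}
        rec = asr.marginal_asr(idx, trait, Q)
        assert np.allclose(rec.node_loglik, rec.log_likelihood, atol=1e-9)
        assert rec.log_likelihood == pytest.approx(
            hmm.pruning_loglik(idx, trait, Q), abs=1e-12
        )

    def test_observed_tip_keeps_projection_mass(self, balanced4):
        rng = np.random.default_rng(11)
        Q = rand_rates(rng)
        rec = asr.marginal_asr(balanced4, {"A": "present", "B": "absent", "C": "present", "D": "missing"}, Q)
        idx = rec.tree
        a = idx.tip_index("A")
        b = idx.tip_index("B")
        assert rec.p_present[a] == pytest.approx(1.0)
        assert rec.p_present[b] == pytest.approx(0.0)

    def test_near_zero_loss_all_present_root(self):
        rng = np.random.default_rng(14)
        tree = random_binary_tree(rng, 16)
        Q = RateMatrix(0.5, 1e-9, 0.5, 1e-9, 0.1, 0.1, 0.1, 0.1)
        trait = {f"t{i+1}": "present" for i in range(16)}
        rec = asr.marginal_asr(tree, trait, Q)
        assert rec.p_present[rec.tree.root] > 0.95


class TestFamilyRoot:
    def test_constrained_family_mrca(self):
        fams = ["(" + ",".join(f"{n}{i}" for i in range(6)) + ")" for n in "AB"]
        tax = taxonomy_from_string("(" + ",".join(fams) + ");")
        post = sample_trees(tax, 5, seed=2)
        families = {f"{n}{i}": n for n in "AB" for i in range(6)}
        rng = np.random.default_rng(0)
        Q = rand_rates(rng)
        trait = {t: ("present" if t.startswith("A") else "absent") for t in families}
        for tree in post:
            rec = asr.marginal_asr(tree, trait, Q)
            node = rec.node_of([t for t in families if t.startswith("A")])
            below = rec.tree.tipset_below()[node]
            labels = {rec.tree.tip_labels[i] for i in below}
            assert labels == {f"A{i}" for i in range(6)}

    def test_all_present_slow_loss_high_probability(self):
        fams = ["(" + ",".join(f"{n}{i}" for i in range(6)) + ")" for n in "AB"]
        tax = taxonomy_from_string("(" + ",".join(fams) + ");")
        tree = sample_trees(tax, 1, seed=3)[0]
        families = {f"{n}{i}": n for n in "AB" for i in range(6)}
        Q = RateMatrix(0.3, 1e-9, 0.3, 1e-9, 0.1, 0.1, 0.1, 0.1)
        trait = {t: "present" for t in families}
        rec = asr.marginal_asr(tree, trait, Q)
        assert asr.family_root_presence(rec, "A", families) > 0.95

    def test_small_family_rejected(self, balanced4):
        rng = np.random.default_rng(1)
        Q = rand_rates(rng)
        rec = asr.marginal_asr(balanced4, {t: "present" for t in "ABCD"}, Q)
        with pytest.raises(ValueError, match="need >= 2"):
            asr.family_root_presence(rec, "X", {"A": "X", "B": "Y", "C": "Y", "D": "Y"})


class TestReconstructability:
    def test_all_certain(self):
        probs = pd.DataFrame({"A": [1.0] * 5, "B": [1.0] * 5})
        s = asr.reconstructability_summary(probs)
        assert (s["cumulative_proportions"].loc["p>=0.95"] == 1.0).all()
        assert (s["band_proportions"].loc["p95"] == 1.0).all()

    def test_nested_thresholds(self):
        probs = pd.DataFrame({"A": [0.96, 0.5]})
        s = asr.reconstructability_summary(probs)
        assert s["cumulative_counts"].at["p>=0.95", "A"] == 1
        assert s["cumulative_counts"].at["p>=0.75", "A"] == 1  # 0.96 counts in both

    def test_bands_partition(self):
        rng = np.random.default_rng(21)
        probs = pd.DataFrame({"A": rng.uniform(size=200)})
        s = asr.reconstructability_summary(probs)
        assert s["band_counts"]["A"].sum() == 200
        assert s["band_proportions"]["A"].sum() == pytest.approx(1.0)

    def test_uniform_probabilities_half_uncertain(self):
        rng = np.random.default_rng(33)
        probs = pd.DataFrame({"A": rng.uniform(size=1000)})
        s = asr.reconstructability_summary(probs)
        assert s["band_proportions"].at["uncertain", "A"] == pytest.approx(0.5, abs=0.06)


class TestCategoryNormalized:
    def test_normalization_arithmetic(self):
        from phylostab.simulate import make_catalog

        feats = [f"F{i}" for i in range(10)]
        catalog = make_catalog(feats, seed=0)
        # force one category of 5 features with 2 reconstructed
        table = catalog.table.copy()
        table["domain"] = ["word"] * 5 + ["clause"] * 5
        from phylostab.matrix import FeatureCatalog

        catalog = FeatureCatalog(table)
        probs = pd.DataFrame({"A": [1, 1, 0, 0, 0, 1, 1, 1, 1, 0.99]}, index=feats, dtype=float)
        norm = asr.category_normalized_reconstruction(probs, catalog, axis="domain")
        assert norm.at["word", "A"] == pytest.approx(0.4)
        assert norm.at["clause", "A"] == pytest.approx(1.0)

    def test_size_effect_removed(self):
        from phylostab.matrix import FeatureCatalog

        feats = [f"F{i}" for i in range(55)]
        table = pd.DataFrame(
            {
                "functional_category": ["negation"] * 5 + ["deixis"] * 50,
                "domain": ["clause"] * 55,
                "part_of_speech": ["verb"] * 55,
            },
            index=feats,
        )
        catalog = FeatureCatalog(table)
        vals = [1.0] * 2 + [0.0] * 3 + [1.0] * 20 + [0.0] * 30
        probs = pd.DataFrame({"A": vals}, index=feats)
        norm = asr.category_normalized_reconstruction(probs, catalog)
        assert norm.at["negation", "A"] == pytest.approx(norm.at["deixis", "A"])


class TestFamilyOverlap:
    def test_toy_overlap(self):
        feats = [f"F{i}" for i in range(1, 11)]
        a = [1.0 if i <= 4 else 0.0 for i in range(1, 11)]
        b = [1.0 if 3 <= i <= 6 else 0.0 for i in range(1, 11)]
        probs = pd.DataFrame({"A": a, "B": b}, index=feats)
        m = asr.pairwise_family_overlap(probs, threshold=0.95)
        assert m.at["A", "B"] == pytest.approx(20.0)
        assert m.at["B", "A"] == pytest.approx(20.0)

    def test_identical_and_disjoint(self):
        probs = pd.DataFrame({"A": [1, 1, 0, 0], "B": [1, 1, 0, 0], "C": [0, 0, 1, 1]}, dtype=float)
        m = asr.pairwise_family_overlap(probs)
        assert m.at["A", "B"] == m.at["A", "A"]
        assert m.at["A", "C"] == 0.0


class TestProtoChildDistance:
    def _matrix(self):
        feats = [f"F{i}" for i in range(4)]
        values = pd.DataFrame(
            [[1, 1, 1, 1], [0, 1, np.nan, 1], [1, 0, 0, 0]],
            index=["x1", "x2", "y1"], columns=feats, dtype=float,
        )
        fams = pd.Series({"x1": "X", "x2": "X", "y1": "Y"})
        return FeatureMatrix(values, fams)

    def test_counts(self):
        m = self._matrix()
        probs = pd.Series({"F0": 0.99, "F1": 0.97, "F2": 0.96, "F3": 0.5})
        d = asr.proto_child_distance(probs, m, "X", threshold=0.95)
        assert d.at["x1", "n_differing"] == 0
        assert d.at["x2", "n_differing"] == 1  # F0 absent
        assert d.at["x2", "n_missing"] == 1  # F2 unknown
        assert d.at["x1", "n_reconstructed"] == 3

    def test_brute_force_tally(self):
        rng = np.random.default_rng(2)
        feats = [f"F{i}" for i in range(12)]
        taxa = [f"x{i}" for i in range(5)]
        values = pd.DataFrame(
            rng.choice([0.0, 1.0, np.nan], size=(5, 12)), index=taxa, columns=feats
        )
        m = FeatureMatrix(values, pd.Series("X", index=taxa))
        probs = pd.Series(rng.uniform(size=12), index=feats)
        d = asr.proto_child_distance(probs, m, "X", threshold=0.6)
        chosen = [f for f in feats if probs[f] >= 0.6]
        for t in taxa:
            expect = sum(1 for f in chosen if values.at[t, f] == 0.0)
            assert d.at[t, "n_differing"] == expect
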