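"""Coreceptor rules, pseudotime association, and differential gene importance."""

import numpy as np
import pandas as pd
import pytest

from clonolink import function_link as fl, synthetic_data as sd


class TestCoreceptor:
    def _gene(self, cd8a, cd8b, cd4):
        return pd.DataFrame({"CD8A": [cd8a], "CD8B": [cd8b], "CD4": [cd4]})

    @pytest.mark.parametrize(
        "cd8a,cd8b,cd4,label",
        [(1, 0, 0, "CD8+"), (0, 2, 0, "CD8+"), (0, 0, 0, "DN"), (0, 0, 1, "CD4+")],
    )
    def test_gene_mode_rules(self, cd8a, cd8b, cd4, label):
        call = fl.assign_coreceptor(self._gene(cd8a, cd8b, cd4), "gene")
        assert call["coreceptor"].iloc[0] == label

    def test_gene_mode_conflict_is_cd8_with_flag(self):
        call = fl.assign_coreceptor(self._gene(1, 0, 1), "gene")
        assert call["coreceptor"].iloc[0] == "CD8+"
        assert bool(call["ambiguous"].iloc[0])

    @pytest.mark.parametrize(
        "cd8,cd4,label",
        [(0.5, 0.0, "CD8+"), (0.1, 3.0, "CD4+"), (0.25, 3.0, "DN"), (0.1, 1.0, "DN")],
    )
    def test_protein_mode_literal_rules(self, cd8, cd4, label):
        call = fl.assign_coreceptor(pd.DataFrame({"CD8": [cd8], "CD4": [cd4]}), "protein")
        assert call["coreceptor"].iloc[0] == label

    def test_missing_channel_raises(self):
        with pytest.raises(ValueError, match="CD8B"):
            fl.assign_coreceptor(pd.DataFrame({"CD8A": [1], "CD4": [0]}), "gene")

    def test_labels_partition_input(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.choice([0.0, 1.0], size=(50, 3)),
                            columns=["CD8A", "CD8B", "CD4"])
        call = fl.assign_coreceptor(expr, "gene")
        assert len(call) == 50
        assert call["coreceptor"].isin(["CD8+", "CD4+", "DN"]).all()

    def test_generated_expression_recovers_labels(self):
        barcodes = [f"b{i}" for i in range(90)]
        target = {bc: ["CD8+", "CD4+", "DN"][i % 3] for i, bc in enumerate(barcodes)}
        for mode in ("gene", "protein"):
            expr = sd.generate_expression(barcodes, coreceptor_labels=target,
                                          mode=mode, seed=4)
            call = fl.assign_coreceptor(expr, mode)
            assert all(call.loc[bc, "coreceptor"] == target[bc] for bc in barcodes)


class TestPseudotimeAssociation:
    def test_two_identical_groups_have_small_h(self):
        pt = pd.Series(np.tile(np.arange(30.0), 2))
        groups = pd.Series(["g1"] * 30 + ["g2"] * 30)
        res = fl.pseudotime_group_association(pt, groups, min_size=20)
        assert res["H"] == pytest.approx(0.0, abs=1e-9)
        assert res["p"] > 0.9

    def test_small_groups_excluded(self):
        pt = pd.Series(np.arange(45.0))
        groups = pd.Series(["big"] * 40 + ["tiny"] * 5)
        res = fl.pseudotime_group_association(pt, groups, min_size=20)
        assert res["groups"] == ["big"] and np.isnan(res["H"])

    def test_null_p_uniformity(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(300):
            pt = pd.Series(rng.normal(size=120))
            groups = pd.Series(np.repeat([f"g{i}" for i in range(4)], 30))
            pvals.append(fl.pseudotime_group_association(pt, groups)["p"])
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(50):
            pt = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])
            groups = pd.Series(["a"] * 50 + ["b"] * 50)
            if fl.pseudotime_group_association(pd.Series(pt), groups)["p"] < 0.05:
                hits += 1
        assert hits >= 45

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(7)
        pt = pd.Series(rng.normal(size=80))
        groups = pd.Series(np.repeat(["a", "b"], 40))
        a = fl.pseudotime_group_association(pt, groups)
        b = fl.pseudotime_group_association(3.0 * pt + 11.0, groups)
        assert a["H"] == pytest.approx(b["H"]) and a["p"] == pytest.approx(b["p"])

    def test_frequency_threshold_mode(self):
        pt = pd.Series(np.arange(200.0))
        groups = pd.Series(["common"] * 198 + ["rare"] * 2)
        res = fl.pseudotime_group_association(pt, groups, min_frequency=0.01)
        assert res["groups"] == ["common"]


class TestCrossTrajectory:
    def test_identical_effects_give_rho_one(self):
        barcodes = [f"b{i}" for i in range(300)]
        group_of = {bc: f"g{i % 10}" for i, bc in enumerate(barcodes)}
        effects = {f"g{i}": float(i) for i in range(10)}
        table, _ = sd.generate_pseudotime(barcodes, group_of, effects,
                                          noise_sd=0.3, effect_correlation=1.0, seed=8)
        rho, _ = fl.cross_trajectory_group_correlation(table, pd.Series(group_of))
        assert rho > 0.95

    def test_independent_effects_near_zero(self):
        rng = np.random.default_rng(9)
        rhos = []
        for seed in range(40):
            barcodes = [f"b{i}" for i in range(200)]
            group_of = {bc: f"g{i % 10}" for i, bc in enumerate(barcodes)}
            effects = {f"g{i}": float(rng.normal()) for i in range(10)}
            table, _ = sd.generate_pseudotime(barcodes, group_of, effects,
                                              noise_sd=0.5, effect_correlation=0.0,
                                              seed=seed)
            rho, _ = fl.cross_trajectory_group_correlation(table, pd.Series(group_of))
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.15

    def test_too_few_groups_undefined(self):
        table = pd.DataFrame({"TCR": [1.0, 2.0], "cytokine": [1.0, 2.0]}, index=["a", "b"])
        rho, p = fl.cross_trajectory_group_correlation(table, pd.Series({"a": "g1", "b": "g2"}))
        assert np.isnan(rho)


class TestCloneSizePseudotime:
    def test_equal_sizes_undefined(self):
        pt = pd.Series(np.arange(60.0))
        cids = pd.Series(np.repeat([1, 2, 3], 20))
        r, p = fl.clone_size_pseudotime_correlation(pt, cids)
        assert np.isnan(r)

    def test_null_effect_near_zero(self):
        rng = np.random.default_rng(10)
        rs = []
        for _ in range(30):
            cids = np.repeat([1, 2, 3, 4], [80, 40, 30, 20])
            pt = rng.normal(size=cids.size)
            r, _ = fl.clone_size_pseudotime_correlation(pd.Series(pt), pd.Series(cids))
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_planted_positive_size_effect(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(30):
            sizes = {1: 100, 2: 60, 3: 30, 4: 20}
            cids = np.repeat(list(sizes), list(sizes.values()))
            effect = {cid: 0.5 * np.log10(n) for cid, n in sizes.items()}
            pt = np.array([effect[c] for c in cids]) + rng.normal(0, 0.3, size=cids.size)
            r, _ = fl.clone_size_pseudotime_correlation(pd.Series(pt), pd.Series(cids))
            hits += r > 0
        assert hits >= 27


class TestDifferentialImportance:
    def _tables(self, ranks_a, ranks_b, fdr_a=None, fdr_b=None):
        genes = [f"G{i}" for i in range(len(ranks_a))]
        fa = [0.01] * len(genes) if fdr_a is None else fdr_a
        fb = [0.01] * len(genes) if fdr_b is None else fdr_b
        a = pd.DataFrame({"importance": 1.0 / np.asarray(ranks_a),
                          "rank": ranks_a, "fdr": fa}, index=genes)
        b = pd.DataFrame({"importance": 1.0 / np.asarray(ranks_b),
                          "rank": ranks_b, "fdr": fb}, index=genes)
        return a, b

    def test_equal_ranks_give_unit_ratio(self):
        a, b = self._tables([1, 2, 3], [1, 2, 3])
        res = fl.differential_gene_importance(a, b)
        assert (res["ratio"] == 1.0).all()

    def test_ratio_arithmetic(self):
        a, b = self._tables([3, 10], [300, 10])
        res = fl.differential_gene_importance(a, b)
        assert res["ratio"].iloc[0] == pytest.approx(100.0)

    def test_symmetry(self):
        rng = np.random.default_rng(12)
        ranks_a = rng.permutation(200) + 1
        ranks_b = rng.permutation(200) + 1
        a, b = self._tables(ranks_a, ranks_b)
        ab = fl.differential_gene_importance(a, b)
        ba = fl.differential_gene_importance(b, a)
        np.testing.assert_array_equal(ab["ratio"].to_numpy(), ba["ratio"].to_numpy())
        np.testing.assert_array_equal(ab["selected"].to_numpy(), ba["selected"].to_numpy())

    def test_selection_matches_brute_force_predicate(self):
        rng = np.random.default_rng(13)
        n = 1000
        ranks_a = rng.permutation(n) + 1
        ranks_b = rng.permutation(n) + 1
        fdr_a = rng.random(n)
        fdr_b = rng.random(n)
        a, b = self._tables(ranks_a, ranks_b, fdr_a, fdr_b)
        res = fl.differential_gene_importance(a, b)
        for g, ra, rb, qa, qb in zip(res.index, ranks_a, ranks_b, fdr_a, fdr_b):
            expected = ((qa < 0.05) or (qb < 0.05)) and ((ra <= 150) or (rb <= 150))
            assert bool(res.loc[g, "selected"]) == expected
            assert res.loc[g, "ratio"] == pytest.approx(max(ra, rb) / min(ra, rb))

    def test_differing_universes_raise(self):
        a, b = self._tables([1, 2], [1, 2])
        with pytest.raises(ValueError):
            fl.differential_gene_importance(a, b.rename(index={"G0": "X"}))
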